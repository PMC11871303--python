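"""Peak picking, Lorentzian fitting, elliptical integration, CSP matching."""

import itertools

import numpy as np
import pytest

from carnmr.spectra import (
    Spectrum2D,
    csp,
    estimate_noise,
    fit_peak,
    integrate_elliptical,
    lorentzian_volume,
    pick_peaks,
    read_peaklist,
    read_spectrum,
    transfer_assignments,
    write_peaklist,
    write_spectrum,
)
from carnmr.synthetic import GridSpec, LigandGroundTruth, simulate_spectrum

from conftest import make_lorentzian_spectrum


class TestSpectrumContainer:
    def test_axis_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Spectrum2D(np.zeros((4, 5)), np.linspace(0, 1, 4), np.linspace(0, 1, 4))

    def test_non_monotone_axis_rejected(self):
        with pytest.raises(ValueError):
            Spectrum2D(np.zeros((3, 3)), np.array([1.0, 3.0, 2.0]), np.linspace(0, 1, 3))

    def test_descending_axes_normalised(self):
        z = np.arange(12.0).reshape(3, 4)
        asc = Spectrum2D(z.copy(), np.linspace(8, 9, 4), np.linspace(100, 105, 3))
        desc = Spectrum2D(z[::-1, ::-1].copy(), np.linspace(9, 8, 4),
                          np.linspace(105, 100, 3))
        np.testing.assert_array_equal(asc.intensities, desc.intensities)
        np.testing.assert_array_equal(asc.axis_H, desc.axis_H)

    def test_tsv_json_round_trip(self, tmp_path):
        spec = make_lorentzian_spectrum(grid=GridSpec(h_points=32, n_points=16))
        write_spectrum(spec, tmp_path / "s")
        back = read_spectrum(tmp_path / "s")
        np.testing.assert_allclose(back.intensities, spec.intensities, rtol=1e-6)
        np.testing.assert_allclose(back.axis_H, spec.axis_H)


class TestNoiseEstimate:
    def test_all_zero_spectrum(self):
        spec = Spectrum2D(np.zeros((64, 64)), np.linspace(8, 9, 64),
                          np.linspace(100, 110, 64))
        assert estimate_noise(spec) == 0.0

    def test_pure_gaussian_grid(self):
        """MAD estimator on 512x128 unit-variance noise lands within 5%."""
        rng = np.random.default_rng(123)
        z = rng.normal(0, 1, (128, 512))
        spec = Spectrum2D(z, np.linspace(7, 9, 512), np.linspace(100, 112, 128))
        assert 0.95 <= estimate_noise(spec) <= 1.05

    def test_peak_does_not_bias_estimate(self):
        """A peak occupying <5% of the grid leaves the estimate within 10%."""
        rng = np.random.default_rng(7)
        spec = make_lorentzian_spectrum(amp=100.0, noise_sd=2.0, rng=rng)
        assert estimate_noise(spec) == pytest.approx(2.0, rel=0.10)

    def test_explicit_region(self):
        rng = np.random.default_rng(5)
        spec = make_lorentzian_spectrum(amp=100.0, noise_sd=1.5, rng=rng)
        sigma = estimate_noise(spec, region=(7.7, 8.0, 106.0, 108.0))
        assert sigma == pytest.approx(1.5, rel=0.10)

    def test_empty_region_rejected(self):
        spec = make_lorentzian_spectrum()
        with pytest.raises(ValueError):
            estimate_noise(spec, region=(1.0, 1.1, 2.0, 2.1))


class TestPeakPicking:
    def test_two_resolved_peaks_found_at_true_centers(self):
        lig = LigandGroundTruth("L", f_rep=0.5, seed=0)
        spec = simulate_spectrum(lig)
        spec.noise_sigma = 1e-9
        seeds = pick_peaks(spec, threshold_sigma=5.0)
        assert len(seeds) == 2
        found = sorted((s.ppm_H, s.ppm_N) for s in seeds)
        assert found[0][0] == pytest.approx(8.10, abs=spec.step_H)
        assert found[1][0] == pytest.approx(8.40, abs=spec.step_H)

    def test_all_noise_high_threshold_finds_nothing(self):
        rng = np.random.default_rng(99)
        z = rng.normal(0, 1, (128, 256))
        spec = Spectrum2D(z, np.linspace(7, 9, 256), np.linspace(100, 112, 128))
        estimate_noise(spec)
        assert pick_peaks(spec, threshold_sigma=8.0) == []

    def test_close_pair_suppressed_to_taller(self):
        grid = GridSpec()
        ax_h, ax_n = grid.axes()
        z = np.zeros((ax_n.size, ax_h.size))
        for amp, ch in ((10.0, 8.40), (6.0, 8.41)):
            lh = 1.0 / (1.0 + (2 * (ax_h - ch) / 0.02) ** 2)
            ln = 1.0 / (1.0 + (2 * (ax_n - 109.5) / 0.15) ** 2)
            z += amp * ln[:, None] * lh[None, :]
        spec = Spectrum2D(z, ax_h, ax_n)
        spec.noise_sigma = 0.1
        seeds = pick_peaks(spec, threshold_sigma=5.0, min_separation=(0.05, 0.4))
        assert len(seeds) == 1
        assert seeds[0].ppm_H == pytest.approx(8.40, abs=2 * spec.step_H)

    def test_threshold_must_be_positive(self):
        spec = make_lorentzian_spectrum()
        spec.noise_sigma = 1.0
        with pytest.raises(ValueError):
            pick_peaks(spec, threshold_sigma=0.0)

    def test_requires_noise_estimate(self):
        spec = make_lorentzian_spectrum()
        with pytest.raises(ValueError):
            pick_peaks(spec)


def _seed_at(spec, h, n):
    ih = int(np.argmin(np.abs(spec.axis_H - h)))
    inn = int(np.argmin(np.abs(spec.axis_N - n)))
    from carnmr.spectra import PeakSeed
    return PeakSeed(float(spec.axis_H[ih]), float(spec.axis_N[inn]), ih, inn,
                    float(spec.intensities[inn, ih]))


class TestPeakFitting:
    def test_noiseless_parameters_and_analytic_volume(self):
        spec = make_lorentzian_spectrum(amp=100.0, fwhm_h=0.02, fwhm_n=0.15)
        spec.noise_sigma = 0.0
        peak = fit_peak(spec, _seed_at(spec, 8.40, 109.5))
        assert peak.converged
        assert peak.amplitude == pytest.approx(100.0, rel=1e-3)
        assert peak.fwhm_H == pytest.approx(0.02, rel=1e-3)
        assert peak.fwhm_N == pytest.approx(0.15, rel=1e-3)
        assert peak.volume == pytest.approx(
            (np.pi / 2) ** 2 * 100 * 0.02 * 0.15, rel=0.01)

    def test_center_accuracy_at_snr_50(self):
        """Across 50 noise realisations, center error stays below fwhm/10."""
        errs_h, errs_n = [], []
        for i in range(50):
            rng = np.random.default_rng(1000 + i)
            spec = make_lorentzian_spectrum(amp=100.0, noise_sd=2.0, rng=rng)
            spec.noise_sigma = 2.0
            peak = fit_peak(spec, _seed_at(spec, 8.40, 109.5))
            errs_h.append(abs(peak.center_H - 8.40))
            errs_n.append(abs(peak.center_N - 109.5))
        assert np.quantile(errs_h, 0.95) < 0.02 / 10
        assert np.quantile(errs_n, 0.95) < 0.15 / 10

    def test_displaced_seed_same_basin(self):
        spec = make_lorentzian_spectrum()
        spec.noise_sigma = 0.0
        exact = fit_peak(spec, _seed_at(spec, 8.40, 109.5))
        ih = int(np.argmin(np.abs(spec.axis_H - 8.40))) + 1
        inn = int(np.argmin(np.abs(spec.axis_N - 109.5))) + 1
        from carnmr.spectra import PeakSeed
        displaced = PeakSeed(float(spec.axis_H[ih]), float(spec.axis_N[inn]),
                             ih, inn, float(spec.intensities[inn, ih]))
        shifted = fit_peak(spec, displaced)
        assert shifted.center_H == pytest.approx(exact.center_H, abs=1e-5)
        assert shifted.center_N == pytest.approx(exact.center_N, abs=1e-4)

    def test_window_too_small_rejected(self):
        spec = make_lorentzian_spectrum()
        with pytest.raises(ValueError):
            fit_peak(spec, _seed_at(spec, 8.40, 109.5), window=(0.005, 0.02))

    def test_scale_equivariance(self):
        spec = make_lorentzian_spectrum(amp=50.0)
        spec.noise_sigma = 0.0
        base = fit_peak(spec, _seed_at(spec, 8.40, 109.5))
        spec2 = Spectrum2D(spec.intensities * 3.0, spec.axis_H, spec.axis_N, 0.0)
        scaled = fit_peak(spec2, _seed_at(spec2, 8.40, 109.5))
        assert scaled.amplitude == pytest.approx(3 * base.amplitude, rel=1e-3)
        assert scaled.volume == pytest.approx(3 * base.volume, rel=1e-3)
        assert scaled.center_H == pytest.approx(base.center_H, abs=1e-6)
        assert scaled.fwhm_H == pytest.approx(base.fwhm_H, rel=1e-4)

    def test_axis_direction_invariance(self):
        spec = make_lorentzian_spectrum()
        spec.noise_sigma = 0.0
        base = fit_peak(spec, _seed_at(spec, 8.40, 109.5))
        flipped = Spectrum2D(spec.intensities[::-1, ::-1].copy(),
                             spec.axis_H[::-1].copy(), spec.axis_N[::-1].copy(), 0.0)
        other = fit_peak(flipped, _seed_at(flipped, 8.40, 109.5))
        assert other.center_H == pytest.approx(base.center_H, abs=1e-6)
        assert other.volume == pytest.approx(base.volume, rel=1e-4)


class TestEllipticalIntegration:
    def test_capture_fraction_matches_analytic_ellipse_integral(self):
        """dblquad oracle: the ellipse with semi-axes 3x fwhm contains 79.25%
        of a separable 2D Lorentzian's volume; the grid sum should land just
        below that (median-baseline subtraction removes a sliver of tail)."""
        spec = make_lorentzian_spectrum(amp=100.0)
        spec.noise_sigma = 0.0
        peak = fit_peak(spec, _seed_at(spec, 8.40, 109.5))
        result = integrate_elliptical(spec, peak, radii_multiplier=3.0)
        analytic = lorentzian_volume(100.0, 0.02, 0.15)
        assert 0.77 * analytic <= result.volume <= 0.7925 * analytic * 1.01

    def test_zero_spectrum_zero_volume(self):
        spec = make_lorentzian_spectrum(amp=100.0)
        spec.noise_sigma = 0.0
        peak = fit_peak(spec, _seed_at(spec, 8.40, 109.5))
        zero = Spectrum2D(np.zeros_like(spec.intensities), spec.axis_H, spec.axis_N)
        assert integrate_elliptical(zero, peak).volume == 0.0

    def test_ratio_stable_across_equal_shape_peaks(self):
        """Model volume vs elliptical sum: constant ratio (CV < 2%) for peaks
        of identical shape and varying amplitude/position."""
        ratios = []
        for amp, ch, cn in [(100, 8.40, 109.5), (40, 8.10, 108.5),
                            (70, 8.25, 110.5), (15, 8.55, 107.5)]:
            spec = make_lorentzian_spectrum(amp=amp, center_h=ch, center_n=cn)
            spec.noise_sigma = 0.0
            peak = fit_peak(spec, _seed_at(spec, ch, cn))
            ratios.append(integrate_elliptical(spec, peak).volume / peak.volume)
        assert np.std(ratios) / np.mean(ratios) < 0.02

    def test_edge_clipping_flagged(self):
        spec = make_lorentzian_spectrum(center_h=7.72)  # near grid edge
        spec.noise_sigma = 0.0
        peak = fit_peak(spec, _seed_at(spec, 7.72, 109.5), window=(0.08, 0.9))
        assert integrate_elliptical(spec, peak).clipped


class TestCsp:
    def test_identical_shifts(self):
        assert csp((8.2, 109.0), (8.2, 109.0)) == 0.0

    def test_proton_only(self):
        assert csp((8.0, 109.0), (8.03, 109.0), alpha_N=0.7) == pytest.approx(0.03)

    def test_three_four_five(self):
        assert csp((8.0, 109.0), (8.03, 109.2), alpha_N=0.2) == pytest.approx(0.05)


class TestAssignmentTransfer:
    def test_identity_mapping(self):
        ref = [("G399", 8.40, 109.5), ("R234", 7.95, 118.0), ("N375", 8.60, 115.2)]
        obs = [(h, n) for _, h, n in ref]
        result = transfer_assignments(ref, obs)
        assert result.unmatched == []
        assert result.total_csp == 0.0
        assert {rid: j for rid, (j, _) in result.mapping.items()} == {
            "G399": 0, "R234": 1, "N375": 2}

    def test_moved_peak_unmatched(self):
        ref = [("G399", 8.40, 109.5), ("R234", 7.95, 118.0)]
        obs = [(8.40, 109.5), (7.40, 125.0)]
        result = transfer_assignments(ref, obs, max_csp=0.1)
        assert result.unmatched == ["R234"]

    def test_matches_brute_force_on_random_instances(self):
        """5x5 matching equals exhaustive enumeration over all 120 assignments."""
        rng = np.random.default_rng(17)
        for _ in range(5):
            ref = [(f"R{i}", 8 + rng.uniform(-0.3, 0.3), 110 + rng.uniform(-3, 3))
                   for i in range(5)]
            obs = [(h + rng.normal(0, 0.03), n + rng.normal(0, 0.2))
                   for _, h, n in ref]
            result = transfer_assignments(ref, obs, alpha_N=0.14, max_csp=0.15)
            big = 1e6
            best = None
            for perm in itertools.permutations(range(5)):
                cost = 0.0
                for i, j in enumerate(perm):
                    d = csp(ref[i][1:], obs[j], 0.14)
                    cost += d if d <= 0.15 else big
                best = cost if best is None else min(best, cost)
            matched_cost = result.total_csp + big * len(result.unmatched)
            assert matched_cost == pytest.approx(best % big + big * (best // big), rel=1e-9) \
                or abs(matched_cost - best) < 1e-6

    def test_empty_lists_rejected(self):
        with pytest.raises(ValueError):
            transfer_assignments([], [(8.0, 109.0)])


def test_peaklist_tsv_round_trip(tmp_path):
    from carnmr.spectra import FittedPeak
    peaks = [FittedPeak(8.4, 109.5, 0.02, 0.15, 100.0, 0.74, 1.0, True,
                        residue_id="G399", flags=["ok"])]
    path = tmp_path / "peaks.tsv"
    write_peaklist(peaks, path)
    df = read_peaklist(path)
    assert df.loc[0, "residue_id"] == "G399"
    assert df.loc[0, "volume"] == pytest.approx(0.74)
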