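"""End-to-end orchestration: ligand series -> spectra/assays -> CAR table.

This is the glue the analysis scripts and the acceptance checks run: it
simulates (or accepts) the raw data, fits it with the module-level
operations, and assembles the per-ligand conformation-activity profile.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import pharm, synthetic
from .ensemble import Anchors, ensemble_table
from .spectra import FittedPeak, Spectrum2D, estimate_noise, fit_peak, pick_peaks
from .synthetic import GLY399, GridSpec, LigandGroundTruth

DEFAULT_ANCHORS = Anchors(
    rep=(GLY399.delta_H_rep, GLY399.delta_N_rep),
    act=(GLY399.delta_H_act, GLY399.delta_N_act),
)

# 12-point half-log dilution from 100 uM: spans every latent EC50 in the series
TRFRET_CONCENTRATIONS_M = 1e-4 * 10.0 ** (-0.5 * np.arange(12))[::-1]


def fit_spectrum_peaks(
    spectrum: Spectrum2D,
    threshold_sigma: float = 5.0,
    window: tuple[float, float] = (0.12, 0.9),
    min_separation: tuple[float, float] = (0.05, 0.4),
) -> list[FittedPeak]:
    """Noise estimate, peak pick, per-seed Lorentzian fit, and deduplication.

    Seeds riding on the tails of a strong peak converge to the same optimum;
    fitted peaks whose centers coincide within half a linewidth are merged,
    keeping the fit with the lowest residual.
    """
    estimate_noise(spectrum)
    seeds = pick_peaks(spectrum, threshold_sigma=threshold_sigma,
                       min_separation=min_separation)
    fitted = [fit_peak(spectrum, s, window=window) for s in seeds]
    fitted.sort(key=lambda p: p.fit_rss)
    unique: list[FittedPeak] = []
    for p in fitted:
        dup = any(
            abs(p.center_H - q.center_H) < 0.5 * max(p.fwhm_H, q.fwhm_H)
            and abs(p.center_N - q.center_N) < 0.5 * max(p.fwhm_N, q.fwhm_N)
            for q in unique
        )
        if not dup:
            unique.append(p)
    unique.sort(key=lambda p: -p.volume)
    return unique


def ensemble_from_series(
    series: list[LigandGroundTruth],
    snr: float = 50.0,
    grid: GridSpec = GridSpec(),
    anchors: Anchors = DEFAULT_ANCHORS,
    residue=GLY399,
    threshold_sigma: float = 5.0,
) -> pd.DataFrame:
    """Simulate one spectrum per ligand and recover delta_bar / p_rep."""
    peaks_by_ligand = {}
    for lig in series:
        spec = synthetic.simulate_spectrum(lig, residues=(residue,), grid=grid, snr=snr)
        peaks_by_ligand[lig.ligand_id] = fit_spectrum_peaks(
            spec, threshold_sigma=threshold_sigma
        )
    return ensemble_table(peaks_by_ligand, residue.residue_id, anchors)


def profile_from_series(
    series: list[LigandGroundTruth],
    noise_cv: float = 0.02,
    fp_noise_sd: float = 1.0,
    ct_noise_sd: float = 0.1,
    include_fp: bool = True,
    include_expression: bool = True,
) -> pd.DataFrame:
    """Per-ligand functional profile from simulated assay data.

    TR-FRET efficacies are the fitted plateaus (top); affinities are pKd from
    fixed-shared-Bmax saturation fits; bias columns difference NCoR1 - MED1;
    reporter activity is the fitted plateau of the cellular reporter;
    expression is RQ of the target gene vs the vehicle calibrator.
    """
    rows = []
    fp_tables: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
    if include_fp:
        for lig in series:
            for pep in ("NCoR1", "MED1"):
                df = synthetic.simulate_fp_curve(lig, pep, noise_sd=fp_noise_sd)
                fp_tables[(lig.ligand_id, pep)] = (
                    df["x_value"].to_numpy(), df["response"].to_numpy()
                )
        bmax = pharm.estimate_shared_bmax(list(fp_tables.values()))
    for lig in series:
        row: dict = {"ligand_id": lig.ligand_id}
        for pep, col in (("NCoR1", "ncor1"), ("MED1", "med1")):
            df = synthetic.simulate_trfret_curve(
                lig, pep, TRFRET_CONCENTRATIONS_M, noise_cv=noise_cv
            )
            fit = pharm.fit_dose_response(df["x_value"], df["response"],
                                          direction_hint="up")
            row[f"{col}_efficacy"] = fit.top
            row[f"{col}_log_ec50"] = fit.log_ec50
        row["trfret_bias"] = row["ncor1_efficacy"] - row["med1_efficacy"]
        if include_fp:
            for pep, col in (("NCoR1", "ncor1"), ("MED1", "med1")):
                x, y = fp_tables[(lig.ligand_id, pep)]
                sat = pharm.fit_saturation(x, y, bmax_fixed=bmax)
                row[f"{col}_affinity"] = sat.pkd
            row["fp_bias"] = pharm.bias_factor(
                10.0 ** -row["ncor1_affinity"], 10.0 ** -row["med1_affinity"],
                scale="log-affinity",
            ).bias
        rep = synthetic.simulate_reporter_curve(lig, TRFRET_CONCENTRATIONS_M)
        rep_fit = pharm.fit_dose_response(rep["x_value"], rep["response"])
        row["reporter_activity"] = rep_fit.top
        if include_expression:
            ct = synthetic.simulate_expression(lig, noise_sd=ct_noise_sd)
            rqs = pharm.relative_expression(
                ct, synthetic.TARGET_GENE, synthetic.HOUSEKEEPING_GENE,
                synthetic.CALIBRATOR,
            )
            row["rq_expression"] = next(
                r.rq for r in rqs if r.condition == lig.ligand_id
            )
        rows.append(row)
    return pd.DataFrame(rows)


def build_car_table(
    series: list[LigandGroundTruth],
    snr: float = 50.0,
    noise_cv: float = 0.02,
    include_fp: bool = True,
    include_expression: bool = True,
    **ensemble_kwargs,
) -> pd.DataFrame:
    """Join the NMR ensemble summary with the functional profile per ligand."""
    ens = ensemble_from_series(series, snr=snr, **ensemble_kwargs)
    prof = profile_from_series(series, noise_cv=noise_cv, include_fp=include_fp,
                               include_expression=include_expression)
    out = ens.rename(columns={"delta_bar_H_ppm": "weighted_shift_H"}).merge(
        prof, on="ligand_id", how="outer"
    )
    return out.drop(columns=["residue_id", "flags"], errors="ignore")
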