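import numpy as np
import pytest

from carnmr.spectra import Spectrum2D
from carnmr.synthetic import GLY399, GridSpec, LigandGroundTruth


@pytest.fixture
def grid():
    return GridSpec()


@pytest.fixture
def half_rep_ligand():
    return LigandGroundTruth("L01", f_rep=0.5, seed=11)


def make_lorentzian_spectrum(
    amp=100.0, center_h=8.40, center_n=109.5, fwhm_h=0.02, fwhm_n=0.15,
    grid=GridSpec(), noise_sd=0.0, rng=None,
):
    """Single separable 2D Lorentzian on the default grid."""
    ax_h, ax_n = grid.axes()
    lh = 1.0 / (1.0 + (2.0 * (ax_h - center_h) / fwhm_h) ** 2)
    ln = 1.0 / (1.0 + (2.0 * (ax_n - center_n) / fwhm_n) ** 2)
    z = amp * ln[:, None] * lh[None, :]
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        z = z + rng.normal(0, noise_sd, z.shape)
    return Spectrum2D(z, ax_h, ax_n)


def make_pdb(coords, chain="A", start_res=1, altlocs=None, n_models=1):
    """Minimal PDB text with one CA atom per residue."""
    lines = []
    for m in range(1, n_models + 1):
        if n_models > 1:
            lines.append(f"MODEL     {m:4d}")
        serial = 1
        for i, xyz in enumerate(coords):
            x, y, z = (c + (m - 1) * 10.0 for c in xyz)
            alts = altlocs[i] if altlocs else [" "]
            for alt in alts:
                lines.append(
                    f"ATOM  {serial:5d}  CA {alt}ALA {chain}{start_res + i:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00 20.00           C"
                )
                serial += 1
        if n_models > 1:
            lines.append("ENDMDL")
    lines.append("END")
    return "\n".join(lines) + "\n"
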