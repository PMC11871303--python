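"""Synthetic ligand series with ground-truth ensemble populations.

Every downstream raw-data type the analysis consumes is generated here from a
single latent variable per ligand: ``f_rep``, the fraction of the receptor
ligand-binding domain occupying the repressive (corepressor-competent)
conformation.  Slow conformational exchange puts one 2D NMR peak per state on
the spectrum with volumes proportional to the state populations; corepressor
(NCoR1) recruitment efficacy rises with ``f_rep`` while coactivator (MED1)
recruitment falls; target-gene expression falls with ``f_rep``.

All generators are pure functions of (parameters, seed): the master seed is
expanded with a counter-based SeedSequence scheme so each (ligand, assay)
pair gets an independent, reproducible stream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .spectra import Spectrum2D, lorentzian_volume

# --- stream codes for counter-based seed expansion -------------------------
_STREAM = {"spectrum": 1, "trfret": 2, "fp": 3, "qpcr": 4, "reporter": 5}


def _rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAM[stream], *extra))
    )


# ---------------------------------------------------------------------------
# ground truth

@dataclass(frozen=True)
class LigandGroundTruth:
    """Latent per-ligand truth driving all synthetic outputs."""

    ligand_id: str
    f_rep: float
    exchange_regime: str = "slow"  # {"slow", "fast"}
    potency_log10_M: float = -6.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_rep <= 1.0:
            raise ValueError(f"f_rep must be in [0, 1], got {self.f_rep}")
        if self.exchange_regime not in ("slow", "fast"):
            raise ValueError(f"unknown exchange regime {self.exchange_regime!r}")


def make_ligand_series(
    n_ligands: int,
    f_rep_spacing: str | Sequence[float] = "uniform",
    seed: int = 0,
) -> list[LigandGroundTruth]:
    """A graded ligand series spanning the full repressive-active range.

    Ligands are numbered by descending ``f_rep`` (L01 is the strongest
    inverse agonist), mirroring rank-order-by-corepressor-efficacy naming.
    Per-ligand assay potencies are drawn once from the master seed; per-ligand
    child seeds are spawned deterministically.
    """
    if n_ligands < 2:
        raise ValueError("n_ligands must be >= 2")
    if isinstance(f_rep_spacing, str):
        if f_rep_spacing != "uniform":
            raise ValueError(f"unknown spacing {f_rep_spacing!r}")
        f_values = np.linspace(1.0, 0.0, n_ligands)
    else:
        f_values = np.asarray(list(f_rep_spacing), dtype=float)
        if f_values.size != n_ligands:
            raise ValueError("custom f_rep list length must equal n_ligands")
    master = np.random.SeedSequence(int(seed))
    child_seeds = master.generate_state(n_ligands, dtype=np.uint32)
    potencies = np.random.default_rng(master).uniform(-7.5, -5.5, size=n_ligands)
    return [
        LigandGroundTruth(
            ligand_id=f"L{i + 1:02d}",
            f_rep=float(f),
            potency_log10_M=float(p),
            seed=int(s),
        )
        for i, (f, p, s) in enumerate(zip(f_values, potencies, child_seeds))
    ]


def ground_truth_frame(series: Iterable[LigandGroundTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "ligand_id": lig.ligand_id,
                "f_rep": lig.f_rep,
                "exchange_regime": lig.exchange_regime,
                "potency_log10_M": lig.potency_log10_M,
                "seed": lig.seed,
            }
            for lig in series
        ]
    )


# ---------------------------------------------------------------------------
# 2D spectra

@dataclass(frozen=True)
class ResidueStateShifts:
    """Peak geometry for one ensemble-reporter residue: repressive- and
    active-state (1H, 15N) centers plus linewidths (FWHM, ppm)."""

    residue_id: str
    delta_H_rep: float
    delta_N_rep: float
    delta_H_act: float
    delta_N_act: float
    lw_H: float = 0.02
    lw_N: float = 0.15

    def __post_init__(self) -> None:
        if self.lw_H <= 0 or self.lw_N <= 0:
            raise ValueError("linewidths must be strictly positive")
        if (self.delta_H_rep, self.delta_N_rep) == (self.delta_H_act, self.delta_N_act):
            raise ValueError("repressive and active centers must be distinct")


# Gly399-like default: rep/act 1H centers 15 linewidths apart, so slow-exchange
# doublets are fully resolved on the default grid.
GLY399 = ResidueStateShifts("G399", delta_H_rep=8.40, delta_N_rep=109.5,
                            delta_H_act=8.10, delta_N_act=108.5)
# Overlap decoy emulating a nearby glycine stabilised by repressive ligands;
# sits 1.5 H-linewidths from the G399 repressive peak.
GLY284_DECOY = ResidueStateShifts("G284", delta_H_rep=8.43, delta_N_rep=109.65,
                                  delta_H_act=7.90, delta_N_act=107.2)


@dataclass(frozen=True)
class GridSpec:
    """ppm extents and point counts for the synthetic 2D grid."""

    h_range: tuple[float, float] = (7.7, 8.8)
    n_range: tuple[float, float] = (106.0, 112.0)
    h_points: int = 320
    n_points: int = 256

    def axes(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            np.linspace(*self.h_range, self.h_points),
            np.linspace(*self.n_range, self.n_points),
        )


DEFAULT_AMPLITUDE = 100.0


def simulate_spectrum(
    ligand: LigandGroundTruth,
    residues: Sequence[ResidueStateShifts] = (GLY399,),
    grid: GridSpec = GridSpec(),
    snr: float = np.inf,
    seed: int | None = None,
    decoy_overlap: bool = False,
) -> Spectrum2D:
    """One- or two-peak slow-exchange spectrum per residue.

    Each residue contributes Lorentzian peaks at its repressive and active
    centers with volumes ``f_rep`` and ``1 - f_rep`` times a common scale, so
    the total volume per residue is independent of ``f_rep``.  Additive
    Gaussian noise has sd = (max noiseless height) / snr.  ``snr=inf`` gives
    the noiseless surface.
    """
    axis_h, axis_n = grid.axes()
    residues = list(residues)
    if decoy_overlap:
        residues.append(GLY284_DECOY)
    z = np.zeros((axis_n.size, axis_h.size))
    for res in residues:
        for (c_h, c_n) in ((res.delta_H_rep, res.delta_N_rep),
                           (res.delta_H_act, res.delta_N_act)):
            if not (axis_h[0] <= c_h <= axis_h[-1] and axis_n[0] <= c_n <= axis_n[-1]):
                raise ValueError(
                    f"peak center ({c_h}, {c_n}) of residue {res.residue_id} "
                    "lies outside the grid"
                )
        min_pts = min((axis_h.size - 1) / (grid.h_range[1] - grid.h_range[0]) * res.lw_H,
                      (axis_n.size - 1) / (grid.n_range[1] - grid.n_range[0]) * res.lw_N)
        if min_pts < 5:
            raise ValueError(
                f"grid too coarse for residue {res.residue_id}: "
                f"{min_pts:.1f} points per linewidth (need >= 5)"
            )
        for amp_frac, c_h, c_n in (
            (ligand.f_rep, res.delta_H_rep, res.delta_N_rep),
            (1.0 - ligand.f_rep, res.delta_H_act, res.delta_N_act),
        ):
            if amp_frac <= 0.0:
                continue
            amp = DEFAULT_AMPLITUDE * amp_frac
            lh = 1.0 / (1.0 + (2.0 * (axis_h - c_h) / res.lw_H) ** 2)
            ln = 1.0 / (1.0 + (2.0 * (axis_n - c_n) / res.lw_N) ** 2)
            z += amp * ln[:, None] * lh[None, :]
    true_sigma = 0.0
    if np.isfinite(snr):
        if snr <= 0:
            raise ValueError("snr must be positive")
        true_sigma = float(z.max() / snr)
        rng = _rng(ligand.seed if seed is None else seed, "spectrum")
        z = z + rng.normal(0.0, true_sigma, size=z.shape)
    return Spectrum2D(z, axis_h, axis_n)


def true_peak_volumes(ligand: LigandGroundTruth,
                      residue: ResidueStateShifts = GLY399) -> tuple[float, float]:
    """Noiseless (repressive, active) analytic peak volumes for a residue."""
    total = lorentzian_volume(DEFAULT_AMPLITUDE, residue.lw_H, residue.lw_N)
    return total * ligand.f_rep, total * (1.0 - ligand.f_rep)


# ---------------------------------------------------------------------------
# TR-FRET dose-response curves

TRFRET_BOTTOM = 0.20      # basal 520/495 TR-FRET ratio (DMSO)
TRFRET_TOP_MIN = 0.25     # plateau at zero population of the favoured state
TRFRET_SPAN = 0.55        # plateau dynamic range across the series


def trfret_true_params(ligand: LigandGroundTruth, peptide: str) -> tuple[float, float, float]:
    """(bottom, top, EC50 molar) of the generating three-parameter sigmoid."""
    if peptide == "NCoR1":
        link = ligand.f_rep
    elif peptide == "MED1":
        link = 1.0 - ligand.f_rep
    else:
        raise ValueError(f"unknown peptide {peptide!r}")
    top = TRFRET_TOP_MIN + TRFRET_SPAN * link
    return TRFRET_BOTTOM, top, 10.0 ** ligand.potency_log10_M


def simulate_trfret_curve(
    ligand: LigandGroundTruth,
    peptide: str,
    concentrations: Sequence[float],
    noise_cv: float = 0.02,
    seed: int | None = None,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Coregulator-peptide recruitment dose-response table.

    Responses follow the three-parameter sigmoid (Hill slope 1) with a
    plateau linked monotonically to ``f_rep`` (increasing for NCoR1,
    decreasing for MED1) plus multiplicative Gaussian noise of the given CV.
    """
    x = np.asarray(list(concentrations), dtype=float)
    if x.size == 0:
        raise ValueError("concentration list must be non-empty")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    bottom, top, ec50 = trfret_true_params(ligand, peptide)
    rng = _rng(ligand.seed if seed is None else seed, "trfret",
               0 if peptide == "NCoR1" else 1)
    rows = []
    for rep in range(n_replicates):
        y = bottom + (top - bottom) / (1.0 + ec50 / x)
        if noise_cv > 0:
            y = y * (1.0 + rng.normal(0.0, noise_cv, size=y.shape))
        for xi, yi in zip(x, y):
            rows.append({"ligand_id": ligand.ligand_id, "peptide": peptide,
                         "x_value": xi, "x_units": "M", "response": yi,
                         "replicate": rep + 1})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FP saturation binding

FP_BMAX = 120.0        # mP above background at saturation
FP_BACKGROUND = 60.0   # free-tracer polarization, mP
MAX_PROTEIN_M = 45e-6  # highest protein concentration used


def default_kd_link(f_rep: float, peptide: str) -> float:
    """Affinity link: pKd = 4.0 + 2.5 * (state population favouring the peptide).

    NCoR1 binds the repressive conformation (Kd from 100 uM at f_rep=0 down
    to 0.32 uM at f_rep=1); MED1 the mirror image.  The weak end deliberately
    exceeds the 45 uM maximum protein concentration, so those conditions do
    not saturate.
    """
    link = f_rep if peptide == "NCoR1" else 1.0 - f_rep
    return 10.0 ** -(4.0 + 2.5 * link)


def simulate_fp_curve(
    ligand: LigandGroundTruth,
    peptide: str,
    protein_concentrations: Sequence[float] | None = None,
    kd_link: Callable[[float, str], float] = default_kd_link,
    bmax: float = FP_BMAX,
    background: float = FP_BACKGROUND,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fluorescence-polarization saturation table: Y = Bmax*X/(Kd+X) + background + noise."""
    if bmax <= 0:
        raise ValueError("Bmax must be positive")
    if protein_concentrations is None:
        protein_concentrations = MAX_PROTEIN_M / (2.0 ** np.arange(12))[::-1]
    x = np.asarray(list(protein_concentrations), dtype=float)
    if np.any(x <= 0):
        raise ValueError("protein concentrations must be positive")
    kd = kd_link(ligand.f_rep, peptide)
    y = bmax * x / (kd + x) + background
    if noise_sd > 0:
        rng = _rng(ligand.seed if seed is None else seed, "fp",
                   0 if peptide == "NCoR1" else 1)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return pd.DataFrame({
        "ligand_id": ligand.ligand_id, "peptide": peptide, "x_value": x,
        "x_units": "M", "response": y, "replicate": 1,
    })


# ---------------------------------------------------------------------------
# cellular reporter (single-concentration profile support)

REPORTER_BOTTOM = 0.1   # fully repressed luciferase activity (fold vs DMSO=1)
REPORTER_TOP = 4.0      # fully agonised


def simulate_reporter_curve(
    ligand: LigandGroundTruth,
    concentrations: Sequence[float],
    noise_cv: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Transcriptional reporter dose-response: activity falls as f_rep rises."""
    x = np.asarray(list(concentrations), dtype=float)
    if x.size == 0 or np.any(x <= 0):
        raise ValueError("concentrations must be positive and non-empty")
    top = REPORTER_BOTTOM + (REPORTER_TOP - REPORTER_BOTTOM) * (1.0 - ligand.f_rep)
    bottom = 1.0  # DMSO-normalised baseline
    ec50 = 10.0 ** ligand.potency_log10_M
    y = bottom + (top - bottom) / (1.0 + ec50 / x)
    if noise_cv > 0:
        rng = _rng(ligand.seed if seed is None else seed, "reporter")
        y = y * (1.0 + rng.normal(0.0, noise_cv, size=y.shape))
    return pd.DataFrame({
        "ligand_id": ligand.ligand_id, "peptide": "reporter", "x_value": x,
        "x_units": "M", "response": y, "replicate": 1,
    })


# ---------------------------------------------------------------------------
# qPCR expression

CT_HOUSEKEEPING = 20.0
DELTA_CT_CALIBRATOR = 5.0
TARGET_GENE = "aP2"
HOUSEKEEPING_GENE = "TBP"
CALIBRATOR = "DMSO"


def true_log2_rq(f_rep: float) -> float:
    """Latent target-gene induction: log2 RQ = 2 - 4*f_rep (agonists induce,
    inverse agonists repress relative to the vehicle calibrator)."""
    return 2.0 - 4.0 * f_rep


def simulate_expression(
    ligand: LigandGroundTruth,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Ct table (condition, gene, replicate, ct) for the ligand plus the
    vehicle calibrator, constructed so that 2^-ddCt recovers the latent RQ."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ddct = -true_log2_rq(ligand.f_rep)
    rng = _rng(ligand.seed if seed is None else seed, "qpcr")
    rows = []
    for condition, delta in ((CALIBRATOR, 0.0), (ligand.ligand_id, ddct)):
        for rep in range(1, n_replicates + 1):
            ct_hk = CT_HOUSEKEEPING + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0)
            ct_tg = (CT_HOUSEKEEPING + DELTA_CT_CALIBRATOR + delta
                     + (rng.normal(0, noise_sd) if noise_sd > 0 else 0.0))
            rows.append({"condition": condition, "gene": HOUSEKEEPING_GENE,
                         "replicate": rep, "ct": ct_hk})
            rows.append({"condition": condition, "gene": TARGET_GENE,
                         "replicate": rep, "ct": ct_tg})
    return pd.DataFrame(rows)


__all__ = [
    "LigandGroundTruth", "ResidueStateShifts", "GridSpec", "GLY399",
    "GLY284_DECOY", "make_ligand_series", "ground_truth_frame",
    "simulate_spectrum", "true_peak_volumes", "simulate_trfret_curve",
    "trfret_true_params", "simulate_fp_curve", "default_kd_link",
    "simulate_reporter_curve", "simulate_expression", "true_log2_rq",
]
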