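"""Per-residue conformational-ensemble quantification from peak volumes.

Each analysis residue shows one or two slow-exchange peaks per ligand.  Peak
volumes estimate relative state populations, and the population-weighted 1H
chemical shift

    delta_bar = sum_i V_i * delta_H_i / sum_i V_i

summarises where the ensemble sits between the repressive- and active-state
anchor positions.  Peaks are labelled repressive- or active-like by chemical
shift proximity to the anchors.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spectra import ALPHA_N_GLYCINE, FittedPeak, csp

REP = "rep-like"
ACT = "act-like"

# Below this fraction of the total volume a putative second state is treated
# as noise and the observation reduced to one state.
MIN_STATE_VOLUME_FRACTION = 0.02


@dataclass(frozen=True)
class Anchors:
    """Reference (1H, 15N) peak positions of the two conformational states."""

    rep: tuple[float, float]
    act: tuple[float, float]
    alpha_N: float = ALPHA_N_GLYCINE

    def __post_init__(self) -> None:
        if self.rep == self.act:
            raise ValueError("repressive and active anchors must be distinct")


@dataclass
class PeakObs:
    state: str  # REP, ACT, or "unlabeled"
    delta_H: float
    delta_N: float
    volume: float


@dataclass
class EnsembleObservation:
    ligand_id: str
    residue_id: str
    peaks: list[PeakObs]

    @property
    def n_states(self) -> int:
        return len(self.peaks)


@dataclass
class EnsembleSummary:
    ligand_id: str
    residue_id: str
    weighted_shift_H: float
    p_rep: float
    qc_flags: list[str] = field(default_factory=list)


def weighted_shift(peaks: Sequence[tuple[float, float]]) -> float:
    """Population-weighted mean 1H shift: sum(V * delta_H) / sum(V)."""
    if len(peaks) == 0:
        raise ValueError("at least one peak required")
    deltas = np.array([p[0] for p in peaks], dtype=float)
    vols = np.array([p[1] for p in peaks], dtype=float)
    if vols.sum() <= 0:
        raise ValueError("total peak volume must be positive")
    return float(np.average(deltas, weights=vols))


def state_populations(peaks: Sequence[PeakObs]) -> tuple[float, float]:
    """(p_rep, p_act) from labelled peak volumes, normalised to 1."""
    if any(p.state not in (REP, ACT) for p in peaks):
        raise ValueError("unlabeled peaks: call label_states first")
    v_rep = sum(p.volume for p in peaks if p.state == REP)
    v_act = sum(p.volume for p in peaks if p.state == ACT)
    total = v_rep + v_act
    if total <= 0:
        raise ValueError("total peak volume must be positive")
    return v_rep / total, v_act / total


def label_states(obs: EnsembleObservation, anchors: Anchors) -> EnsembleObservation:
    """Label peaks repressive- or active-like by anchor proximity.

    Two peaks receive distinct labels via the assignment minimising total
    CSP distance to the anchors.  A single peak is projected onto the
    rep-act axis and labelled by the nearest endpoint; at the exact midpoint
    the tie breaks to repressive-like.
    """
    a = anchors
    pos = [(p.delta_H, p.delta_N) for p in obs.peaks]
    labels: list[str]
    if len(pos) == 1:
        d_rep = csp(a.rep, pos[0], a.alpha_N)
        d_act = csp(a.act, pos[0], a.alpha_N)
        labels = [REP if d_rep <= d_act else ACT]
    else:
        anchor_list = [(REP, a.rep), (ACT, a.act)]
        best = None
        # exhaustive over label assignments; at most 2 anchors so cheap
        for perm in itertools.permutations(range(len(anchor_list)), len(pos)) \
                if len(pos) <= 2 else [None]:
            if perm is None:
                break
            total = sum(
                csp(anchor_list[ai][1], pos[pi], a.alpha_N)
                for pi, ai in enumerate(perm)
            )
            if best is None or total < best[0]:
                best = (total, perm)
        if best is not None:
            labels = [anchor_list[ai][0] for ai in best[1]]
        else:  # > 2 peaks: nearest anchor each (flagged upstream)
            labels = [
                REP if csp(a.rep, p, a.alpha_N) <= csp(a.act, p, a.alpha_N) else ACT
                for p in pos
            ]
    new_peaks = [
        PeakObs(lab, p.delta_H, p.delta_N, p.volume)
        for lab, p in zip(labels, obs.peaks)
    ]
    return EnsembleObservation(obs.ligand_id, obs.residue_id, new_peaks)


def summarize_observation(
    obs: EnsembleObservation,
    anchors: Anchors,
    min_volume_fraction: float = MIN_STATE_VOLUME_FRACTION,
) -> EnsembleSummary:
    """delta_bar and p_rep for one ligand/residue observation."""
    flags: list[str] = []
    peaks = [p for p in obs.peaks if p.volume > 0]
    if not peaks:
        return EnsembleSummary(obs.ligand_id, obs.residue_id, math.nan, math.nan,
                               ["no_peaks"])
    if len(peaks) > 2:
        flags.append("more_than_two_states")
    total = sum(p.volume for p in peaks)
    major = [p for p in peaks if p.volume / total >= min_volume_fraction]
    if len(major) < len(peaks):
        flags.append("minor_state_dropped")
    labelled = label_states(
        EnsembleObservation(obs.ligand_id, obs.residue_id, major), anchors
    )
    p_rep, _ = state_populations(labelled.peaks)
    dbar = weighted_shift([(p.delta_H, p.volume) for p in labelled.peaks])
    return EnsembleSummary(obs.ligand_id, obs.residue_id, dbar, p_rep, flags)


def observation_from_peaks(
    ligand_id: str,
    residue_id: str,
    peaks: Sequence[FittedPeak],
    anchors: Anchors,
    capture_csp: float = 0.3,
) -> EnsembleObservation | None:
    """Select the fitted peaks belonging to a residue's rep/act region.

    Peaks within ``capture_csp`` (scaled ppm) of either anchor are kept; the
    closest peak per anchor wins if several compete.  Returns None when no
    peak falls in the capture region.
    """
    kept: list[tuple[float, FittedPeak]] = []
    for p in peaks:
        d = min(
            csp(anchors.rep, (p.center_H, p.center_N), anchors.alpha_N),
            csp(anchors.act, (p.center_H, p.center_N), anchors.alpha_N),
        )
        if d <= capture_csp:
            kept.append((d, p))
    if not kept:
        return None
    kept.sort(key=lambda t: t[0])
    obs_peaks = [
        PeakObs("unlabeled", p.center_H, p.center_N, p.volume)
        for _, p in kept[:2]
    ]
    return EnsembleObservation(ligand_id, residue_id, obs_peaks)


def ensemble_table(
    peaks_by_ligand: Mapping[str, Sequence[FittedPeak]],
    residue_id: str,
    anchors: Anchors,
    min_volume_fraction: float = MIN_STATE_VOLUME_FRACTION,
    capture_csp: float = 0.3,
) -> pd.DataFrame:
    """One row per ligand: delta_bar_H, p_rep, QC flags.

    Ligands whose peak list lacks the residue get a row of missing values
    with a flag rather than an exception, so downstream correlations can
    apply pairwise deletion.
    """
    rows = []
    for ligand_id, peaks in peaks_by_ligand.items():
        flags: list[str] = []
        usable = []
        for p in peaks:
            if not p.converged:
                flags.append("unconverged_peak_skipped")
                continue
            usable.append(p)
        obs = observation_from_peaks(ligand_id, residue_id, usable, anchors,
                                     capture_csp)
        if obs is None:
            rows.append({"ligand_id": ligand_id, "residue_id": residue_id,
                         "delta_bar_H_ppm": np.nan, "p_rep": np.nan,
                         "flags": ";".join(flags + ["residue_missing"])})
            continue
        summary = summarize_observation(obs, anchors, min_volume_fraction)
        rows.append({"ligand_id": ligand_id, "residue_id": residue_id,
                     "delta_bar_H_ppm": summary.weighted_shift_H,
                     "p_rep": summary.p_rep,
                     "flags": ";".join(flags + summary.qc_flags)})
    return pd.DataFrame(rows)
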