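"""Assay-model fits: dose-response, saturation binding, coregulator bias, ddCt.

Conventions follow standard plate-pharmacology practice: the "three-parameter
sigmoidal" dose-response (Hill slope fixed at 1),

    y = bottom + (top - bottom) / (1 + EC50 / x),

the one-site total-binding hyperbola with a fixed, shared Bmax,

    Y = Bmax * X / (Kd + X) + background,

a coregulator bias factor defined as the NCoR1 value minus the MED1 value,
and comparative-Ct relative expression RQ = 2^(-ddCt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lmfit import Parameters, minimize


@dataclass
class DoseResponseFit:
    bottom: float
    top: float
    log_ec50: float  # log10 molar
    se: dict = field(default_factory=dict)
    converged: bool = True
    ligand_id: str | None = None
    readout: str | None = None

    @property
    def ec50(self) -> float:
        return 10.0 ** self.log_ec50

    @property
    def efficacy_window(self) -> float:
        return self.top - self.bottom


@dataclass
class SaturationFit:
    kd: float  # molar
    bmax: float  # fixed, shared across the analysis set
    background: float
    se_kd: float | None = None
    converged: bool = True
    ligand_id: str | None = None
    peptide: str | None = None

    @property
    def pkd(self) -> float:
        return -math.log10(self.kd)


@dataclass
class BiasValue:
    ncor1_value: float
    med1_value: float
    bias: float
    scale: str
    ligand_id: str | None = None
    assay: str | None = None


@dataclass
class RelativeExpression:
    condition: str
    delta_delta_ct: float
    rq: float
    rq_lower: float
    rq_upper: float


def _sigmoid(x, bottom, top, ec50):
    return bottom + (top - bottom) / (1.0 + ec50 / x)


def fit_dose_response(
    concentrations,
    responses,
    direction_hint: str | None = None,
) -> DoseResponseFit:
    """Three-parameter sigmoid fit (Hill slope 1) with self-starting values.

    EC50 is bounded to [min(x)/100, 100*max(x)].  Flat data (response range
    indistinguishable from zero) returns converged=False with
    bottom = top = mean.  ``direction_hint`` ("up"/"down") only seeds the
    initial top/bottom assignment.
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if np.unique(x).size < 4:
        raise ValueError("at least 4 distinct concentrations required")
    if np.any(x <= 0):
        raise ValueError("concentrations must be positive")
    span = float(y.max() - y.min())
    scale = max(abs(y).max(), 1e-300)
    if span <= 1e-9 * scale:
        m = float(y.mean())
        return DoseResponseFit(m, m, math.log10(float(np.sqrt(x.min() * x.max()))),
                               converged=False)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    low_end, high_end = float(np.mean(ys[:2])), float(np.mean(ys[-2:]))
    if direction_hint == "up":
        low_end, high_end = min(low_end, high_end), max(low_end, high_end)
    elif direction_hint == "down":
        low_end, high_end = max(low_end, high_end), min(low_end, high_end)
    mid = 0.5 * (low_end + high_end)
    ec50_0 = float(xs[np.argmin(np.abs(ys - mid))])
    ec50_0 = min(max(ec50_0, x.min() / 100), x.max() * 100)

    params = Parameters()
    params.add("bottom", value=low_end)
    params.add("top", value=high_end)
    params.add("log_ec50", value=math.log10(ec50_0),
               min=math.log10(x.min() / 100), max=math.log10(x.max() * 100))

    def residual(p):
        return _sigmoid(x, p["bottom"].value, p["top"].value,
                        10.0 ** p["log_ec50"].value) - y

    out = minimize(residual, params, method="least_squares")
    p = out.params
    se = {k: (p[k].stderr if p[k].stderr is not None else math.nan)
          for k in ("bottom", "top", "log_ec50")}
    return DoseResponseFit(float(p["bottom"].value), float(p["top"].value),
                           float(p["log_ec50"].value), se=se,
                           converged=bool(out.success))


def efficacy_at(fit: DoseResponseFit, concentration: float) -> float:
    """Model response at a concentration (0 -> bottom, inf -> top)."""
    if concentration == 0:
        return fit.bottom
    if math.isinf(concentration):
        return fit.top
    return float(_sigmoid(concentration, fit.bottom, fit.top, fit.ec50))


def _hyperbola(x, bmax, kd, background):
    return bmax * x / (kd + x) + background


def fit_saturation(concentrations, signals, bmax_fixed: float) -> SaturationFit:
    """One-site total-binding fit with Bmax held fixed; Kd and background free."""
    if bmax_fixed <= 0:
        raise ValueError("Bmax must be positive")
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(signals, dtype=float)
    if np.unique(x).size < 4:
        raise ValueError("at least 4 distinct concentrations required")
    if not np.any(y != 0):
        return SaturationFit(math.nan, bmax_fixed, 0.0, converged=False)
    params = Parameters()
    half = y.min() + 0.5 * (y.max() - y.min())
    kd0 = float(x[np.argmin(np.abs(y - half))])
    params.add("log_kd", value=math.log10(max(kd0, x.min() / 10)),
               min=math.log10(x.min()) - 4, max=math.log10(x.max()) + 4)
    params.add("background", value=float(y.min()))

    def residual(p):
        return _hyperbola(x, bmax_fixed, 10.0 ** p["log_kd"].value,
                          p["background"].value) - y

    out = minimize(residual, params, method="least_squares")
    kd = 10.0 ** out.params["log_kd"].value
    se_log = out.params["log_kd"].stderr
    se_kd = kd * math.log(10) * se_log if se_log is not None else None
    return SaturationFit(float(kd), bmax_fixed,
                         float(out.params["background"].value),
                         se_kd=se_kd, converged=bool(out.success))


def estimate_shared_bmax(tables) -> float:
    """Shared Bmax from a joint fit of the high-affinity (saturating) curves.

    ``tables`` is a sequence of (concentrations, signals).  A table qualifies
    when its maximum concentration is at least 5x its apparent Kd from an
    individual free-Bmax fit; non-saturating curves cannot pin Bmax down.
    """
    qualifying = []
    for x, y in tables:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        params = Parameters()
        params.add("bmax", value=float(y.max() - y.min()) or 1.0, min=1e-12)
        params.add("log_kd", value=math.log10(float(np.median(x))),
                   min=math.log10(x.min()) - 4, max=math.log10(x.max()) + 4)
        params.add("background", value=float(y.min()))
        out = minimize(
            lambda p: _hyperbola(x, p["bmax"].value, 10.0 ** p["log_kd"].value,
                                 p["background"].value) - y,
            params, method="least_squares",
        )
        kd_app = 10.0 ** out.params["log_kd"].value
        if x.max() >= 5.0 * kd_app:
            qualifying.append((x, y))
    if not qualifying:
        raise ValueError(
            "no saturating curve available to determine Bmax; "
            "supply an explicit Bmax"
        )
    params = Parameters()
    y0 = qualifying[0][1]
    params.add("bmax", value=float(y0.max() - y0.min()) or 1.0, min=1e-12)
    for i, (x, y) in enumerate(qualifying):
        params.add(f"log_kd_{i}", value=math.log10(float(np.median(x))),
                   min=math.log10(x.min()) - 4, max=math.log10(x.max()) + 4)
        params.add(f"background_{i}", value=float(y.min()))

    def residual(p):
        res = [
            _hyperbola(x, p["bmax"].value, 10.0 ** p[f"log_kd_{i}"].value,
                       p[f"background_{i}"].value) - y
            for i, (x, y) in enumerate(qualifying)
        ]
        return np.concatenate(res)

    out = minimize(residual, params, method="least_squares")
    return float(out.params["bmax"].value)


def bias_factor(ncor1_value: float, med1_value: float,
                scale: str = "linear") -> BiasValue:
    """Coregulator bias: NCoR1 value minus MED1 value.

    ``scale="linear"`` differences the raw values (TR-FRET efficacies);
    ``scale="log-affinity"`` treats inputs as Kd in molar and differences
    pKd = -log10(Kd), so tighter NCoR1 binding gives positive bias.
    """
    if scale == "log-affinity":
        n, m = -math.log10(ncor1_value), -math.log10(med1_value)
    elif scale == "linear":
        n, m = float(ncor1_value), float(med1_value)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    return BiasValue(n, m, n - m, scale)


def relative_expression(
    ct_table: pd.DataFrame,
    target_gene: str,
    housekeeping_gene: str,
    calibrator: str,
) -> list[RelativeExpression]:
    """Comparative-Ct quantification per condition.

    dCt = Ct_target - Ct_housekeeping (replicate-paired means); ddCt relative
    to the calibrator condition; RQ = 2^(-ddCt) with upper/lower limits from
    RQ at ddCt -/+ sd(dCt).
    """
    results = []
    by_cond = {}
    for cond, grp in ct_table.groupby("condition", sort=False):
        for gene in (target_gene, housekeeping_gene):
            if not (grp["gene"] == gene).any():
                raise ValueError(f"condition {cond!r} lacks Ct values for gene {gene!r}")
        tg = grp[grp["gene"] == target_gene].set_index("replicate")["ct"]
        hk = grp[grp["gene"] == housekeeping_gene].set_index("replicate")["ct"]
        dct = (tg - hk).dropna()
        by_cond[cond] = (float(dct.mean()), float(dct.std(ddof=1)) if len(dct) > 1 else 0.0)
    if calibrator not in by_cond:
        raise ValueError(f"calibrator condition {calibrator!r} absent from table")
    dct_cal = by_cond[calibrator][0]
    for cond, (dct, sd) in by_cond.items():
        ddct = dct - dct_cal
        results.append(RelativeExpression(
            condition=cond,
            delta_delta_ct=ddct,
            rq=2.0 ** (-ddct),
            rq_upper=2.0 ** (-(ddct - sd)),
            rq_lower=2.0 ** (-(ddct + sd)),
        ))
    return results
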