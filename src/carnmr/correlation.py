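"""Conformation-activity-relationship (CAR) correlation analysis.

Spearman rank correlations with two-sided p-values relate the
population-weighted NMR shift to the functional ligand-profiling columns.
The two-sided p follows the convention that p is the probability that
|s| of an uncorrelated (x, y) draw is at least the observed |s|: for small n
this is evaluated by full permutation enumeration; otherwise by the
t-approximation with n - 2 degrees of freedom.  No multiple-comparison
adjustment is applied; per-pair sample sizes are reported instead.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

EXACT_MAX_N_DEFAULT = 9

CAR_COLUMNS = [
    "weighted_shift_H", "ncor1_efficacy", "med1_efficacy",
    "ncor1_affinity", "med1_affinity", "trfret_bias", "fp_bias",
    "reporter_activity", "rq_expression",
]


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    s: float
    p_two_sided: float
    n_used: int
    method: str  # "exact permutation" or "t-approximation"
    p_t_approx: float = math.nan
    flags: list[str] = field(default_factory=list)


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float((rx**2).sum() * (ry**2).sum()))
    if denom == 0:
        return math.nan
    return float((rx * ry).sum() / denom)


def _t_approx_p(s: float, n: int) -> float:
    if abs(s) >= 1.0:
        return 0.0
    t = s * math.sqrt((n - 2) / (1.0 - s * s))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def _pairwise_complete(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    return x[mask], y[mask]


def exact_permutation_p(x, y, max_n: int = EXACT_MAX_N_DEFAULT) -> float:
    """Two-sided permutation p: fraction of all n! orderings of y whose
    |Spearman s| meets or exceeds the observed |s|."""
    x, y = _pairwise_complete(x, y)
    n = x.size
    if n > max_n:
        raise ValueError(
            f"n = {n} exceeds max_n = {max_n}; use monte_carlo_permutation_p"
        )
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    s_obs = _rank_corr(rx, ry)
    if math.isnan(s_obs):
        return math.nan
    perms = np.array(list(itertools.permutations(ry)))
    rxc = rx - rx.mean()
    pc = perms - perms.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc**2).sum() * (pc**2).sum(axis=1))
    s_perm = (pc @ rxc) / denom
    return float(np.mean(np.abs(s_perm) >= abs(s_obs) - 1e-12))


def monte_carlo_permutation_p(x, y, n_draws: int = 100_000, seed: int = 0) -> float:
    """Seeded Monte-Carlo version of the permutation p for larger n."""
    x, y = _pairwise_complete(x, y)
    rng = np.random.default_rng(seed)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    s_obs = _rank_corr(rx, ry)
    count = 0
    for _ in range(n_draws):
        count += abs(_rank_corr(rx, rng.permutation(ry))) >= abs(s_obs) - 1e-12
    return (count + 1) / (n_draws + 1)


def spearman(x, y, pair: tuple[str, str] = ("x", "y"),
             exact_max_n: int = EXACT_MAX_N_DEFAULT) -> CorrelationResult:
    """Spearman correlation with a two-sided p-value.

    Average ranks for ties; s is the Pearson correlation of the ranks.  The
    reported p is the exact permutation p when n <= exact_max_n (labelled so)
    and the t-approximation otherwise; the t-approximation is always carried
    alongside.  Constant inputs yield a flagged NaN result.
    """
    xc, yc = _pairwise_complete(x, y)
    n = xc.size
    if n < 3:
        raise ValueError("at least 3 complete pairs required")
    rx = stats.rankdata(xc)
    ry = stats.rankdata(yc)
    s = _rank_corr(rx, ry)
    if math.isnan(s):
        return CorrelationResult(pair, math.nan, math.nan, n, "undefined",
                                 flags=["constant_input"])
    p_t = _t_approx_p(s, n)
    if n <= exact_max_n:
        p = exact_permutation_p(xc, yc, max_n=exact_max_n)
        method = "exact permutation"
    else:
        p = p_t
        method = "t-approximation"
    return CorrelationResult(pair, s, p, n, method, p_t_approx=p_t)


@dataclass
class CorrelationMatrix:
    s: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    long: pd.DataFrame


def correlation_matrix(table: pd.DataFrame,
                       exact_max_n: int = EXACT_MAX_N_DEFAULT) -> CorrelationMatrix:
    """All pairwise Spearman results over pairwise-complete observations.

    The diagonal is 1; the matrix is symmetric; each cell reports its own
    n.  Columns without any complete pair against a partner are flagged NaN
    there without affecting other cells.
    """
    cols = [c for c in table.columns if table[c].dtype.kind in "fiu"]
    if len(cols) < 2:
        raise ValueError("at least 2 numeric columns required")
    s = pd.DataFrame(np.full((len(cols), len(cols)), math.nan),
                     index=cols, columns=cols)
    np.fill_diagonal(s.values, 1.0)
    p = pd.DataFrame(np.full((len(cols), len(cols)), math.nan), index=cols, columns=cols)
    nmat = pd.DataFrame(0, index=cols, columns=cols)
    rows = []
    for i, a in enumerate(cols):
        nmat.loc[a, a] = int(np.isfinite(table[a].astype(float)).sum())
        for b in cols[i + 1:]:
            xc, yc = _pairwise_complete(table[a], table[b])
            if xc.size < 3:
                rows.append({"pair_a": a, "pair_b": b, "s": math.nan,
                             "p": math.nan, "n": int(xc.size),
                             "method": "insufficient_pairs"})
                continue
            res = spearman(xc, yc, pair=(a, b), exact_max_n=exact_max_n)
            s.loc[a, b] = s.loc[b, a] = res.s
            p.loc[a, b] = p.loc[b, a] = res.p_two_sided
            nmat.loc[a, b] = nmat.loc[b, a] = res.n_used
            rows.append({"pair_a": a, "pair_b": b, "s": res.s,
                         "p": res.p_two_sided, "n": res.n_used,
                         "method": res.method})
    return CorrelationMatrix(s, p, nmat, pd.DataFrame(rows))


def rank_ligands(table: pd.DataFrame, by: str,
                 ligand_col: str = "ligand_id") -> list[str]:
    """Ligands ordered by descending efficacy in the given column; ties break
    by ligand id (stable)."""
    if by not in table.columns:
        raise KeyError(f"column {by!r} not in table")
    df = table.sort_values([by, ligand_col], ascending=[False, True],
                           kind="stable")
    return list(df[ligand_col])
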