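"""Univariate feature statistics for two-group peak tables.

Per feature: a Mann-Whitney U test (exact by enumeration for small,
tie-free samples; normal approximation with tie and continuity correction
otherwise), group-mean fold change on the untransformed scale, a Welch t
statistic used purely as a signed ranking score for enrichment analysis,
Benjamini-Hochberg FDR across features, and the joint significance rule
(fold change > 2 or < 0.5, FDR <= 0.05).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .peaktable import PeakTable

__all__ = [
    "mann_whitney_u",
    "fold_change",
    "bh_fdr",
    "t_score",
    "select_significant",
    "compute_feature_stats",
]

_EXACT_LIMIT = 12  # enumerate all label assignments when n + m <= this and no ties


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U = #{(i,j): x_i > y_j} + 0.5 * #{ties}."""
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact p by full enumeration of label assignments when the pooled sample
    has at most 12 observations and no ties; otherwise the normal
    approximation with tie correction and continuity correction. Two-sided
    extremity is measured as distance of U from its null mean nm/2.

    Returns
    -------
    (U, p) where U is computed for ``x`` against ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    n, m = x.size, y.size
    u_obs = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    center = n * m / 2.0
    if n + m <= _EXACT_LIMIT and not has_ties:
        # enumerate every way of labelling n of the pooled values as group x
        dist = [
            _u_statistic(pooled[list(comb)],
                         pooled[[i for i in range(n + m) if i not in comb]])
            for comb in itertools.combinations(range(n + m), n)
        ]
        obs_dev = abs(u_obs - center)
        p = sum(abs(u - center) >= obs_dev - 1e-12 for u in dist) / len(dist)
        return u_obs, float(p)
    # normal approximation with tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var = n * m / 12.0 * ((n + m + 1) - tie_term / ((n + m) * (n + m - 1)))
    if var <= 0:
        return u_obs, 1.0  # all values identical
    z = (abs(u_obs - center) - 0.5) / math.sqrt(var)  # continuity correction
    z = max(z, 0.0)
    return u_obs, float(2.0 * sps.norm.sf(z))


def fold_change(x, y) -> float:
    """mean(x) / mean(y) on untransformed intensities; both means must be positive."""
    mx, my = float(np.mean(x)), float(np.mean(y))
    if mx <= 0 or my <= 0:
        raise ValueError(f"fold change needs positive group means, got {mx}, {my}")
    return mx / my


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def t_score(x, y) -> float:
    """Welch t statistic of x vs y: a signed ranking score (positive = x higher)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both groups have zero variance; t score undefined")
    se = math.sqrt(vx / x.size + vy / y.size)
    return float((x.mean() - y.mean()) / se)


def select_significant(
    stats: pd.DataFrame,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    fdr_cut: float = 0.05,
    mode: str = "fdr_fc",
    p_cut: float = 0.05,
) -> pd.DataFrame:
    """Flag significant features.

    ``mode="fdr_fc"`` (default): fold change > fc_up or < fc_down AND
    FDR <= fdr_cut — the joint volcano rule. ``mode="raw_p"``: raw
    p <= p_cut, the convention feeding the over-representation analysis.
    """
    out = stats.copy()
    if mode == "fdr_fc":
        fc_gate = (out["fold_change"] > fc_up) | (out["fold_change"] < fc_down)
        out["significant"] = fc_gate & (out["fdr"] <= fdr_cut)
    elif mode == "raw_p":
        out["significant"] = out["p_value"] <= p_cut
    else:
        raise ValueError(f"unknown significance mode {mode!r}")
    return out


def compute_feature_stats(pt: PeakTable, **select_kwargs) -> pd.DataFrame:
    """Per-feature statistics of a two-group peak table (untransformed scale).

    Returns a DataFrame with columns mz, rt, p_value, t_score, fold_change,
    fdr, significant — the ranked-feature input of the pathway methods.
    """
    ga, gb = pt.require_two_groups()
    ca, cb = pt.group_columns(ga), pt.group_columns(gb)
    X = pt.intensities
    records = []
    for i in range(pt.n_features):
        x, y = X[i, ca], X[i, cb]
        x = x[~np.isnan(x)]
        y = y[~np.isnan(y)]
        _, p = mann_whitney_u(x, y)
        records.append({
            "mz": pt.mz[i],
            "rt": pt.rt[i],
            "p_value": p,
            "t_score": t_score(x, y),
            "fold_change": fold_change(x, y),
        })
    df = pd.DataFrame(records)
    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    return select_significant(df, **select_kwargs)
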