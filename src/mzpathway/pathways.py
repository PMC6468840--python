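"""Pathway-activity prediction from ranked m/z features.

Two complementary routes from the same feature -> compound match table:

* **Over-representation analysis (ORA)** in the mummichog style: compounds
  tentatively annotated from features passing a raw-p cutoff form the
  "significant" set S; compounds annotated from any feature form the
  reference universe R. Each pathway P is scored by the hypergeometric
  right tail of |S ∩ P| given |R ∩ P| hits in a universe of size |R|, plus
  the conservative EASE variant (one observed hit removed). A resampling
  null — random feature subsets of size |significant features|, re-annotated
  and re-scored — calibrates the EASE statistic into an empirical p via a
  Gamma fit on -log(null p) (method of moments, pooled across pathways;
  empirical rank fallback when the fit degenerates).

* **Metabolite-set GSEA**: every matched compound receives the t score of
  its most extreme matched feature (max |t|, ties to the larger m/z), the
  compounds are ranked, and each pathway is scored by the weighted
  Kolmogorov-Smirnov running-sum enrichment score (weight exponent 1).
  Significance comes from permuting set membership among ranked compounds,
  sign-matched, with NES = ES / mean(|null ES| of the same sign) and BH-FDR
  across pathways. GSEA uses the whole ranking, so it can detect pathways
  whose compounds shift subtly but consistently — exactly the signals a
  cutoff-based ORA discards.

* **Integration**: the two p-values per pathway are combined with Fisher's
  method (chi-square with 4 df) and exported with -log10 coordinates for
  the standard two-method scatter plot.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .library import CompoundPathwayLibrary
from .matching import MatchTable
from .stats import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "mummichog_ora",
    "gsea_pathways",
    "integrate",
    "enrichment_score",
]


# ---------------------------------------------------------------------------
# ORA (mummichog style)
# ---------------------------------------------------------------------------

def _hypergeom_right_tail(k: int, M: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(universe M, K marked, N drawn)."""
    if k <= 0:
        return 1.0
    return float(sps.hypergeom.sf(k - 1, M, K, N))


def _pathway_ease(sig_compounds: set[str], universe_compounds: set[str],
                  pathway_ids: frozenset[str]) -> tuple[int, int, float, float]:
    hits_total = universe_compounds & pathway_ids
    hits_sig = sig_compounds & hits_total
    n_sig, n_total = len(hits_sig), len(hits_total)
    M, N = len(universe_compounds), len(sig_compounds)
    if n_total == 0:
        return 0, 0, 1.0, 1.0
    fisher = _hypergeom_right_tail(n_sig, M, n_total, N)
    ease = _hypergeom_right_tail(max(n_sig - 1, 0), M, n_total, N)
    return n_sig, n_total, fisher, ease


def mummichog_ora(
    stats: pd.DataFrame,
    matches: MatchTable,
    library: CompoundPathwayLibrary,
    p_cutoff: float = 0.05,
    n_perm: int = 100,
    seed: int = 0,
    calibration: str = "gamma",
) -> pd.DataFrame:
    """Pathway over-representation analysis from significant m/z features.

    Parameters
    ----------
    stats
        Feature statistics with a ``p_value`` column, row i describing the
        feature matched as index i in ``matches`` (the match table must be
        built from ALL features, not only significant ones).
    p_cutoff
        Raw per-feature p-value defining the significant feature list.
    n_perm
        Number of random same-size feature subsets for the resampling null.
    calibration
        "gamma" (default): empirical p = Gamma survival of -log(EASE p),
        Gamma fit by moments on the pooled null. "rank": per-pathway
        empirical rank (count + 1) / (n_perm + 1).

    Returns
    -------
    DataFrame with one row per pathway, sorted by ``empirical_p``:
    pathway_id, pathway_name, n_sig_compounds, n_total_hits, hits
    ("sig/total"), fisher_p, ease_p, empirical_p.
    """
    if calibration not in ("gamma", "rank"):
        raise ValueError(f"unknown calibration {calibration!r}")
    pvals = stats["p_value"].to_numpy()
    n_features = len(pvals)
    if matches.n_features != n_features:
        raise ValueError(
            f"match table covers {matches.n_features} features but stats has {n_features}"
        )
    sig_features = np.flatnonzero(pvals <= p_cutoff)
    sig_compounds = matches.compounds_for_features(sig_features)
    universe = matches.matched_compounds
    if not sig_compounds:
        raise ValueError("no significant compounds: nothing below the p-value cutoff matched")

    observed = {
        pw.id: _pathway_ease(sig_compounds, universe, pw.compound_ids)
        for pw in library.pathways
    }

    # resampling null: random feature subsets of the significant-list size
    rng = np.random.default_rng(seed)
    null_ease: dict[str, np.ndarray] = {pw.id: np.empty(n_perm) for pw in library.pathways}
    for b in range(n_perm):
        subset = rng.choice(n_features, size=len(sig_features), replace=False)
        s_b = matches.compounds_for_features(subset)
        for pw in library.pathways:
            null_ease[pw.id][b] = _pathway_ease(s_b, universe, pw.compound_ids)[3]

    pooled = -np.log(np.clip(np.concatenate(list(null_ease.values())), 1e-300, 1.0))
    gamma_params = None
    if calibration == "gamma":
        mu, var = float(pooled.mean()), float(pooled.var(ddof=1))
        if var > 1e-12 and mu > 0:
            gamma_params = (mu**2 / var, var / mu)  # shape, scale
        else:
            logger.warning("degenerate null for Gamma fit; falling back to rank calibration")

    rows = []
    for pw in library.pathways:
        n_sig, n_total, fisher, ease = observed[pw.id]
        if n_total == 0:
            emp = 1.0
        elif gamma_params is not None:
            shape, scale = gamma_params
            emp = float(sps.gamma.sf(-math.log(max(ease, 1e-300)), a=shape, scale=scale))
        else:
            emp = (float((null_ease[pw.id] <= ease).sum()) + 1.0) / (n_perm + 1.0)
        rows.append({
            "pathway_id": pw.id,
            "pathway_name": pw.name,
            "n_sig_compounds": n_sig,
            "n_total_hits": n_total,
            "hits": f"{n_sig}/{n_total}",
            "fisher_p": fisher,
            "ease_p": ease,
            "empirical_p": emp,
        })
    df = pd.DataFrame(rows)
    return df.sort_values("empirical_p", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# GSEA (weighted Kolmogorov-Smirnov on the ranked compound list)
# ---------------------------------------------------------------------------

def enrichment_score(scores: np.ndarray, hit_mask: np.ndarray) -> float:
    """Weighted KS enrichment score of a hit set within a ranked score list.

    ``scores`` must already be sorted in ranking order (descending). Hits
    advance the running sum by |score| / sum(|score| over hits); misses
    retreat by 1 / (N - Nh). The ES is the extremum of largest magnitude.
    """
    scores = np.asarray(scores, dtype=float)
    hit_mask = np.asarray(hit_mask, dtype=bool)
    N = scores.size
    nh = int(hit_mask.sum())
    if nh == 0 or nh == N:
        raise ValueError("hit set must be a non-empty strict subset of the ranked list")
    weights = np.abs(scores[hit_mask])
    total = weights.sum()
    steps = np.where(hit_mask, 0.0, -1.0 / (N - nh))
    if total > 0:
        steps[hit_mask] = np.abs(scores[hit_mask]) / total
    else:  # all hit scores zero: unweighted fallback
        steps[hit_mask] = 1.0 / nh
    running = np.cumsum(steps)
    hi, lo = float(running.max()), float(running.min())
    return hi if hi >= -lo else lo


def _compound_scores(stats: pd.DataFrame, matches: MatchTable) -> pd.DataFrame:
    """Collapse feature t scores to one score per matched compound.

    Each compound takes the t score of its matched feature with the largest
    |t|; ties break to the feature with the larger m/z (deterministic).
    """
    t = stats["t_score"].to_numpy()
    mz = stats["mz"].to_numpy()
    rows = []
    for cid in sorted(matches.compound_to_features):
        feats = matches.compound_to_features[cid]
        best = max(feats, key=lambda i: (abs(t[i]), mz[i]))
        rows.append({"compound_id": cid, "score": t[best],
                     "feature_index": best, "n_features": len(feats)})
    df = pd.DataFrame(rows)
    return df.sort_values("score", ascending=False, kind="stable").reset_index(drop=True)


def gsea_pathways(
    stats: pd.DataFrame,
    matches: MatchTable,
    library: CompoundPathwayLibrary,
    n_perm: int = 1000,
    seed: int = 0,
    min_hits: int = 2,
) -> pd.DataFrame:
    """Metabolite-set GSEA over the ranked matched-compound list.

    Returns a DataFrame per scored pathway: pathway_id, pathway_name,
    n_compound_hits, es, nes, p_value, fdr, sorted by p_value. Pathways
    with fewer than ``min_hits`` matched compounds are skipped (logged).
    """
    ranked = _compound_scores(stats, matches)
    if ranked.empty:
        raise ValueError("no compounds matched; cannot rank")
    scores = ranked["score"].to_numpy()
    compound_order = ranked["compound_id"].tolist()
    index_of = {cid: i for i, cid in enumerate(compound_order)}
    N = len(compound_order)
    rng = np.random.default_rng(seed)
    null_cache: dict[int, np.ndarray] = {}

    def null_es(nh: int) -> np.ndarray:
        if nh not in null_cache:
            out = np.empty(n_perm)
            mask = np.zeros(N, dtype=bool)
            for b in range(n_perm):
                idx = rng.choice(N, size=nh, replace=False)
                mask[:] = False
                mask[idx] = True
                out[b] = enrichment_score(scores, mask)
            null_cache[nh] = out
        return null_cache[nh]

    rows = []
    for pw in library.pathways:
        hit_idx = [index_of[c] for c in pw.compound_ids if c in index_of]
        nh = len(hit_idx)
        if nh < min_hits:
            logger.info("GSEA: pathway %s has %d matched compounds (< %d); skipped",
                        pw.id, nh, min_hits)
            continue
        if nh == N:
            logger.info("GSEA: pathway %s covers the whole ranked list; skipped", pw.id)
            continue
        mask = np.zeros(N, dtype=bool)
        mask[hit_idx] = True
        es = enrichment_score(scores, mask)
        null = null_es(nh)
        if es > 0:
            same = null[null > 0]
            extreme = int((same >= es).sum())
        elif es < 0:
            same = null[null < 0]
            extreme = int((same <= es).sum())
        else:
            same = np.empty(0)
            extreme = 0
        p = (extreme + 1.0) / (same.size + 1.0)
        nes = es / float(np.abs(same).mean()) if same.size else 0.0
        rows.append({
            "pathway_id": pw.id,
            "pathway_name": pw.name,
            "n_compound_hits": nh,
            "es": es,
            "nes": nes,
            "p_value": p,
        })
    if not rows:
        raise ValueError("no pathway had enough matched compounds for GSEA")
    df = pd.DataFrame(rows)
    df["fdr"] = bh_fdr(df["p_value"].to_numpy())
    return df.sort_values("p_value", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Integration of the two methods
# ---------------------------------------------------------------------------

def integrate(
    ora: pd.DataFrame,
    gsea: pd.DataFrame,
    p_floor: float | None = None,
) -> pd.DataFrame:
    """Combine ORA and GSEA pathway p-values with Fisher's method.

    For pathways scored by both methods, X2 = -2 (ln p_ora + ln p_gsea) is
    referred to a chi-square with 4 df. Pathways present in only one method
    carry that method's p as ``combined_p`` and are flagged. Exact zeros are
    clamped to ``p_floor`` (default 1/1001) with a warning, since a
    permutation p of 0 is an artefact, not evidence.

    The output carries ``x`` = -log10 p_gsea and ``y`` = -log10 p_ora, the
    coordinates of the two-method scatter plot.
    """
    floor = 1.0 / 1001.0 if p_floor is None else p_floor
    ora_p = dict(zip(ora["pathway_id"], ora["empirical_p"]))
    names = dict(zip(ora["pathway_id"], ora["pathway_name"]))
    gsea_p = dict(zip(gsea["pathway_id"], gsea["p_value"]))
    names.update(zip(gsea["pathway_id"], gsea["pathway_name"]))

    def clamp(p: float, pid: str, method: str) -> float:
        if p <= 0:
            logger.warning("%s p for pathway %s is %g; clamped to %g", method, pid, p, floor)
            return floor
        return min(p, 1.0)

    rows = []
    for pid in sorted(set(ora_p) | set(gsea_p)):
        pm = ora_p.get(pid)
        pg = gsea_p.get(pid)
        if pm is not None and pg is not None:
            pm_c = clamp(pm, pid, "ORA")
            pg_c = clamp(pg, pid, "GSEA")
            x2 = -2.0 * (math.log(pm_c) + math.log(pg_c))
            combined = float(sps.chi2.sf(x2, df=4))
            flagged = False
        else:
            only = pm if pm is not None else pg
            pm_c = clamp(pm, pid, "ORA") if pm is not None else None
            pg_c = clamp(pg, pid, "GSEA") if pg is not None else None
            combined = clamp(only, pid, "single-method")
            flagged = True
        rows.append({
            "pathway_id": pid,
            "pathway_name": names.get(pid, pid),
            "mummichog_p": pm_c,
            "gsea_p": pg_c,
            "combined_p": combined,
            "x": -math.log10(pg_c) if pg_c is not None else np.nan,
            "y": -math.log10(pm_c) if pm_c is not None else np.nan,
            "single_method": flagged,
        })
    df = pd.DataFrame(rows)
    return df.sort_values("combined_p", kind="stable").reset_index(drop=True)
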