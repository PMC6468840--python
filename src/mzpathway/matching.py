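"""Annotation of m/z features against a compound library under adduct rules.

Every (feature, compound, adduct) triple whose theoretical m/z lies within
the ppm tolerance of the observed m/z is kept — annotation from mass alone
is inherently ambiguous (isomers share a formula, isobars share a mass), so
no best-hit collapse happens here; downstream methods decide how to use the
many-to-many structure. The ppm error denominator is the theoretical m/z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import AdductRuleSet, CompoundPathwayLibrary

__all__ = ["MatchCandidate", "MatchTable", "match_features", "ambiguity_report"]


@dataclass(frozen=True)
class MatchCandidate:
    feature_index: int
    feature_mz: float
    compound_id: str
    adduct_label: str
    theoretical_mz: float
    ppm_error: float


@dataclass
class MatchTable:
    candidates: list[MatchCandidate]
    n_features: int
    feature_to_compounds: dict[int, list[str]] = field(init=False)
    compound_to_features: dict[str, list[int]] = field(init=False)

    def __post_init__(self) -> None:
        f2c: dict[int, list[str]] = {}
        c2f: dict[str, list[int]] = {}
        for c in self.candidates:
            f2c.setdefault(c.feature_index, [])
            if c.compound_id not in f2c[c.feature_index]:
                f2c[c.feature_index].append(c.compound_id)
            c2f.setdefault(c.compound_id, [])
            if c.feature_index not in c2f[c.compound_id]:
                c2f[c.compound_id].append(c.feature_index)
        self.feature_to_compounds = f2c
        self.compound_to_features = c2f

    @property
    def matched_compounds(self) -> set[str]:
        return set(self.compound_to_features)

    def compounds_for_features(self, feature_indices) -> set[str]:
        out: set[str] = set()
        for i in feature_indices:
            out.update(self.feature_to_compounds.get(int(i), ()))
        return out

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "feature_index": c.feature_index,
                    "feature_mz": c.feature_mz,
                    "compound_id": c.compound_id,
                    "adduct": c.adduct_label,
                    "theoretical_mz": c.theoretical_mz,
                    "ppm_error": c.ppm_error,
                }
                for c in self.candidates
            ],
            columns=["feature_index", "feature_mz", "compound_id", "adduct",
                     "theoretical_mz", "ppm_error"],
        )


def match_features(
    feature_mzs,
    library: CompoundPathwayLibrary,
    rules: AdductRuleSet,
    ion_mode: str,
) -> MatchTable:
    """Match observed m/z values to library compounds under the adduct rules.

    A candidate is emitted iff |observed - theoretical| / theoretical * 1e6
    is at most ``rules.ppm_tolerance``. Candidates are ordered by
    (feature index, compound id, adduct label) so the table serializes
    identically for identical inputs.
    """
    mode_rules = rules.for_mode(ion_mode)
    feature_mzs = np.asarray(feature_mzs, dtype=float)
    tol = rules.ppm_tolerance

    # theoretical m/z grid: one entry per (compound, adduct)
    entries = []  # (theoretical_mz, compound_id, adduct_label)
    for cid in sorted(library.compounds):
        mass = library.compounds[cid].monoisotopic_mass
        for rule in mode_rules:
            entries.append((rule.mz(mass), cid, rule.label))
    if not entries:
        return MatchTable([], n_features=len(feature_mzs))
    theo = np.array([e[0] for e in entries])
    order = np.argsort(theo)
    theo_sorted = theo[order]

    candidates: list[MatchCandidate] = []
    for fi, obs in enumerate(feature_mzs):
        # window of theoretical masses within tol ppm of obs (tol is small,
        # so a symmetric window in absolute Da, padded, then exact check)
        half = obs * tol * 1e-6 * 1.001
        lo = np.searchsorted(theo_sorted, obs - half, side="left")
        hi = np.searchsorted(theo_sorted, obs + half, side="right")
        hits = []
        for j in order[lo:hi]:
            t, cid, label = entries[j]
            ppm = (obs - t) / t * 1e6
            if abs(ppm) <= tol:
                hits.append(MatchCandidate(fi, float(obs), cid, label, t, float(ppm)))
        hits.sort(key=lambda c: (c.compound_id, c.adduct_label))
        candidates.extend(hits)
    return MatchTable(candidates, n_features=len(feature_mzs))


def ambiguity_report(mt: MatchTable) -> pd.DataFrame:
    """Per-feature candidate-compound counts; features with >= 2 are ambiguous."""
    rows = []
    for fi in range(mt.n_features):
        n = len(mt.feature_to_compounds.get(fi, ()))
        rows.append({"feature_index": fi, "n_candidates": n, "ambiguous": n >= 2})
    return pd.DataFrame(rows, columns=["feature_index", "n_candidates", "ambiguous"])
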