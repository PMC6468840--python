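"""Pathway scoring: exact oracles, degenerate cases, and integration math."""

import math
from math import comb

import numpy as np
import pandas as pd
import pytest

from mzpathway import (
    enrichment_score,
    gsea_pathways,
    integrate,
    match_features,
    mummichog_ora,
)
from mzpathway.library import Compound, CompoundPathwayLibrary, PathwaySet
from mzpathway.matching import MatchCandidate, MatchTable
from mzpathway.pathways import _hypergeom_right_tail


def hypergeom_tail_oracle(k, M, K, N):
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    if k <= 0:
        return 1.0
    total = comb(M, N)
    acc = 0
    for j in range(k, min(K, N) + 1):
        if N - j <= M - K:
            acc += comb(K, j) * comb(M - K, N - j)
    return acc / total


def es_walk_oracle(scores, hit_mask):
    """Brute-force running-sum walk with explicit bookkeeping."""
    scores = list(scores)
    hits = list(hit_mask)
    nr = sum(abs(s) for s, h in zip(scores, hits) if h)
    n_miss = len(scores) - sum(hits)
    running = 0.0
    best = 0.0
    for s, h in zip(scores, hits):
        if h:
            running += abs(s) / nr if nr > 0 else 1.0 / sum(hits)
        else:
            running -= 1.0 / n_miss
        if abs(running) > abs(best) or (abs(running) == abs(best) and running > best):
            best = running
    return best


def _match_table_from_map(feature_compounds, n_features):
    cands = [
        MatchCandidate(fi, 100.0 + fi, cid, "[M-H]-", 100.0 + fi, 0.0)
        for fi, cids in feature_compounds.items()
        for cid in cids
    ]
    return MatchTable(cands, n_features=n_features)


def _library_with(pathways, compound_ids):
    cpds = {cid: Compound(cid, cid, "C2H4O2", 60.02113) for cid in compound_ids}
    return CompoundPathwayLibrary(
        name="t", compounds=cpds,
        pathways=[PathwaySet(pid, pid, frozenset(ids)) for pid, ids in pathways],
    )


class TestHypergeomTails:
    def test_worked_example_universe_50(self):
        """Universe 50 compounds, 10 drawn significant, pathway of 5 with 3
        significant: Fisher tail ~0.0483, EASE tail ~0.258."""
        fisher = _hypergeom_right_tail(3, 50, 5, 10)
        ease = _hypergeom_right_tail(2, 50, 5, 10)
        assert fisher == pytest.approx(hypergeom_tail_oracle(3, 50, 5, 10), abs=1e-12)
        assert ease == pytest.approx(hypergeom_tail_oracle(2, 50, 5, 10), abs=1e-12)
        assert fisher == pytest.approx(0.0483, abs=5e-4)
        assert ease == pytest.approx(0.258, abs=1e-3)

    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            M = int(rng.integers(5, 61))
            K = int(rng.integers(1, M + 1))
            N = int(rng.integers(1, M + 1))
            k = int(rng.integers(0, min(K, N) + 1))
            assert _hypergeom_right_tail(k, M, K, N) == pytest.approx(
                hypergeom_tail_oracle(k, M, K, N), abs=1e-12
            )


class TestMummichogOra:
    def test_compound_level_counts_and_ease_ordering(self):
        # 6 features; features 0-2 significant, mapping to compounds a,b,c
        lib = _library_with(
            [("pw1", ["a", "b", "c"]), ("pw2", ["d", "e"])],
            ["a", "b", "c", "d", "e"],
        )
        stats = pd.DataFrame({
            "mz": np.arange(6) + 100.0,
            "p_value": [0.01, 0.02, 0.03, 0.5, 0.6, 0.7],
            "t_score": [3, 2.5, 2, 0.1, -0.2, 0.3],
        })
        mt = _match_table_from_map(
            {0: ["a"], 1: ["b"], 2: ["c"], 3: ["d"], 4: ["e"], 5: []}, 6)
        res = mummichog_ora(stats, mt, lib, p_cutoff=0.05, n_perm=50, seed=0)
        row = res.set_index("pathway_id").loc["pw1"]
        assert row["n_sig_compounds"] == 3
        assert row["n_total_hits"] == 3
        assert row["hits"] == "3/3"
        # fisher: P(X >= 3) with universe 5, marked 3, drawn 3 = 1/C(5,3)
        assert row["fisher_p"] == pytest.approx(1 / 10, abs=1e-12)
        assert row["ease_p"] >= row["fisher_p"]

    def test_all_features_significant_is_degenerate(self):
        lib = _library_with([("pw1", ["a", "b"]), ("pw2", ["c", "d"])],
                            ["a", "b", "c", "d"])
        stats = pd.DataFrame({
            "mz": np.arange(4) + 100.0,
            "p_value": [0.01] * 4,
            "t_score": [1.0] * 4,
        })
        mt = _match_table_from_map({0: ["a"], 1: ["b"], 2: ["c"], 3: ["d"]}, 4)
        res = mummichog_ora(stats, mt, lib, p_cutoff=0.05, n_perm=20, seed=0)
        # S == R: drawing the whole universe makes every tail 1
        assert np.allclose(res["fisher_p"], 1.0)

    def test_no_significant_compounds_is_an_error(self):
        lib = _library_with([("pw1", ["a", "b"])], ["a", "b"])
        stats = pd.DataFrame({"mz": [100.0, 101.0], "p_value": [0.9, 0.8],
                              "t_score": [0.1, 0.2]})
        mt = _match_table_from_map({0: ["a"], 1: ["b"]}, 2)
        with pytest.raises(ValueError, match="significant"):
            mummichog_ora(stats, mt, lib)

    def test_unmatched_pathway_reported_with_p_one(self):
        lib = _library_with([("pw1", ["a"]), ("lonely", ["zz"])], ["a", "zz"])
        stats = pd.DataFrame({"mz": [100.0, 101.0], "p_value": [0.01, 0.9],
                              "t_score": [2.0, 0.1]})
        mt = _match_table_from_map({0: ["a"], 1: []}, 2)
        res = mummichog_ora(stats, mt, lib, n_perm=20, seed=0)
        lonely = res.set_index("pathway_id").loc["lonely"]
        assert lonely["n_total_hits"] == 0
        assert lonely["empirical_p"] == 1.0

    def test_deterministic_given_seed(self, library, rules):
        rng = np.random.default_rng(1)
        rule = rules.rule("[M-H]-", "negative")
        mzs = np.array([
            rule.mz(library.compounds[cid].monoisotopic_mass) * (1 + rng.normal(0, 2e-6))
            for cid in sorted(library.compounds)
        ] + list(rng.uniform(80, 600, 60)))
        n = len(mzs)
        stats = pd.DataFrame({"mz": mzs, "p_value": rng.uniform(0, 1, n),
                              "t_score": rng.normal(0, 2, n)})
        mt = match_features(mzs, library, rules, "negative")
        a = mummichog_ora(stats, mt, library, n_perm=30, seed=9)
        b = mummichog_ora(stats, mt, library, n_perm=30, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestEnrichmentScore:
    def test_top_two_ranked_compounds(self):
        """Set = top-2 of a positive ranking: the running sum peaks at 1."""
        scores = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        mask = np.array([True, True, False, False, False])
        es = enrichment_score(scores, mask)
        assert es == pytest.approx(1.0, abs=1e-12)

    def test_hand_walk(self):
        # hits at ranks 1,2 with scores 5,4: running sum 5/9 then 9/9
        scores = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        mask = np.array([True, True, False, False, False])
        nr = 9.0
        running = [5 / nr, 5 / nr + 4 / nr]
        assert enrichment_score(scores, mask) == pytest.approx(max(running), abs=1e-12)

    def test_bottom_set_is_negative(self):
        scores = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        mask = np.array([False, False, False, True, True])
        assert enrichment_score(scores, mask) < 0

    def test_matches_walk_oracle_on_random_lists(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(3, 21))
            scores = np.sort(rng.normal(0, 2, n))[::-1]
            nh = int(rng.integers(1, n))
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, nh, replace=False)] = True
            assert enrichment_score(scores, mask) == pytest.approx(
                es_walk_oracle(scores, mask), abs=1e-12
            )

    def test_es_bounded_by_one(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(3, 15))
            scores = np.sort(rng.normal(0, 1, n))[::-1]
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, int(rng.integers(1, n)), replace=False)] = True
            assert abs(enrichment_score(scores, mask)) <= 1 + 1e-12

    def test_degenerate_sets_rejected(self):
        with pytest.raises(ValueError):
            enrichment_score(np.array([1.0, 2.0]), np.array([True, True]))


class TestGseaPathways:
    def _setup(self, rng, n_compounds=40):
        cids = [f"c{i:02d}" for i in range(n_compounds)]
        lib = _library_with(
            [("top", cids[:8]), ("rest", cids[20:30])], cids)
        t = np.linspace(4, -4, n_compounds) + rng.normal(0, 0.2, n_compounds)
        stats = pd.DataFrame({
            "mz": np.arange(n_compounds) + 100.0,
            "p_value": rng.uniform(0, 1, n_compounds),
            "t_score": t,
        })
        mt = _match_table_from_map({i: [cids[i]] for i in range(n_compounds)},
                                   n_compounds)
        return lib, stats, mt

    def test_top_loaded_pathway_detected(self):
        rng = np.random.default_rng(4)
        lib, stats, mt = self._setup(rng)
        res = gsea_pathways(stats, mt, lib, n_perm=500, seed=0)
        top = res.set_index("pathway_id").loc["top"]
        assert top["es"] > 0.5
        assert top["p_value"] < 0.05
        assert np.sign(top["nes"]) == np.sign(top["es"])

    def test_max_abs_t_collapse_with_mz_tiebreak(self):
        lib = _library_with([("pw", ["a", "b"]), ("pw2", ["b"])], ["a", "b"])
        stats = pd.DataFrame({
            "mz": [100.0, 150.0, 120.0],
            "p_value": [0.5, 0.5, 0.5],
            "t_score": [2.0, -2.0, 1.0],
        })
        # compound a matched by features 0 and 1 (|t| tie -> larger mz wins)
        mt = _match_table_from_map({0: ["a"], 1: ["a"], 2: ["b"]}, 3)
        from mzpathway.pathways import _compound_scores

        ranked = _compound_scores(stats, mt)
        assert ranked.set_index("compound_id").loc["a", "score"] == -2.0
        assert ranked.set_index("compound_id").loc["a", "feature_index"] == 1

    def test_small_pathways_skipped(self):
        rng = np.random.default_rng(5)
        cids = [f"c{i}" for i in range(10)]
        lib = _library_with([("tiny", cids[:1]), ("ok", cids[2:8])], cids)
        stats = pd.DataFrame({"mz": np.arange(10) + 100.0,
                              "p_value": rng.uniform(0, 1, 10),
                              "t_score": rng.normal(0, 1, 10)})
        mt = _match_table_from_map({i: [cids[i]] for i in range(10)}, 10)
        res = gsea_pathways(stats, mt, lib, n_perm=100, seed=0)
        assert set(res["pathway_id"]) == {"ok"}

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        lib, stats, mt = self._setup(rng)
        a = gsea_pathways(stats, mt, lib, n_perm=200, seed=3)
        b = gsea_pathways(stats, mt, lib, n_perm=200, seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestIntegrate:
    def _frames(self, ora_p, gsea_p, ids=None):
        ids = ids or [f"p{i}" for i in range(len(ora_p))]
        ora = pd.DataFrame({"pathway_id": ids, "pathway_name": ids,
                            "empirical_p": ora_p})
        gsea = pd.DataFrame({"pathway_id": ids, "pathway_name": ids,
                             "p_value": gsea_p})
        return ora, gsea

    def test_fisher_closed_form(self):
        """p = 0.05 from both methods: X2 = -4 ln 0.05 ~ 11.983 and the
        4-df chi-square tail e^{-x/2}(1 + x/2) ~ 0.0175."""
        ora, gsea = self._frames([0.05], [0.05])
        res = integrate(ora, gsea)
        x2 = -4.0 * math.log(0.05)
        closed = math.exp(-x2 / 2) * (1 + x2 / 2)
        assert res.loc[0, "combined_p"] == pytest.approx(closed, abs=1e-12)
        assert res.loc[0, "combined_p"] == pytest.approx(0.0175, abs=2e-4)

    def test_both_one_gives_one(self):
        ora, gsea = self._frames([1.0], [1.0])
        assert integrate(ora, gsea).loc[0, "combined_p"] == pytest.approx(1.0)

    def test_symmetric_in_the_two_methods(self):
        ora, gsea = self._frames([0.01, 0.3], [0.2, 0.04])
        a = integrate(*self._frames([0.01, 0.3], [0.2, 0.04]))
        b = integrate(*self._frames([0.2, 0.04], [0.01, 0.3]))
        np.testing.assert_allclose(a["combined_p"], b["combined_p"], atol=1e-15)

    def test_zero_p_clamped(self):
        ora, gsea = self._frames([0.0], [0.5])
        res = integrate(ora, gsea)
        assert 0 < res.loc[0, "combined_p"] <= 1

    def test_single_method_pathway_flagged(self):
        ora, _ = self._frames([0.02], ["x"])
        ora = ora.iloc[[0]]
        _, gsea = self._frames([0.5, 0.5], [0.03, 0.2], ids=["p0", "extra"])
        res = integrate(ora, gsea).set_index("pathway_id")
        assert not res.loc["p0", "single_method"]
        assert res.loc["extra", "single_method"]
        assert res.loc["extra", "combined_p"] == pytest.approx(0.2)

    def test_scatter_coordinates_are_neglog10(self):
        ora, gsea = self._frames([0.01], [0.1])
        res = integrate(ora, gsea)
        assert res.loc[0, "y"] == pytest.approx(2.0)
        assert res.loc[0, "x"] == pytest.approx(1.0)
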