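import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from kdapipe import (
    GeneSetCollection,
    ParameterError,
    fold_enrichment,
    gsea,
    gsea_es,
    ora,
    rank_features,
    simulate_expression,
)

from _oracles import hypergeom_upper_tail, running_sum_es


class TestFoldEnrichment:
    def test_printed_formula_example(self):
        assert fold_enrichment(5, 10, 50, 1000) == 10.0

    def test_equal_rates_give_exactly_one(self):
        assert fold_enrichment(3, 30, 10, 100) == 1.0
        assert fold_enrichment(7, 7, 70, 70) == 1.0

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 10), st.integers(1, 20), st.integers(1, 50),
           st.integers(1, 200), st.integers(1, 9))
    def test_scale_invariance(self, k, K, n, N, factor):
        a = fold_enrichment(k, K, n, N)
        b = fold_enrichment(k * factor, K * factor, n * factor, N * factor)
        assert a == pytest.approx(b)


class TestOra:
    def test_counts_and_formula(self):
        detected = {f"g{i}" for i in range(100)}
        significant = {f"g{i}" for i in range(10)}
        pathways = GeneSetCollection(sets={"P": [f"g{i}" for i in range(5, 25)]})
        res = ora(significant, detected, pathways)
        row = res.iloc[0]
        assert (row["k"], row["K"], row["n"], row["N"]) == (5, 20, 10, 100)
        assert row["fold_enrichment"] == pytest.approx((5 / 20) / (10 / 100))

    def test_p_matches_exhaustive_enumeration_small_margins(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            N = int(rng.integers(4, 26))
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            detected = {f"g{i}" for i in range(N)}
            significant = set(rng.choice(sorted(detected), size=n, replace=False))
            members = list(rng.choice(sorted(detected), size=K, replace=False))
            res = ora(significant, detected, GeneSetCollection(sets={"P": members}))
            k = int(res.iloc[0]["k"])
            oracle = hypergeom_upper_tail(k, K - k, n - k, N - K - n + k)
            assert res.iloc[0]["p_value"] == pytest.approx(oracle, abs=1e-10)

    def test_significant_outside_detected_rejected(self):
        with pytest.raises(ParameterError, match="x"):
            ora({"x"}, {"a", "b"}, GeneSetCollection(sets={"P": ["a"]}))

    def test_pathway_with_no_detected_member_skipped(self):
        res = ora({"a"}, {"a", "b"}, GeneSetCollection(sets={"P": ["zz"]}))
        assert len(res) == 0

    def test_depletion_tail(self):
        detected = {f"g{i}" for i in range(20)}
        significant = {f"g{i}" for i in range(10)}
        pathways = GeneSetCollection(sets={"P": [f"g{i}" for i in range(10, 15)]})
        res = ora(significant, detected, pathways, alternative="less")
        assert res.iloc[0]["p_value"] < 0.5  # zero overlap is depleted


class TestRankFeatures:
    def _results(self, t, p, lfc, ids):
        return pd.DataFrame({"t": t, "p": p, "log2fc": lfc}, index=ids)

    def test_descending_by_signed_score(self):
        res = self._results([2.0, -2.0], [0.05, 0.05], [1.0, -1.0], ["a", "b"])
        ranked = rank_features(res, metric="t")
        assert list(ranked["feature"]) == ["a", "b"]

    def test_all_equal_scores_fall_back_to_id_order(self):
        res = self._results([1.0, 1.0, 1.0], [0.5] * 3, [1.0] * 3, ["c", "a", "b"])
        ranked = rank_features(res, metric="t")
        assert list(ranked["feature"]) == ["a", "b", "c"]

    def test_permutation_invariance(self):
        res = self._results([3.0, 1.0, 2.0], [0.01, 0.5, 0.1],
                            [1.5, 0.2, 1.0], ["a", "b", "c"])
        ranked = rank_features(res)
        ranked_perm = rank_features(res.iloc[[2, 0, 1]])
        pd.testing.assert_frame_equal(ranked, ranked_perm)

    def test_duplicate_ids_rejected(self):
        res = self._results([1.0, 2.0], [0.5, 0.5], [1.0, 1.0], ["a", "a"])
        with pytest.raises(ParameterError):
            rank_features(res)


class TestGseaEs:
    def test_hand_evaluated_running_sum(self):
        ranked = pd.DataFrame({"feature": ["g1", "g2", "g3", "g4", "g5"],
                               "score": [5.0, 4.0, 3.0, 2.0, 1.0]})
        es, running = gsea_es(ranked, {"g1", "g3"}, weight_exponent=0)
        assert running == pytest.approx([0.5, 1 / 6, 2 / 3, 1 / 3, 0.0])
        assert es == pytest.approx(2 / 3)

    def test_top_loaded_set_maximal_es(self):
        n, s = 20, 4
        ranked = pd.DataFrame({"feature": [f"g{i}" for i in range(n)],
                               "score": np.linspace(10, 1, n)})
        top = {f"g{i}" for i in range(s)}
        es, _ = gsea_es(ranked, top, weight_exponent=0)
        oracle_es, _ = running_sum_es(ranked["feature"], ranked["score"], top, 0)
        assert es == pytest.approx(oracle_es)
        # all hits precede any miss: the running sum peaks at exactly 1
        assert es == pytest.approx(1.0)

    def test_bottom_loaded_set_negative_es(self):
        ranked = pd.DataFrame({"feature": [f"g{i}" for i in range(10)],
                               "score": np.linspace(10, 1, 10)})
        es, _ = gsea_es(ranked, {"g8", "g9"}, weight_exponent=0)
        assert es < 0

    def test_matches_brute_force_oracle_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            N = int(rng.integers(5, 51))
            size = int(rng.integers(1, min(10, N - 1) + 1))
            scores = np.sort(rng.normal(size=N))[::-1]
            features = [f"g{i}" for i in range(N)]
            members = set(rng.choice(features, size=size, replace=False))
            exponent = float(rng.choice([0.0, 1.0, 2.0]))
            ranked = pd.DataFrame({"feature": features, "score": scores})
            es, _ = gsea_es(ranked, members, weight_exponent=exponent)
            oracle_es, _ = running_sum_es(features, scores, members, exponent)
            assert abs(es - oracle_es) < 1e-12

    def test_antisymmetric_under_ranking_reversal_exponent_zero(self):
        rng = np.random.default_rng(2)
        features = [f"g{i}" for i in range(30)]
        scores = np.sort(rng.normal(size=30))[::-1]
        members = set(rng.choice(features, size=6, replace=False))
        ranked = pd.DataFrame({"feature": features, "score": scores})
        reversed_ranked = ranked.iloc[::-1].reset_index(drop=True)
        es_f, _ = gsea_es(ranked, members, weight_exponent=0)
        es_r, _ = gsea_es(reversed_ranked, members, weight_exponent=0)
        assert es_f == pytest.approx(-es_r)

    def test_degenerate_sets_rejected(self):
        ranked = pd.DataFrame({"feature": ["a", "b"], "score": [2.0, 1.0]})
        with pytest.raises(ParameterError):
            gsea_es(ranked, {"zz"})
        with pytest.raises(ParameterError):
            gsea_es(ranked, {"a", "b"})


class TestGsea:
    def _planted_instance(self, seed, n_genes=400, set_size=20):
        matrix, truth = simulate_expression(
            n_genes=n_genes, n_per_group=8, frac_de=0.2,
            effect_range=(1.5, 2.0), noise_sd=0.25, seed=seed)
        up = sorted(g for g, e in truth.planted_degs.items() if e > 0)[:set_size]
        rng = np.random.default_rng(seed + 1000)
        null = sorted(rng.choice(
            [g for g in matrix.feature_ids if g not in truth.planted_degs],
            size=set_size, replace=False))
        pathways = GeneSetCollection(sets={"planted": up, "null": null})
        return matrix, pathways

    def test_planted_top_loaded_set_detected(self):
        matrix, pathways = self._planted_instance(seed=0)
        res = gsea(matrix, pathways, "FA", "DE", n_permutations=500,
                   min_size=5, seed=0).set_index("set_name")
        assert res.loc["planted", "p_value"] < 0.05
        assert res.loc["planted", "es"] > 0
        assert res.loc["planted", "p_value"] < res.loc["null", "p_value"]

    def test_leading_edge_within_set_and_universe(self):
        matrix, pathways = self._planted_instance(seed=3)
        res = gsea(matrix, pathways, "FA", "DE", n_permutations=200,
                   min_size=5, seed=3).set_index("set_name")
        edge = set(res.loc["planted", "leading_edge"].split(","))
        assert edge <= set(pathways["planted"])
        assert len(edge) >= 1

    def test_deterministic_under_seed(self):
        matrix, pathways = self._planted_instance(seed=5)
        a = gsea(matrix, pathways, "FA", "DE", n_permutations=200, min_size=5, seed=9)
        b = gsea(matrix, pathways, "FA", "DE", n_permutations=200, min_size=5, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_phenotype_fallback_warning_for_tiny_groups(self, caplog):
        matrix, truth = simulate_expression(n_genes=100, n_per_group=2,
                                            frac_de=0.2, seed=6)
        pathways = GeneSetCollection(sets={"S": matrix.feature_ids[:20]})
        with caplog.at_level("WARNING", logger="kdapipe.genesets"):
            gsea(matrix, pathways, "FA", "DE", n_permutations=100,
                 permutation_type="phenotype", min_size=5, seed=0)
        assert "falling back" in caplog.text

    def test_phenotype_permutation_runs(self):
        matrix, pathways = self._planted_instance(seed=7, n_genes=150, set_size=15)
        res = gsea(matrix, pathways, "FA", "DE", n_permutations=100,
                   permutation_type="phenotype", min_size=5, seed=7)
        assert set(res["set_name"]) == {"planted", "null"}
        assert res["p_value"].between(0, 1).all()

    def test_size_filter_error_when_nothing_kept(self):
        matrix, pathways = self._planted_instance(seed=8)
        with pytest.raises(ParameterError, match="size bounds"):
            gsea(matrix, pathways, "FA", "DE", n_permutations=100,
                 min_size=400, seed=0)
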