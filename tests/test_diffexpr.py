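import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from kdapipe import (
    ExpressionMatrix,
    ParameterError,
    bh_adjust,
    differential_table,
    make_signature,
    q_values,
    rank_invariant_normalize,
    simulate_expression,
    venn_counts,
    welch_test,
)
from kdapipe.diffexpr import Signature, student_test

from _oracles import bh_step_up


class TestWelch:
    def test_identical_groups(self):
        t, df, p = welch_test([1, 2, 3], [1, 2, 3])
        assert t == 0 and p == 1

    def test_hand_evaluated_closed_form(self):
        # x=(1,2,3), y=(2,3,4): se = sqrt(1/3+1/3), t = -1/se, WS df = 4
        t, df, p = welch_test([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.224744871391589, abs=1e-10)
        assert df == pytest.approx(4.0, abs=1e-10)
        assert p == pytest.approx(0.28786413472669053, abs=1e-10)

    def test_zero_variance_distinct_means_gives_p_zero(self):
        t, df, p = welch_test([1.0, 1.0], [2.0, 2.0])
        assert p == 0 and np.isinf(t)

    def test_insufficient_values_yield_missing_not_crash(self):
        assert all(np.isnan(v) for v in welch_test([1.0], [1, 2, 3]))
        assert all(np.isnan(v) for v in welch_test([1, np.nan], [1, 2, 3]))

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=2, max_size=8),
           st.lists(st.floats(-50, 50), min_size=2, max_size=8))
    def test_group_swap_negates_t_preserves_p(self, x, y):
        t1, df1, p1 = welch_test(x, y)
        t2, df2, p2 = welch_test(y, x)
        assert t1 == pytest.approx(-t2, nan_ok=True)
        assert p1 == pytest.approx(p2, nan_ok=True)

    def test_matches_scipy_reference(self):
        from scipy import stats
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.normal(size=rng.integers(2, 10))
            y = rng.normal(1, 2, size=rng.integers(2, 10))
            t, df, p = welch_test(x, y)
            ref = stats.ttest_ind(x, y, equal_var=False)
            assert t == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_step_up_hand_example(self):
        # p=(0.01,0.02,0.03,0.04): p_(i)*4/i = (.04,.04,.04,.04)
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_matches_independent_step_up_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40)).tolist()
            assert np.max(np.abs(bh_adjust(p) - np.array(bh_step_up(p)))) < 1e-12

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(7)
        p = rng.uniform(size=500)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.max(np.abs(bh_adjust(p) - ref)) < 1e-12

    def test_nan_passthrough_and_family_size(self):
        out = bh_adjust([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        # m=2, not 3
        assert out[0] == pytest.approx(0.02)

    def test_out_of_range_p_names_index(self):
        with pytest.raises(ParameterError, match="index 1"):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_permutation_invariance_and_monotonicity(self, p):
        adj = bh_adjust(p)
        perm = np.random.default_rng(0).permutation(len(p))
        adj_perm = bh_adjust(list(np.array(p)[perm]))
        assert np.allclose(np.array(adj)[perm], adj_perm)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(np.array(adj)[order]) >= -1e-15)
        assert np.all((0 <= adj) & (adj <= 1)) and np.all(adj >= np.array(p) - 1e-15)


class TestQValues:
    def test_bh_method_equals_bh_adjust(self):
        p = np.random.default_rng(1).uniform(size=50)
        assert np.allclose(q_values(p, method="bh"), bh_adjust(p))

    def test_storey_pi0_near_one_under_null(self):
        p = np.random.default_rng(2).uniform(size=10_000)
        q = q_values(p, method="storey")
        # under a uniform null pi0-hat ~ 1, so q ~ BH within 10%
        ratio = q[~np.isnan(q)] / bh_adjust(p)[~np.isnan(q)]
        assert 0.9 <= np.median(ratio) <= 1.1

    def test_all_ones(self):
        assert q_values([1.0] * 200, method="storey") == pytest.approx([1.0] * 200)

    def test_small_family_falls_back_to_bh_with_warning(self):
        p = [0.01, 0.5, 0.9]
        with pytest.warns(UserWarning, match="falling back"):
            q = q_values(p, method="storey")
        assert np.allclose(q, bh_adjust(p))


class TestRankInvariantNormalize:
    def _matrix(self, cols):
        df = pd.DataFrame(cols)
        groups = {c: "G" for c in df.columns}
        return ExpressionMatrix(values=df, groups=groups)

    def test_identity_when_sample_equals_reference(self):
        base = np.exp(np.random.default_rng(0).normal(5, 1, 200))
        m = self._matrix({"r": base, "s": base})
        out = rank_invariant_normalize(m, reference="r")
        assert np.allclose(out.values["s"], base)

    def test_constant_scaling_recovered_exactly(self):
        base = np.exp(np.random.default_rng(1).normal(5, 1, 200))
        m = self._matrix({"r": base, "s": 2.0 * base})
        out = rank_invariant_normalize(m, reference="r")
        assert np.allclose(out.values["s"], base)
        assert np.allclose(out.values["r"], base)

    def test_reversed_ranks_rejected(self):
        vals = np.arange(1.0, 11.0)
        m = self._matrix({"r": vals, "s": vals[::-1].copy()})
        with pytest.raises(ParameterError, match="reference"):
            rank_invariant_normalize(m, reference="r")

    def test_nonpositive_intensities_rejected(self):
        m = self._matrix({"r": [1.0, 2.0, 0.0], "s": [1.0, 2.0, 3.0]})
        with pytest.raises(ParameterError):
            rank_invariant_normalize(m, reference="r")


class TestDifferentialTable:
    def test_planted_effect_recovered_in_fold_change(self):
        # planted +1 log2 at low noise: fold changes near 2 and tiny p
        folds = []
        for seed in range(5):
            m, truth = simulate_expression(
                n_genes=300, n_per_group=8, frac_de=0.1,
                effect_range=(1.0, 1.0), noise_sd=0.1, seed=seed)
            res = differential_table(m, "FA", "DE")
            up = [g for g, e in truth.planted_degs.items() if e > 0]
            folds.extend(res.loc[up, "fold_change"])
        se = 3 * 0.1 * np.sqrt(2 / 8) * np.log(2) * 2  # delta method on ratio
        assert abs(np.mean(folds) - 2.0) < se

    def test_null_type_one_error_near_alpha(self):
        m, _ = simulate_expression(n_genes=4000, n_per_group=8, frac_de=0.0, seed=11)
        res = differential_table(m, "FA", "DE")
        frac = (res["p"] < 0.05).mean()
        # binomial 99.9% band around 0.05 at m=4000
        assert 0.05 - 3.3 * np.sqrt(0.05 * 0.95 / 4000) < frac < 0.05 + 3.3 * np.sqrt(0.05 * 0.95 / 4000)

    def test_metabolite_missing_group_excluded_from_family(self, small_metabolome):
        tab = small_metabolome
        tab.abundances.loc["m2", ["t1", "t2"]] = np.nan
        res = differential_table(tab, "FA", "DE")
        assert np.isnan(res.loc["m2", "p"])
        assert res["adj_p"].notna().sum() == 2

    def test_fold_change_is_ratio_of_arithmetic_means(self, small_metabolome):
        res = differential_table(small_metabolome, "FA", "DE")
        exp = (350 + 330) / 2 / ((100 + 110) / 2)
        assert res.loc["m1", "fold_change"] == pytest.approx(exp)

    def test_unknown_label_rejected(self, small_expression):
        with pytest.raises(ParameterError, match="XX"):
            differential_table(small_expression, "FA", "XX")

    def test_student_option(self, small_expression):
        res = differential_table(small_expression, "FA", "DE", test="student")
        assert (res["df"].dropna() == 2.0).all()

    def test_student_matches_scipy(self):
        from scipy import stats
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=6), rng.normal(size=5)
        t, df, p = student_test(x, y)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert t == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)


class TestSignature:
    def test_empty_when_nothing_passes(self, small_expression):
        res = differential_table(small_expression, "FA", "DE")
        res["adj_p"] = 0.9
        sig = make_signature(res, threshold=0.05)
        assert len(sig) == 0

    def test_direction_assignment_and_flat_exclusion(self):
        res = pd.DataFrame({
            "fold_change": [2.0, 0.5, 1.0],
            "adj_p": [0.01, 0.01, 0.01],
        }, index=["a", "b", "c"])
        sig = make_signature(res, threshold=0.05)
        assert sig.up == {"a"} and sig.down == {"b"}

    def test_monotone_in_cutoff(self):
        m, _ = simulate_expression(n_genes=500, frac_de=0.2, seed=4)
        res = differential_table(m, "FA", "DE")
        previous: set = set()
        for cutoff in (0.001, 0.01, 0.05, 0.2, 0.5):
            called = make_signature(res, threshold=cutoff).genes
            assert previous <= called
            previous = called

    def test_planted_benchmark_recovery(self):
        # 500 planted of 10,000 at |log2FC| >= 1, n=8/group: >=90% recovered
        # at BH 0.05 with observed FDR <= 0.1 (averaged over seeds in the
        # acceptance suite; spot-checked here on one seed)
        m, truth = simulate_expression(n_genes=2000, n_per_group=8,
                                       frac_de=0.05, seed=12)
        res = differential_table(m, "FA", "DE")
        called = make_signature(res, threshold=0.05).genes
        planted = set(truth.planted_degs)
        assert len(called & planted) / len(planted) >= 0.9
        assert len(called - planted) / max(len(called), 1) <= 0.1


class TestVennCounts:
    def test_identical_signatures(self):
        a = Signature(name="A", up={"x", "y"}, down={"z"})
        counts = venn_counts(a, a)
        assert counts.loc["up", "a_only"] == 0 and counts.loc["up", "shared"] == 2
        assert counts.loc["down", "b_only"] == 0

    def test_disjoint_signatures(self):
        a = Signature(name="A", up={"x"}, down=set())
        b = Signature(name="B", up={"y"}, down=set())
        assert venn_counts(a, b).loc["up", "shared"] == 0

    def test_counts_equal_set_arithmetic(self):
        rng = np.random.default_rng(5)
        universe = [f"g{i}" for i in range(30)]
        for _ in range(20):
            pick = lambda: set(rng.choice(universe, size=rng.integers(0, 10), replace=False))
            au, bu = pick(), pick()
            a = Signature(name="A", up=au, down=pick() - au)
            b = Signature(name="B", up=bu, down=pick() - bu)
            c = venn_counts(a, b)
            assert c.loc["up", "shared"] == len(a.up & b.up)
            assert c.loc["up", "a_only"] == len(a.up - b.up)
            assert c.loc["down", "b_only"] == len(b.down - a.down)
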