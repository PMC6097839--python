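"""Differential-TE statistics against brute-force oracles and ground truth."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from riboteq import AnalysisError, ExpressionMatrix
from riboteq.pipeline import analyze_experiment
from riboteq.te import (
    abundance_effect_correlation,
    bh_qvalues,
    class_change_test,
    differential_te,
    moderated_ttest,
    rank_genes,
    te_change,
    translational_efficiency,
)


def expr(values, mode="spike"):
    return ExpressionMatrix(values=pd.DataFrame(values), mode=mode)


def paired_matrices(ribo_rows, rna_rows, ages=("young", "old"), reps=(1, 2)):
    ribo_cols = {f"{a}_ribo_rep{r}": ribo_rows for a in ages for r in reps}
    rna_cols = {f"{a}_rna_rep{r}": rna_rows for a in ages for r in reps}
    return expr(ribo_cols), expr(rna_cols)


class TestTranslationalEfficiency:
    def test_direct_ratio(self):
        ribo, rna = paired_matrices({"g1": 10.0}, {"g1": 5.0})
        tet = translational_efficiency(ribo, rna)
        assert (tet.te.loc["g1"] == 2.0).all()

    def test_identity_when_equal(self):
        ribo, rna = paired_matrices({"g1": 7.0, "g2": 3.0}, {"g1": 7.0, "g2": 3.0})
        tet = translational_efficiency(ribo, rna)
        assert (tet.te == 1.0).all().all()

    def test_zero_rna_flagged_undefined(self):
        ribo, rna = paired_matrices({"g1": 1.0, "g2": 2.0}, {"g1": 0.0, "g2": 4.0})
        tet = translational_efficiency(ribo, rna)
        assert tet.table.loc["g1", "status"] == "undefined_rna_zero"
        assert tet.table.loc["g2", "status"] == "ok"

    def test_unpaired_samples_rejected(self):
        ribo = expr({"young_ribo_rep1": {"g": 1.0}, "young_ribo_rep2": {"g": 1.0}})
        rna = expr({"young_rna_rep1": {"g": 1.0}, "young_rna_rep3": {"g": 1.0}})
        with pytest.raises(AnalysisError, match="unpaired"):
            translational_efficiency(ribo, rna)


class TestTeChange:
    def test_two_fold_down(self):
        ribo, rna = paired_matrices({"g1": 1.0}, {"g1": 1.0})
        tet = translational_efficiency(ribo, rna)
        for col in tet.columns_for("old"):
            tet.te[col] = 0.5
        for col in tet.columns_for("young"):
            tet.te[col] = 2.0
        te_change(tet)
        assert tet.table.loc["g1", "log2fc_old"] == pytest.approx(-2.0)

    def test_forty_fold_ceiling_log2(self):
        ribo, rna = paired_matrices({"g1": 1.0}, {"g1": 1.0})
        tet = translational_efficiency(ribo, rna)
        for col in tet.columns_for("old"):
            tet.te[col] = 1.0 / 40.0
        te_change(tet)
        assert tet.table.loc["g1", "log2fc_old"] == pytest.approx(-math.log2(40))
        assert tet.table.loc["g1", "log2fc_old"] == pytest.approx(-5.32, abs=0.01)

    def test_no_change_is_zero(self):
        ribo, rna = paired_matrices({"g1": 4.0}, {"g1": 2.0})
        tet = te_change(translational_efficiency(ribo, rna))
        assert tet.table.loc["g1", "log2fc_old"] == 0.0


def brute_force_bh(p):
    """Independent BH step-up from the definition."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        k = n - rank_from_end
        prev = min(prev, p[idx] * n / k)
        q[idx] = prev
    return q


class TestBHQvalues:
    def test_worked_example(self):
        np.testing.assert_allclose(
            bh_qvalues([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    @given(
        st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=60)
    )
    def test_matches_brute_force_step_up(self, pvals):
        np.testing.assert_allclose(bh_qvalues(pvals), brute_force_bh(pvals), rtol=1e-12)

    def test_q_monotone_in_p_rank(self):
        rng = np.random.default_rng(0)
        p = rng.random(200)
        q = bh_qvalues(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestModeratedTest:
    def test_flat_gene_in_noisy_universe_not_significant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(50, 3))
        b = rng.normal(size=(50, 3))
        a[0] = b[0] = 1.0  # identical replicate values in both groups
        res = moderated_ttest(a, b)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_needs_two_replicates(self):
        with pytest.raises(AnalysisError):
            moderated_ttest(np.ones((3, 1)), np.ones((3, 2)))

    def test_shrinkage_tempers_tiny_variances(self):
        """A gene with near-zero sample variance must not get an unbounded t."""
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, size=(200, 3))
        b = rng.normal(0, 1, size=(200, 3))
        a[0] = [0.100, 0.1001, 0.0999]
        b[0] = [0.0, 0.0001, -0.0001]
        res = moderated_ttest(a, b)
        plain_t = stats.ttest_ind(a[0], b[0]).statistic
        assert abs(res["t"].iloc[0]) < abs(plain_t)


class TestDifferentialTE:
    def test_alpha_validated(self, small_experiment):
        models, spikes, cm, _ = small_experiment
        with pytest.raises(AnalysisError):
            analyze_experiment(cm, spikes, models, alpha=1.5)

    def test_pipeline_recovers_true_effects(self, small_experiment):
        """Estimated per-gene log2 TE changes track ground truth with low
        error and near-unit slope (regression through the origin)."""
        models, spikes, cm, truth = small_experiment
        tet, _, _ = analyze_experiment(cm, spikes, models)
        ok = tet.table["status"] == "ok"
        est = tet.table.loc[ok, "log2fc_old"]
        true = truth.genes.loc[est.index, "true_log2fc_te_old"]
        rmse = float(np.sqrt(((est - true) ** 2).mean()))
        slope = float((est * true).sum() / (true**2).sum())
        assert rmse <= 0.5
        assert 0.9 <= slope <= 1.1

    def test_alpha_to_zero_calls_nothing(self, small_experiment):
        models, spikes, cm, _ = small_experiment
        tet, _, _ = analyze_experiment(cm, spikes, models, alpha=1e-300)
        assert int(tet.table["significant_decrease"].sum()) == 0


class TestRankGenes:
    def _table(self, fc):
        ribo, rna = paired_matrices(
            {g: 1.0 for g in fc}, {g: 1.0 for g in fc}
        )
        tet = translational_efficiency(ribo, rna)
        te_change(tet)
        tet.table["log2fc_old"] = pd.Series(fc)
        return rank_genes(tet)

    def test_most_reduced_first(self):
        tet = self._table({"a": -2.0, "b": 0.0, "c": -5.0})
        ordered = tet.table["rank"].sort_values().index.tolist()
        assert ordered == ["c", "a", "b"]

    def test_ties_break_lexicographically(self):
        tet = self._table({"b": 1.0, "a": 1.0, "c": 1.0})
        ordered = tet.table["rank"].sort_values().index.tolist()
        assert ordered == ["a", "b", "c"]

    def test_rank_is_permutation(self, small_experiment):
        models, spikes, cm, _ = small_experiment
        tet, _, _ = analyze_experiment(cm, spikes, models)
        ranks = tet.table.loc[tet.table["status"] == "ok", "rank"]
        assert sorted(ranks) == list(range(1, len(ranks) + 1))


def enumeration_wilcoxon_p(x, mask):
    """Two-sided permutation p by full enumeration (test-side oracle)."""
    ranks = stats.rankdata(x)
    n, n1 = len(x), int(np.sum(mask))
    obs = abs(ranks[mask].sum() - n1 * (n + 1) / 2)
    hits = total = 0
    for combo in itertools.combinations(range(n), n1):
        s = sum(ranks[i] for i in combo)
        total += 1
        if abs(s - n1 * (n + 1) / 2) >= obs - 1e-9:
            hits += 1
    return hits / total


class TestClassChangeTest:
    def test_small_example_exact_third(self):
        values = pd.Series([1.0, 2.0, 3.0, 4.0])
        mask = np.array([True, True, False, False])
        _, p = class_change_test(values, mask)
        assert p == pytest.approx(1 / 3)

    def test_symmetric_distribution_p_one(self):
        values = pd.Series([1.0, 2.0, 2.0, 1.0])
        mask = np.array([True, False, True, False])
        _, p = class_change_test(values, mask)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_path_matches_full_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        n1 = int(rng.integers(1, n))
        x = np.round(rng.normal(size=n), 1)  # rounding induces ties sometimes
        mask = np.zeros(n, dtype=bool)
        mask[rng.choice(n, n1, replace=False)] = True
        _, p = class_change_test(pd.Series(x), mask)
        assert p == pytest.approx(enumeration_wilcoxon_p(x, mask))

    @pytest.mark.parametrize("seed", range(3))
    def test_exact_path_matches_scipy_no_ties(self, seed):
        """Independent cross-check against the library implementation when
        there are no ties (where both conventions coincide)."""
        rng = np.random.default_rng(100 + seed)
        x = rng.permutation(np.arange(10, dtype=float))
        mask = np.zeros(10, dtype=bool)
        mask[:4] = True
        _, p = class_change_test(pd.Series(x), mask)
        expected = stats.mannwhitneyu(x[mask], x[~mask], method="exact").pvalue
        assert p == pytest.approx(expected)

    def test_large_sample_normal_path_reasonable(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        mask = np.zeros(500, dtype=bool)
        mask[:100] = True
        x[mask] += 1.0
        _, p = class_change_test(pd.Series(x), mask)
        assert p < 1e-10

    def test_empty_class_rejected(self):
        with pytest.raises(AnalysisError):
            class_change_test(pd.Series([1.0, 2.0]), np.array([False, False]))


class TestAbundanceEffectCorrelation:
    def test_perfect_anticorrelation(self):
        x = pd.Series([1.0, 2.0, 4.0, 8.0])
        rho, _ = abundance_effect_correlation(x, -np.log2(x))
        assert rho == pytest.approx(-1.0)

    def test_independent_vectors_near_zero(self):
        rng = np.random.default_rng(4)
        n = 2000
        x = pd.Series(rng.lognormal(size=n))
        y = pd.Series(rng.normal(size=n))
        rho, _ = abundance_effect_correlation(x, y)
        assert abs(rho) < 3 / math.sqrt(n)

    def test_constant_vector_rejected(self):
        with pytest.raises(AnalysisError):
            abundance_effect_correlation(
                pd.Series([1.0, 1.0, 1.0]), pd.Series([1.0, 2.0, 3.0])
            )

    def test_recovers_generator_coupling(self, small_experiment):
        """Estimated TE change vs estimated young RNA abundance reproduces the
        configured (negative) abundance coupling among affected genes."""
        models, spikes, cm, truth = small_experiment
        tet, rna, _ = analyze_experiment(cm, spikes, models)
        affected = truth.genes.index[truth.genes["affected"]]
        young = rna.values[rna.samples_for(age="young")].mean(axis=1)
        rho, table = abundance_effect_correlation(
            young.loc[affected], tet.table.loc[affected, "log2fc_old"]
        )
        target = truth.scenario.te_effect_abundance_coupling
        assert rho < 0
        assert abs(abs(rho) - target) < 0.15
        assert set(table.columns) == {"log2_young", "te_log2fc"}
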