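import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metastrat import (
    ExpressionMatrix,
    MutationTable,
    bh_adjust,
    correlate_genes_with_score,
    covariate_by_cluster,
    gm_ratio_annotation,
    impactful_filter,
    mutation_cluster_association,
    welch_tests_by_gene,
)
from conftest import random_expression
from oracles import naive_bh, naive_chi_square, naive_pearson, naive_welch


def two_group_matrix(rng, n_genes=20, n_a=5, n_b=6):
    X = random_expression(rng, n_genes=n_genes, n_samples=n_a + n_b)
    labels = pd.Series([1] * n_a + [2] * n_b, index=X.sample_ids)
    return X, labels


class TestWelch:
    def test_identical_gene_t_zero_p_one(self):
        vals = pd.DataFrame(
            [[5.0] * 8, [1, 2, 3, 4, 9, 8, 7, 6]],
            index=["flat", "varies"],
            columns=[f"s{i}" for i in range(8)],
        )
        X = ExpressionMatrix(vals)
        labels = pd.Series([1, 1, 1, 1, 2, 2, 2, 2], index=X.sample_ids)
        res = welch_tests_by_gene(X, labels, 1, 2)
        assert res.table.loc["flat", "t_stat"] == 0.0
        assert res.table.loc["flat", "p_raw"] == 1.0

    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(0)
        X, labels = two_group_matrix(rng, n_genes=50)
        res = welch_tests_by_gene(X, labels, 1, 2)
        L = np.log2(X.values + 1)
        a_cols = labels.index[labels == 1]
        b_cols = labels.index[labels == 2]
        for g in X.gene_ids:
            t, p = naive_welch(L.loc[g, a_cols], L.loc[g, b_cols])
            assert res.table.loc[g, "t_stat"] == pytest.approx(t, abs=1e-10)
            assert res.table.loc[g, "p_raw"] == pytest.approx(p, abs=1e-10)

    def test_within_group_permutation_invariance(self):
        rng = np.random.default_rng(1)
        X, labels = two_group_matrix(rng)
        res1 = welch_tests_by_gene(X, labels, 1, 2)
        order = list(labels.index[labels == 1][::-1]) + list(labels.index[labels == 2][::-1])
        res2 = welch_tests_by_gene(X.subset_samples(order), labels.loc[order], 1, 2)
        pd.testing.assert_frame_equal(res1.table, res2.table)

    def test_small_group_rejected(self):
        rng = np.random.default_rng(2)
        X, labels = two_group_matrix(rng, n_a=1, n_b=5)
        with pytest.raises(ValueError):
            welch_tests_by_gene(X, labels, 1, 2)


class TestBH:
    def test_single_p_unchanged(self):
        adj, flags = bh_adjust([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert flags[0]

    def test_worked_example(self):
        adj, _ = bh_adjust([0.01, 0.02, 0.04, 0.05])
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.05, 0.05], atol=1e-12)

    def test_all_equal_p_unchanged(self):
        adj, _ = bh_adjust([0.2, 0.2, 0.2])
        np.testing.assert_allclose(adj, [0.2, 0.2, 0.2], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_naive_step_up_and_invariants(self, ps):
        adj, _ = bh_adjust(ps)
        np.testing.assert_allclose(adj, naive_bh(ps), atol=1e-12)
        assert (adj <= 1.0 + 1e-12).all()
        assert (adj >= np.asarray(ps) - 1e-12).all()
        # order invariance
        perm = np.random.default_rng(0).permutation(len(ps))
        adj_p, _ = bh_adjust(np.asarray(ps)[perm])
        np.testing.assert_allclose(adj_p, adj[perm], atol=1e-12)


class TestFoldAnnotation:
    def test_identical_groups_unchanged(self):
        rng = np.random.default_rng(3)
        X = random_expression(rng, n_genes=5, n_samples=4)
        dup = ExpressionMatrix(
            pd.concat([X.values, X.values.add_suffix("_b")], axis=1)
        )
        labels = pd.Series([1] * 4 + [2] * 4, index=dup.sample_ids)
        ann = gm_ratio_annotation(dup, labels, 1, 2)
        np.testing.assert_allclose(ann.table["ratio"], 1.0, atol=1e-12)
        assert (ann.table["fold_class"] == "unchanged").all()

    def test_arithmetic_example(self):
        X = ExpressionMatrix(
            pd.DataFrame([[4.0, 4.0, 1.0, 1.0]], index=["g"], columns=list("abcd"))
        )
        labels = pd.Series([1, 1, 2, 2], index=list("abcd"))
        ann = gm_ratio_annotation(X, labels, 1, 2, pseudocount=1.0, fold_threshold=1.4)
        assert ann.table.loc["g", "ratio"] == pytest.approx(2.5)
        assert ann.table.loc["g", "fold_class"] == "up"

    def test_group_swap_inverts_ratio(self):
        rng = np.random.default_rng(4)
        X, labels = two_group_matrix(rng, n_genes=10)
        a = gm_ratio_annotation(X, labels, 1, 2)
        b = gm_ratio_annotation(X, labels, 2, 1)
        np.testing.assert_allclose(a.table["ratio"] * b.table["ratio"], 1.0, rtol=1e-10)


class TestImpactfulFilter:
    @pytest.mark.parametrize(
        "sift,polyphen,kept",
        [
            ("deleterious", "benign", True),
            ("tolerated", "probably_damaging", True),
            ("tolerated", "possibly_damaging", True),
            ("tolerated", "benign", False),
            ("missing", "missing", False),
            ("deleterious", "missing", True),
        ],
    )
    def test_or_rule(self, sift, polyphen, kept):
        t = MutationTable(
            pd.DataFrame(
                [{"gene": "G", "sample_id": "S", "variant_classification": "Missense_Mutation",
                  "sift_label": sift, "polyphen_label": polyphen}]
            )
        )
        assert len(impactful_filter(t)) == (1 if kept else 0)


class TestMutationAssociation:
    def _table(self, pairs):
        rows = [
            {"gene": g, "sample_id": s, "variant_classification": "Missense_Mutation",
             "sift_label": "deleterious", "polyphen_label": "benign"}
            for g, s in pairs
        ]
        return MutationTable(pd.DataFrame(
            rows, columns=["gene", "sample_id", "variant_classification",
                           "sift_label", "polyphen_label"]))

    def test_balanced_table_statistic_zero(self):
        samples = [f"s{i}" for i in range(40)]
        labels = pd.Series([1] * 20 + [2] * 20, index=samples)
        # mutated in 10 of each cluster -> proportional rows
        muts = self._table([("G", s) for s in samples[:10] + samples[20:30]])
        res = mutation_cluster_association(muts, labels, genes=["G"])
        assert res.loc["G", "chi_square"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc["G", "p_raw"] == pytest.approx(1.0)

    def test_strong_association_matches_direct_formula(self):
        samples = [f"s{i}" for i in range(50)]
        labels = pd.Series([1] * 25 + [2] * 25, index=samples)
        muts = self._table([("G", s) for s in samples[:20] + samples[25:30]])
        res = mutation_cluster_association(muts, labels, genes=["G"])
        expect = naive_chi_square([[20, 5], [5, 20]])
        assert res.loc["G", "chi_square"] == pytest.approx(expect, abs=1e-10)
        assert expect == pytest.approx(18.0)

    def test_zero_mutation_gene_degenerate_not_in_family(self):
        samples = [f"s{i}" for i in range(10)]
        labels = pd.Series([1] * 5 + [2] * 5, index=samples)
        muts = self._table([("G", samples[0])])
        res = mutation_cluster_association(muts, labels, genes=["G", "NEVER"])
        assert bool(res.loc["NEVER", "degenerate"])
        assert np.isnan(res.loc["NEVER", "p_adj"])


class TestCovariateByCluster:
    def test_two_clusters_f_equals_t_squared(self):
        rng = np.random.default_rng(5)
        v = pd.Series(rng.normal(size=20), index=[f"s{i}" for i in range(20)])
        labels = pd.Series([1] * 10 + [2] * 10, index=v.index)
        from scipy import stats

        out = covariate_by_cluster(v, labels)
        t, _ = stats.ttest_ind(v[labels == 1], v[labels == 2], equal_var=True)
        assert out["anova_F"] == pytest.approx(t**2, rel=1e-10)

    def test_declining_means_negative_trend(self):
        rng = np.random.default_rng(6)
        idx = [f"s{i}" for i in range(60)]
        labels = pd.Series(np.repeat([1, 2, 3], 20), index=idx)
        v = pd.Series(10.0 - 2.0 * labels.to_numpy() + rng.normal(0, 0.5, 60), index=idx)
        out = covariate_by_cluster(v, labels)
        assert out["trend_spearman_rho"] < -0.8
        assert out["anova_p"] < 1e-6

    def test_tiny_cluster_excluded_with_warning(self):
        idx = [f"s{i}" for i in range(9)]
        labels = pd.Series([1] * 4 + [2] * 4 + [3], index=idx)
        v = pd.Series(np.arange(9, dtype=float), index=idx)
        with pytest.warns(UserWarning, match="excluded"):
            out = covariate_by_cluster(v, labels)
        assert list(out["summary"].index) == [1, 2]


class TestCorrelationScreen:
    def test_perfect_and_anti_correlation(self):
        rng = np.random.default_rng(7)
        score = pd.Series(rng.normal(size=8), index=[f"s{i}" for i in range(8)])
        vals = pd.DataFrame(
            {s: [score[s] + 5.0, -score[s] + 5.0, 1.0] for s in score.index},
            index=["same", "anti", "const"],
        )
        X = ExpressionMatrix(vals.clip(lower=0))
        out = correlate_genes_with_score(X, score)
        assert out.loc["same", "r"] == pytest.approx(1.0)
        assert out.loc["anti", "r"] == pytest.approx(-1.0)
        assert np.isnan(out.loc["const", "r"])

    def test_matches_covariance_formula_oracle(self):
        rng = np.random.default_rng(8)
        X = random_expression(rng, n_genes=30, n_samples=12)
        score = pd.Series(rng.normal(size=12), index=X.sample_ids)
        out = correlate_genes_with_score(X, score)
        for g in X.gene_ids:
            assert out.loc[g, "r"] == pytest.approx(
                naive_pearson(X.values.loc[g], score.loc[X.sample_ids]), abs=1e-12
            )

    def test_sorted_by_absolute_r(self):
        rng = np.random.default_rng(9)
        X = random_expression(rng, n_genes=15, n_samples=10)
        score = pd.Series(rng.normal(size=10), index=X.sample_ids)
        out = correlate_genes_with_score(X, score)
        r = out["r"].abs().dropna().to_numpy()
        assert (np.diff(r) <= 1e-12).all()
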