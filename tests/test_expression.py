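import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from polpoised.expression import (
    DEConfig,
    ExpressionMatrix,
    ddct_fold_change,
    estimate_prior,
    merge_cohorts,
    moderated_t,
    quantile_normalize,
    select_significant,
    standardize_genes,
    stratify_by_gene,
)

from helpers import binom_bounds_99, pooled_two_sample_t


def em(values, labels=None, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=genes, columns=samples)
    lab = pd.Series(labels or ["all"] * len(samples), index=samples)
    return ExpressionMatrix(df, lab)


class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        m = em(np.tile([[1.0], [5.0], [3.0]], (1, 4)))
        out = quantile_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_two_column_example(self):
        m = em(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]))
        out = quantile_normalize(m).values.to_numpy()
        np.testing.assert_allclose(out[:, 0], [2.5, 3.5, 4.5])
        np.testing.assert_allclose(out[:, 1], [2.5, 3.5, 4.5])

    def test_columns_share_distribution(self, rng):
        m = em(rng.normal(size=(50, 6)) * rng.uniform(0.5, 3, size=6))
        out = quantile_normalize(m).values.to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 6):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-12)

    def test_ties_get_mean_of_targets(self):
        m = em(np.array([[1.0, 1.0], [1.0, 2.0], [3.0, 3.0]]))
        out = quantile_normalize(m).values.to_numpy()
        # tied inputs in column 0 share one value
        assert out[0, 0] == out[1, 0]

    def test_single_sample_raises(self):
        with pytest.raises(ValueError):
            quantile_normalize(em(np.ones((3, 1))))


class TestModeratedT:
    def _null_data(self, rng, n_genes=500, n=5):
        x = rng.standard_normal((n_genes, 2 * n))
        labels = ["a"] * n + ["b"] * n
        df = pd.DataFrame(x, index=[f"g{i}" for i in range(n_genes)],
                          columns=[f"s{i}" for i in range(2 * n)])
        return df, labels

    def test_d0_zero_equals_pooled_t(self, rng):
        df, labels = self._null_data(rng)
        out = moderated_t(df, labels, DEConfig(prior_df=0.0, prior_var=1.0),
                          group_pos="a", group_neg="b")
        t_ref, p_ref = pooled_two_sample_t(
            df.iloc[:, :5].to_numpy(), df.iloc[:, 5:].to_numpy()
        )
        np.testing.assert_allclose(out["t_mod"].to_numpy(), t_ref, atol=1e-10)
        np.testing.assert_allclose(out["p"].to_numpy(), p_ref, atol=1e-10)

    def test_d0_infinite_uses_prior_variance(self, rng):
        df, labels = self._null_data(rng)
        out = moderated_t(
            df, labels, DEConfig(prior_df=math.inf, prior_var=2.0),
            group_pos="a", group_neg="b",
        )
        logfc = out["logFC"].to_numpy()
        expected = logfc / np.sqrt(2.0 * (1 / 5 + 1 / 5))
        np.testing.assert_allclose(out["t_mod"].to_numpy(), expected, atol=1e-12)

    def test_global_null_calibration(self):
        rng = np.random.default_rng(2024)
        x = rng.standard_normal((2000, 10))
        df = pd.DataFrame(x, index=[f"g{i}" for i in range(2000)],
                          columns=[f"s{i}" for i in range(10)])
        out = moderated_t(df, ["a"] * 5 + ["b"] * 5, DEConfig(), group_pos="a")
        rate = (out["p"] < 0.05).mean()
        lo, hi = binom_bounds_99(0.05, 2000)
        assert lo <= rate <= hi

    def test_logfc_sign_and_direction(self):
        df = pd.DataFrame(
            {
                "s1": [10.0, 1.0], "s2": [10.1, 1.1],
                "s3": [1.0, 10.0], "s4": [1.2, 10.2],
            },
            index=["gu", "gd"],
        )
        out = moderated_t(df, ["a", "a", "b", "b"], group_pos="a", group_neg="b")
        assert out.loc["gu", "direction"] == "up"
        assert out.loc["gd", "direction"] == "down"

    def test_sign_invariant_to_common_affine(self, rng):
        df, labels = self._null_data(rng, n_genes=50)
        out1 = moderated_t(df, labels, group_pos="a")
        out2 = moderated_t(df * 3.0 + 7.0, labels, group_pos="a")
        assert (out1["direction"] == out2["direction"]).all()

    def test_needs_two_groups_and_replicates(self):
        df = pd.DataFrame(np.ones((3, 3)), columns=["s1", "s2", "s3"])
        with pytest.raises(ValueError):
            moderated_t(df, ["a", "a", "a"])
        with pytest.raises(ValueError):
            moderated_t(df, ["a", "a", "b"])

    def test_prior_estimation_recovers_scale(self, rng):
        # variances from a scaled chi-square around s0^2 = 4
        n, d = 3000, 6
        s2 = 4.0 * rng.chisquare(d, size=n) / d
        d0, s0 = estimate_prior(s2, d)
        assert s0 == pytest.approx(4.0, rel=0.15)
        assert d0 > 20  # homogeneous variances -> strong shrinkage


class TestSelectSignificant:
    def test_topk_matches_alpha_cut_under_null(self, rng):
        p = rng.random(200)
        de = pd.DataFrame({"p": p}, index=[f"g{i}" for i in range(200)])
        k = int((p < 0.05).sum())
        by_rank, agree = select_significant(de, alpha=0.05, top_k=k)
        assert agree
        assert set(by_rank) == set(de.index[de["p"] < 0.05])


class TestStandardizeGenes:
    def test_closed_form_row(self):
        m = em(np.array([[2.0, 4.0, 6.0]]))
        out = standardize_genes(m).values.to_numpy()[0]
        np.testing.assert_allclose(out, [-1.0, 0.0, 1.0])
        out_pop = standardize_genes(m, ddof=0).values.to_numpy()[0]
        np.testing.assert_allclose(out_pop, [-1.2247448, 0, 1.2247448], atol=1e-6)

    def test_idempotent(self, rng):
        m = em(rng.normal(size=(20, 8)))
        once = standardize_genes(m)
        twice = standardize_genes(once)
        np.testing.assert_allclose(
            once.values.to_numpy(), twice.values.to_numpy(), atol=1e-10
        )

    @given(
        scale=st.floats(min_value=0.01, max_value=100),
        shift=st.floats(min_value=-50, max_value=50),
    )
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance(self, scale, shift):
        x = np.array([[1.0, 2.0, 5.0, 9.0]])
        base = standardize_genes(em(x)).values.to_numpy()
        moved = standardize_genes(em(x * scale + shift)).values.to_numpy()
        np.testing.assert_allclose(base, moved, atol=1e-8)

    def test_constant_rows_dropped(self):
        m = em(np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]))
        out = standardize_genes(m)
        assert list(out.gene_ids) == ["G1"]

    def test_moments(self, rng):
        m = em(rng.normal(size=(30, 10)))
        out = standardize_genes(m).values.to_numpy()
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-10)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-10)


class TestMergeCohorts:
    def test_identical_gene_sets(self, rng):
        a = em(rng.normal(size=(5, 3)), labels=["c1"] * 3)
        b = em(rng.normal(size=(5, 4)), labels=["c2"] * 4,
               samples=[f"t{i}" for i in range(4)])
        merged = merge_cohorts([a, b])
        assert len(merged.gene_ids) == 5
        assert merged.values.shape[1] == 7

    def test_intersection(self, rng):
        a = em(rng.normal(size=(3, 2)), genes=["A", "B", "C"])
        b = em(rng.normal(size=(3, 2)), genes=["B", "C", "D"],
               samples=["t0", "t1"])
        merged = merge_cohorts([a, b])
        assert sorted(merged.gene_ids) == ["B", "C"]

    def test_case_insensitive_matching(self, rng):
        a = em(rng.normal(size=(2, 2)), genes=["abc", "xyz"])
        b = em(rng.normal(size=(2, 2)), genes=["ABC", "XYZ"],
               samples=["t0", "t1"])
        assert len(merge_cohorts([a, b]).gene_ids) == 2

    def test_empty_intersection_raises(self, rng):
        a = em(rng.normal(size=(2, 2)), genes=["A", "B"])
        b = em(rng.normal(size=(2, 2)), genes=["C", "D"],
               samples=["t0", "t1"])
        with pytest.raises(ValueError):
            merge_cohorts([a, b])

    def test_labels_kept(self, rng):
        a = em(rng.normal(size=(2, 2)), labels=["c1", "c1"])
        b = em(rng.normal(size=(2, 3)), labels=["c2"] * 3,
               samples=["t0", "t1", "t2"])
        merged = merge_cohorts([a, b])
        assert list(merged.labels) == ["c1", "c1", "c2", "c2", "c2"]


class TestStratifyByGene:
    def test_floor_arithmetic(self, rng):
        m = em(rng.normal(size=(3, 20)), genes=["HER2", "A", "B"])
        pos, neg = stratify_by_gene(m, "HER2", 0.35)
        assert len(pos) == 7 and len(neg) == 7
        assert set(pos).isdisjoint(neg)

    def test_half_split_partitions(self, rng):
        m = em(rng.normal(size=(1, 10)), genes=["HER2"])
        pos, neg = stratify_by_gene(m, "HER2", 0.5)
        assert len(pos) == 5 and len(neg) == 5
        assert set(pos) | set(neg) == set(m.sample_ids)

    def test_orders_by_marker(self):
        vals = np.array([[5.0, 1.0, 3.0, 2.0, 4.0, 0.0]])
        m = em(vals, genes=["HER2"])
        pos, neg = stratify_by_gene(m, "HER2", 1 / 3)
        assert list(pos) == ["s4", "s0"]
        assert list(neg) == ["s5", "s1"]

    def test_missing_gene(self, rng):
        m = em(rng.normal(size=(1, 10)))
        with pytest.raises(KeyError):
            stratify_by_gene(m, "NOPE", 0.35)

    def test_too_small(self, rng):
        m = em(rng.normal(size=(1, 2)), genes=["HER2"])
        with pytest.raises(ValueError):
            stratify_by_gene(m, "HER2", 0.35)


class TestDdct:
    def test_no_change(self):
        assert ddct_fold_change(20, 15, 22, 17) == pytest.approx(1.0)

    def test_doubling(self):
        # ddCt = -1 -> fold 2
        assert ddct_fold_change(19, 15, 20, 15) == pytest.approx(2.0)

    def test_eightfold_down(self):
        # ddCt = 3 -> fold 0.125
        assert ddct_fold_change(23, 15, 20, 15) == pytest.approx(0.125)

    def test_domain(self):
        with pytest.raises(ValueError):
            ddct_fold_change(-1, 15, 20, 15)


class TestExpressionMatrixIO:
    def test_tsv_roundtrip(self, tmp_path, rng):
        m = em(rng.normal(size=(4, 3)), labels=["g1", "g1", "g2"])
        path = tmp_path / "m.tsv"
        m.to_tsv(path)
        back = ExpressionMatrix.read_tsv(path)
        np.testing.assert_allclose(
            back.values.to_numpy(), m.values.to_numpy(), atol=1e-12
        )
        assert list(back.labels) == list(m.labels)

    def test_duplicate_genes_rejected(self):
        df = pd.DataFrame(np.ones((2, 2)), index=["a", "A"], columns=["s1", "s2"])
        with pytest.raises(ValueError):
            ExpressionMatrix(df)
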