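"""Expression preparation: filtering, TMM, RINT, controls, RUV, kneedle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from eqtlkit import simgen, xprep


def counts_obj(counts, samples=None):
    counts = np.asarray(counts)
    n_genes, n_samples = counts.shape
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n_genes)],
            "chrom": "1",
            "start": np.arange(n_genes) * 1000 + 1,
            "end": np.arange(n_genes) * 1000 + 500,
            "strand": ["+", "-"] * (n_genes // 2) + ["+"] * (n_genes % 2),
        }
    )
    return simgen.ExpressionCounts(
        counts=counts,
        genes=genes,
        samples=samples or [f"s{i}" for i in range(n_samples)],
    )


class TestFilter:
    def test_boundary_gene_kept_at_exact_quarter(self):
        # count 5 in exactly ceil(0.25 n) samples qualifies
        n = 10
        row = np.zeros(n, dtype=int)
        row[: int(np.ceil(0.25 * n))] = 5
        c = counts_obj(np.vstack([row, np.full(n, 100)]))
        kept = xprep.filter_low_expression(c)
        assert "g0" in list(kept.genes["gene_id"])

    def test_all_zero_gene_removed(self):
        c = counts_obj(np.vstack([np.zeros(8, int), np.full(8, 50)]))
        kept = xprep.filter_low_expression(c)
        assert list(kept.genes["gene_id"]) == ["g1"]

    def test_24_of_100_samples_is_below_quarter(self):
        row = np.zeros(100, dtype=int)
        row[:24] = 99
        c = counts_obj(np.vstack([row, np.full(100, 50)]))
        kept = xprep.filter_low_expression(c)
        assert "g0" not in list(kept.genes["gene_id"])

    def test_order_preserved(self):
        rng = np.random.default_rng(0)
        c = counts_obj(rng.integers(5, 100, size=(20, 12)))
        kept = xprep.filter_low_expression(c)
        assert list(kept.genes["gene_id"]) == [f"g{i}" for i in range(20)]


class TestTmm:
    def test_identical_samples_give_unit_factors(self):
        rng = np.random.default_rng(1)
        col = rng.integers(1, 500, size=200)
        counts = np.tile(col[:, None], (1, 5))
        assert np.allclose(xprep.tmm_factors(counts), 1.0)

    def test_pure_depth_change_is_absorbed_by_library_size(self):
        rng = np.random.default_rng(2)
        base = rng.integers(5, 400, size=(500, 4))
        counts = base.copy()
        counts[:, 2] = base[:, 2] * 2  # doubled depth, no composition change
        f = xprep.tmm_factors(counts)
        assert abs(f[2] - 1.0) < 0.02

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 1000, size=(300, 6))
        f = xprep.tmm_factors(counts)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_sample_rejected(self):
        counts = np.zeros((10, 3), int)
        counts[:, 0] = 5
        with pytest.raises(ValueError):
            xprep.tmm_factors(counts)


class TestRint:
    def test_three_point_example(self):
        out = xprep.rank_inverse_normal([3, 1, 2])
        expected = stats.norm.ppf([2.5 / 3, 0.5 / 3, 1.5 / 3])
        assert np.allclose(out, expected, atol=1e-4)
        assert np.allclose(out, [0.9674, -0.9674, 0.0], atol=1e-4)

    @given(st.integers(min_value=1, max_value=30))
    @settings(max_examples=20, deadline=None)
    def test_odd_n_distinct_input_sums_to_zero(self, half):
        n = 2 * half + 1
        v = np.random.default_rng(half).permutation(n).astype(float)
        assert xprep.rank_inverse_normal(v).sum() == pytest.approx(0.0, abs=1e-10)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        v = rng.standard_normal(40)
        assert np.allclose(
            xprep.rank_inverse_normal(v), xprep.rank_inverse_normal(np.exp(v))
        )

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            xprep.rank_inverse_normal([2.0, 2.0, 2.0])

    def test_output_is_standard_normal_by_ks(self):
        rng = np.random.default_rng(5)
        v = rng.exponential(size=200)
        out = xprep.rank_inverse_normal(v)
        assert stats.kstest(out, "norm").pvalue > 0.01


class TestControlGenes:
    def test_planted_housekeeping_genes_selected(self):
        rng = np.random.default_rng(6)
        n_genes, n = 500, 60
        base = rng.uniform(4, 8, size=n_genes)
        mat = base[:, None] + rng.normal(0, 1.0, size=(n_genes, n))
        stable = rng.choice(n_genes, size=10, replace=False)
        mat[stable] = 10.0 + rng.normal(0, 0.005, size=(10, n))  # high, tight
        pheno = xprep.PhenotypeMatrix(
            values=pd.DataFrame(mat, index=[f"g{i}" for i in range(n_genes)])
        )
        picked = xprep.select_control_genes(pheno, n_top_expressed=200, n_controls=10)
        assert set(picked) == {f"g{i}" for i in stable}

    def test_zero_sd_gene_always_selected(self):
        rng = np.random.default_rng(7)
        mat = rng.normal(5, 1, size=(50, 30))
        mat[3] = 6.0  # constant
        pheno = xprep.PhenotypeMatrix(
            values=pd.DataFrame(mat, index=[f"g{i}" for i in range(50)])
        )
        picked = xprep.select_control_genes(pheno, n_top_expressed=50, n_controls=5)
        assert "g3" in picked

    def test_requested_count_returned(self):
        rng = np.random.default_rng(8)
        mat = rng.normal(5, 1, size=(3000, 40))
        pheno = xprep.PhenotypeMatrix(
            values=pd.DataFrame(mat, index=[f"g{i}" for i in range(3000)])
        )
        picked = xprep.select_control_genes(pheno, n_top_expressed=2000, n_controls=700)
        assert len(picked) == 700

    def test_truncates_with_warning_when_short(self):
        rng = np.random.default_rng(9)
        mat = rng.normal(5, 1, size=(100, 20))
        pheno = xprep.PhenotypeMatrix(
            values=pd.DataFrame(mat, index=[f"g{i}" for i in range(100)])
        )
        with pytest.warns(UserWarning):
            picked = xprep.select_control_genes(pheno, 500, 200)
        assert len(picked) == 100


class TestRuvFactors:
    def _pheno(self, mat, ids):
        return xprep.PhenotypeMatrix(values=pd.DataFrame(mat, index=ids))

    def test_k_zero_gives_empty_matrix(self):
        mat = np.random.default_rng(10).normal(size=(20, 15))
        pheno = self._pheno(mat, [f"g{i}" for i in range(20)])
        f = xprep.ruv_factors(pheno, [f"g{i}" for i in range(20)], 0)
        assert f.shape == (15, 0)

    def test_recovers_planted_factor(self):
        rng = np.random.default_rng(11)
        n, n_controls = 200, 300
        truth = rng.standard_normal(n)
        load = rng.normal(0, 1.0, size=n_controls)
        mat = np.outer(load, truth) + rng.normal(0, 1.0, size=(n_controls, n))
        pheno = self._pheno(mat, [f"g{i}" for i in range(n_controls)])
        f = xprep.ruv_factors(pheno, list(pheno.values.index), 1)
        assert abs(np.corrcoef(f[:, 0], truth)[0, 1]) > 0.99

    def test_factor_columns_orthogonal(self):
        rng = np.random.default_rng(12)
        mat = rng.normal(size=(80, 50))
        pheno = self._pheno(mat, [f"g{i}" for i in range(80)])
        f = xprep.ruv_factors(pheno, list(pheno.values.index), 5)
        gram = f.T @ f
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(gram))

    def test_k_beyond_rank_rejected(self):
        mat = np.random.default_rng(13).normal(size=(5, 8))
        pheno = self._pheno(mat, [f"g{i}" for i in range(5)])
        with pytest.raises(ValueError):
            xprep.ruv_factors(pheno, list(pheno.values.index), 7)


class TestKneedle:
    def test_straight_line_has_no_knee(self):
        assert xprep.choose_k_kneedle([(k, k) for k in range(7)]) is None

    def test_reference_curve_knee_at_two(self):
        curve = [(0, 0), (1, 5), (2, 7), (3, 8), (4, 8.5), (5, 8.8), (6, 9)]
        assert xprep.choose_k_kneedle(curve) == 2

    def test_concave_curve_knee_is_difference_argmax(self):
        ks = np.arange(0, 11)
        ys = np.sqrt(ks)
        curve = list(zip(ks, ys))
        # oracle: exhaustive evaluation of the normalized difference curve
        xn = ks / ks.max()
        yn = ys / ys.max()
        expected = int(ks[np.argmax(yn - xn)])
        assert xprep.choose_k_kneedle(curve) == expected

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            xprep.choose_k_kneedle([(0, 0), (1, 1), (2, 3)])

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError):
            xprep.choose_k_kneedle([(0, 0), (2, 1), (1, 2), (3, 3), (4, 4)])


def test_prepared_phenotypes_record_provenance():
    rng = np.random.default_rng(14)
    c = counts_obj(rng.integers(10, 500, size=(30, 40)))
    pheno = xprep.prepare_phenotypes(c)
    assert pheno.provenance == ["filter", "tmm", "rint"]
    prep = xprep.ruv_prep_matrix(c, rng.normal(size=(40, 2)))
    assert prep.provenance == ["filter", "tmm", "log_cpm", "covariate_regression"]
    # RINT rows are centered
    assert np.allclose(pheno.values.to_numpy().mean(axis=1), 0.0, atol=1e-8)


def test_regress_out_removes_covariate_signal():
    rng = np.random.default_rng(15)
    cov = rng.standard_normal((50, 2))
    mat = np.outer(np.ones(10), cov[:, 0]) + rng.normal(0, 0.1, size=(10, 50))
    cleaned = xprep.regress_out(mat, cov)
    for row in cleaned:
        assert abs(np.corrcoef(row, cov[:, 0])[0, 1]) < 0.2
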