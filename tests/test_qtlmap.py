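"""cis-eQTL mapping: nominal scan, beta null, permutations, FDR, conditional."""

import numpy as np
import pytest
from scipy import stats

from eqtlkit import qtlmap, simgen


@pytest.fixture(scope="module")
def geno(small_pop):
    return simgen.simulate_genotypes(small_pop, 300, seed=101)


TSS = 60_000


class TestNominalScan:
    def test_noiseless_phenotype_recovers_slope_exactly(self, geno):
        y = 2.0 * geno.dosages[:, 10]
        recs = qtlmap.nominal_scan(y, geno, None, tss=TSS)
        rec = [r for r in recs if r.variant_id == geno.variants["variant_id"][10]][0]
        assert rec.slope == pytest.approx(2.0, abs=1e-10)
        assert rec.nominal_p <= 1e-250  # numeric floor regime

    def test_null_gene_pvalues_are_uniform(self, geno):
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(200):
            y = rng.standard_normal(geno.n_samples)
            recs = qtlmap.nominal_scan(y, geno, None, tss=TSS)
            pvals.append(recs[0].nominal_p)  # one fixed variant per draw
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_orthogonal_covariate_leaves_slope_unchanged(self, geno):
        rng = np.random.default_rng(1)
        y = geno.dosages[:, 5] + rng.standard_normal(geno.n_samples)
        base = qtlmap.nominal_scan(y, geno, None, tss=TSS)
        # construct a covariate orthogonal to dosage 5 and to the intercept
        c = rng.standard_normal(geno.n_samples)
        d = geno.dosages[:, 5]
        design = np.column_stack([np.ones_like(d), d])
        c -= design @ np.linalg.lstsq(design, c, rcond=None)[0]
        adj = qtlmap.nominal_scan(y, geno, c[:, None], tss=TSS)
        v5 = geno.variants["variant_id"][5]
        s0 = [r.slope for r in base if r.variant_id == v5][0]
        s1 = [r.slope for r in adj if r.variant_id == v5][0]
        assert s0 == pytest.approx(s1, abs=1e-10)

    def test_window_and_maf_filters(self, geno):
        y = np.random.default_rng(2).standard_normal(geno.n_samples)
        narrow = qtlmap.nominal_scan(y, geno, None, tss=TSS, window=10_000)
        assert all(abs(r.distance_to_tss) <= 10_000 for r in narrow)
        high_maf = qtlmap.nominal_scan(y, geno, None, tss=TSS, maf_min=0.3)
        assert all(r.maf >= 0.3 for r in high_maf)

    def test_strand_flip_negates_distance_only(self, geno):
        y = np.random.default_rng(3).standard_normal(geno.n_samples)
        plus = qtlmap.nominal_scan(y, geno, None, tss=TSS, strand="+")
        minus = qtlmap.nominal_scan(y, geno, None, tss=TSS, strand="-")
        for a, b in zip(plus, minus):
            assert a.distance_to_tss == -b.distance_to_tss
            assert a.nominal_p == b.nominal_p
            assert a.slope == b.slope


class TestBetaNull:
    def test_uniform_minima_fit_beta_1_1(self):
        rng = np.random.default_rng(4)
        fit = qtlmap.fit_beta_null(rng.uniform(size=1000))
        assert fit.a == pytest.approx(1.0, abs=0.15)
        assert fit.b == pytest.approx(1.0, abs=0.15)

    def test_min_of_m_uniforms_fits_beta_1_m(self):
        rng = np.random.default_rng(5)
        minima = rng.uniform(size=(1000, 100)).min(axis=1)
        fit = qtlmap.fit_beta_null(minima)
        assert fit.a == pytest.approx(1.0, rel=0.15)
        assert fit.b == pytest.approx(100.0, rel=0.15)

    def test_mle_dominates_moment_estimate(self):
        rng = np.random.default_rng(6)
        p = np.clip(rng.beta(0.9, 40.0, size=500), 1e-12, 1 - 1e-12)
        fit = qtlmap.fit_beta_null(p)
        a0, b0 = qtlmap.beta_moment_estimate(p)
        ll = lambda a, b: stats.beta.logpdf(p, a, b).sum()
        assert ll(fit.a, fit.b) >= ll(a0, b0) - 1e-6

    def test_degenerate_vector_rejected(self):
        with pytest.raises(ValueError):
            qtlmap.fit_beta_null(np.full(200, 0.5))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            qtlmap.fit_beta_null(np.random.default_rng(7).uniform(size=50))


class TestPermutationPass:
    def test_deterministic_given_seed(self, geno):
        y = np.random.default_rng(8).standard_normal(geno.n_samples)
        a = qtlmap.permutation_pass(y, geno, None, tss=TSS, n_perm=200, seed=9)
        b = qtlmap.permutation_pass(y, geno, None, tss=TSS, n_perm=200, seed=9)
        assert a.adjusted_p == b.adjusted_p
        assert a.lead == b.lead
        assert (a.beta_null.a, a.beta_null.b) == (b.beta_null.a, b.beta_null.b)

    def test_median_permutation_p_maps_to_half(self, geno):
        # a lead p equal to the median of the permutation minima has
        # beta-CDF ~ 0.5
        rng = np.random.default_rng(10)
        vals = []
        for rep in range(10):
            y = rng.standard_normal(geno.n_samples)
            res = qtlmap.permutation_pass(y, geno, None, tss=TSS, n_perm=1000,
                                          seed=rep)
            vals.append(
                res.beta_null.cdf(
                    float(stats.beta.ppf(0.5, res.beta_null.a, res.beta_null.b))
                )
            )
        assert np.allclose(vals, 0.5, atol=0.05)

    def test_adjusted_tracks_empirical_p(self, geno):
        rng = np.random.default_rng(11)
        adj, emp = [], []
        for rep in range(60):
            y = rng.standard_normal(geno.n_samples)
            if rep % 3 == 0:  # mix in signal genes
                y += 0.3 * geno.dosages[:, rep % geno.n_variants]
            res = qtlmap.permutation_pass(y, geno, None, tss=TSS, n_perm=500,
                                          seed=rep)
            adj.append(res.adjusted_p)
            emp.append(res.empirical_p)
        rho = stats.spearmanr(adj, emp).statistic
        assert rho > 0.99

    def test_low_perm_count_rejected(self, geno):
        with pytest.raises(ValueError):
            qtlmap.permutation_pass(
                np.zeros(geno.n_samples), geno, None, tss=TSS, n_perm=50, seed=0
            )


class TestStorey:
    def test_pure_null_pi0_near_one(self):
        p = np.random.default_rng(12).uniform(size=10_000)
        pi0, q = qtlmap.storey_qvalues(p)
        assert 0.9 <= pi0 <= 1.0

    def test_mixture_pi0_recovered(self):
        rng = np.random.default_rng(13)
        p = np.concatenate(
            [rng.uniform(size=8000), rng.beta(0.05, 1.0, size=2000)]
        )
        p = np.clip(p, 1e-300, 1.0)
        pi0, _ = qtlmap.storey_qvalues(p)
        assert 0.75 <= pi0 <= 0.85

    def test_qvalues_monotone_in_p(self):
        p = np.random.default_rng(14).uniform(size=2000)
        _, q = qtlmap.storey_qvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_small_input_falls_back_to_bh(self):
        p = np.linspace(0.01, 0.9, 50)
        with pytest.warns(UserWarning):
            pi0, q = qtlmap.storey_qvalues(p)
        assert pi0 == 1.0

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            qtlmap.storey_qvalues(np.array([0.0, 0.5] + [0.3] * 200))


class TestPi1:
    def test_uniform_replication_gives_low_pi1(self):
        p = np.random.default_rng(15).uniform(size=5000)
        assert qtlmap.pi1_replication(p) < 0.1

    def test_strong_replication_gives_high_pi1(self):
        p = np.full(500, 1e-7)
        assert qtlmap.pi1_replication(p) >= 0.95

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            qtlmap.pi1_replication(np.full(50, 0.5))


class TestConditional:
    def test_not_significant_gene_rejected(self, geno):
        y = np.random.default_rng(16).standard_normal(geno.n_samples)
        with pytest.raises(ValueError):
            qtlmap.conditional_scan(
                y, geno, None, tss=TSS, threshold=1e-6, n_perm=200, seed=0
            )

    def test_single_causal_yields_one_signal(self, geno):
        rng = np.random.default_rng(17)
        d = geno.dosages[:, 10]
        beta = simgen.effect_for_variance(0.15, d)
        y = beta * d + rng.standard_normal(geno.n_samples)
        sig = qtlmap.conditional_scan(
            y, geno, None, tss=TSS, threshold=0.01, n_perm=300, seed=1
        )
        assert len(sig.leads) == 1

    def test_two_distant_causals_recovered(self, geno):
        rng = np.random.default_rng(18)
        # variants in different LD blocks: indices 10 (block 0) and 50 (block 2)
        d1, d2 = geno.dosages[:, 10], geno.dosages[:, 50]
        assert np.corrcoef(d1, d2)[0, 1] ** 2 < 0.05
        y = (
            simgen.effect_for_variance(0.12, d1) * d1
            + simgen.effect_for_variance(0.12, d2) * d2
            + rng.standard_normal(geno.n_samples)
        )
        sig = qtlmap.conditional_scan(
            y, geno, None, tss=TSS, threshold=0.01, n_perm=300, seed=2
        )
        assert len(sig.leads) == 2
        lead_blocks = sorted(
            int(geno.variants.index[geno.variants["variant_id"] == l.variant_id][0])
            // 20
            for l in sig.leads
        )
        assert lead_blocks == [0, 2]


def test_tss_respects_strand():
    assert qtlmap.tss_of(100, 500, "+") == 100
    assert qtlmap.tss_of(100, 500, "-") == 500
    with pytest.raises(ValueError):
        qtlmap.tss_of(1, 2, "*")
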