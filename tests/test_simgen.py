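"""Generator properties: LD structure, planted effects, GWAS calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from eqtlkit import simgen


def test_same_seed_gives_identical_matrices(small_pop):
    a = simgen.simulate_genotypes(small_pop, 50, seed=7)
    b = simgen.simulate_genotypes(small_pop, 50, seed=7)
    assert np.array_equal(a.dosages, b.dosages)
    pd.testing.assert_frame_equal(a.variants, b.variants)


def test_dosages_are_hard_calls_in_range(panel300):
    assert panel300.dosages.min() >= 0
    assert panel300.dosages.max() <= 2
    assert np.array_equal(panel300.dosages, np.round(panel300.dosages))


def test_realized_maf_close_to_target_at_large_n():
    pop = simgen.PopulationModel(n_variants=40, maf_range=(0.1, 0.4))
    panel = simgen.define_variant_panel(pop, seed=3)
    g = simgen.simulate_genotypes(pop, 800, seed=5, panel=panel)
    assert np.all(np.abs(g.variants["maf"].to_numpy()
                         - panel["target_maf"].to_numpy()) < 0.05)


def _mean_r2(geno, pairs):
    vals = []
    d = geno.dosages
    for i, j in pairs:
        sd_i, sd_j = d[:, i].std(), d[:, j].std()
        if sd_i > 0 and sd_j > 0:
            vals.append(np.corrcoef(d[:, i], d[:, j])[0, 1] ** 2)
    return float(np.mean(vals))


def test_ld_decays_with_distance():
    pop = simgen.PopulationModel(
        n_variants=100, ld_decay=1e-5, block_size=50, region_span=200_000
    )
    g = simgen.simulate_genotypes(pop, 500, seed=11)
    pos = g.variants["pos"].to_numpy()
    adjacent = [
        (i, i + 1) for i in range(99) if i // 50 == (i + 1) // 50
    ]
    distant = [
        (i, j)
        for i in range(100)
        for j in range(i + 1, 100)
        if abs(int(pos[j]) - int(pos[i])) > 50_000
    ]
    assert _mean_r2(g, adjacent) > _mean_r2(g, distant)


def test_large_decay_gives_independence():
    pop = simgen.PopulationModel(
        n_variants=60, ld_decay=1.0, block_size=20, region_span=120_000
    )
    g = simgen.simulate_genotypes(pop, 500, seed=13)
    adjacent = [(i, i + 1) for i in range(59) if i // 20 == (i + 1) // 20]
    assert _mean_r2(g, adjacent) < 0.05


def test_rejects_bad_population_parameters():
    with pytest.raises(ValueError):
        simgen.PopulationModel(maf_range=(0.0, 0.5))
    with pytest.raises(ValueError):
        simgen.PopulationModel(ld_decay=-1.0)
    with pytest.raises(ValueError):
        simgen.PopulationModel(block_size=0)
    with pytest.raises(ValueError):
        simgen.simulate_genotypes(simgen.PopulationModel(), 1, seed=0)


def test_null_effects_leave_expression_uncorrelated(panel300, one_gene):
    arch = simgen.CausalArchitecture(effects=[], gwas=[])
    rs = []
    for rep in range(10):
        expr = simgen.simulate_expression(
            panel300, arch, one_gene, study="s", seed=rep
        )
        log_counts = np.log1p(expr.counts[0])
        rs.append(np.corrcoef(panel300.dosages[:, 15], log_counts)[0, 1])
    assert np.all(np.abs(rs) < 3.0 / np.sqrt(300))


def test_requested_variance_fraction_is_realized(panel300, one_gene):
    r2 = []
    for rep in range(50):
        beta = simgen.effect_for_variance(0.10, panel300.dosages[:, 15])
        arch = simgen.CausalArchitecture(
            effects=[
                simgen.GeneEffect("g0", 15, beta, frozenset({"s"}))
            ],
            gwas=[],
        )
        expr = simgen.simulate_expression(
            panel300, arch, one_gene, study="s", seed=100 + rep
        )
        d = panel300.dosages[:, 15]
        r2.append(np.corrcoef(d, expr.latent_values[0])[0, 1] ** 2)
    assert 0.05 < np.mean(r2) < 0.15


def test_amplification_scales_fitted_slope(panel300, one_gene):
    beta = simgen.effect_for_variance(0.10, panel300.dosages[:, 15])
    arch = simgen.CausalArchitecture(
        effects=[
            simgen.GeneEffect(
                "g0", 15, beta, frozenset({"a", "b"}), amplification={"a": 2.0}
            )
        ],
        gwas=[],
    )
    d = panel300.dosages[:, 15]
    slopes = {}
    for study in ("a", "b"):
        expr = simgen.simulate_expression(
            panel300, arch, one_gene, study=study, seed=99
        )
        slopes[study] = np.polyfit(d, expr.latent_values[0], 1)[0]
    assert slopes["a"] / slopes["b"] == pytest.approx(2.0, rel=0.2)


def test_variance_fraction_of_one_rejected(panel300):
    with pytest.raises(ValueError):
        simgen.effect_for_variance(1.0, panel300.dosages[:, 0])


class TestGwasSummary:
    def test_null_lambda_gives_standard_normal_margins(self, small_pop):
        g = simgen.simulate_genotypes(small_pop, 400, seed=21)
        zs = np.array(
            [
                simgen.simulate_gwas_summary(g, 10, 0.0, 5000, seed=r).table["z"]
                for r in range(200)
            ]
        )
        # E|z| = sqrt(2/pi) for N(0,1); SE of the mean of 200 |z| draws
        expected = np.sqrt(2.0 / np.pi)
        se = np.sqrt(1.0 - 2.0 / np.pi) / np.sqrt(200)
        mean_abs = np.abs(zs).mean(axis=0)
        assert np.all(np.abs(mean_abs - expected) < 3 * se + 0.05)

    def test_mean_z_at_causal_matches_lambda(self, small_pop):
        g = simgen.simulate_genotypes(small_pop, 400, seed=22)
        z_causal = [
            simgen.simulate_gwas_summary(g, 15, 8.0, 5000, seed=r).table["z"][15]
            for r in range(200)
        ]
        assert np.mean(z_causal) == pytest.approx(8.0, abs=3.0 / np.sqrt(200) + 0.1)

    def test_mean_z_at_ld_partner_scales_with_r(self, small_pop):
        g = simgen.simulate_genotypes(small_pop, 400, seed=23)
        d = g.dosages
        causal = 15
        # pick the partner whose dosage correlation is closest to 0.5
        rs = np.array(
            [
                np.corrcoef(d[:, j], d[:, causal])[0, 1] if j != causal else 1.0
                for j in range(g.n_variants)
            ]
        )
        j = int(np.argmin(np.abs(np.abs(rs) - 0.5)))
        r_true = simgen.regularized_ld(d)[j, causal]
        z_j = [
            simgen.simulate_gwas_summary(g, causal, 8.0, 5000, seed=r).table["z"][j]
            for r in range(200)
        ]
        assert np.mean(z_j) == pytest.approx(8.0 * r_true, abs=3.0 / np.sqrt(200) + 0.15)

    def test_z_equals_beta_over_se(self, small_pop):
        g = simgen.simulate_genotypes(small_pop, 200, seed=24)
        trk = simgen.simulate_gwas_summary(g, 5, 4.0, 1000, seed=0)
        assert np.allclose(trk.table["z"], trk.table["beta"] / trk.table["se"])

    def test_invalid_arguments(self, small_pop):
        g = simgen.simulate_genotypes(small_pop, 100, seed=25)
        with pytest.raises(ValueError):
            simgen.simulate_gwas_summary(g, 5, np.inf, 1000, seed=0)
        with pytest.raises(ValueError):
            simgen.simulate_gwas_summary(g, 5, 1.0, 0, seed=0)
        with pytest.raises(ValueError):
            simgen.simulate_gwas_summary(g, 999, 1.0, 1000, seed=0)


class TestScenarios:
    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            simgen.make_scenario("no-such-scenario", seed=0)

    def test_null_scenario_has_no_effects(self):
        b = simgen.make_scenario("null", seed=5)
        assert b.truth.effects == []
        assert all(v == "none" for v in b.labels.values())
        assert all(sig.lam == 0.0 for sig in b.truth.gwas)

    def test_disease_unique_structure(self):
        b = simgen.make_scenario("disease-unique", seed=5)
        eff = b.truth.effects[0]
        assert eff.studies == frozenset({"disease"})
        assert b.truth.gwas[0].matches_eqtl
        assert b.truth.gwas[0].causal_index == eff.causal_index
        assert b.labels["gene_000"] == "novel"

    def test_distinct_causal_variants_in_low_ld(self):
        b = simgen.make_scenario("distinct-causal", seed=5)
        eff = b.truth.effects[0]
        sig = b.truth.gwas[0]
        assert not sig.matches_eqtl
        geno = b.studies["disease"][0]
        r = np.corrcoef(
            geno.dosages[:, eff.causal_index], geno.dosages[:, sig.causal_index]
        )[0, 1]
        assert r * r < 0.05

    def test_studies_share_the_variant_panel(self):
        b = simgen.make_scenario("shared-coloc", seed=6)
        panels = [g.variants for g, _ in b.studies.values()]
        for other in panels[1:]:
            assert list(panels[0]["variant_id"]) == list(other["variant_id"])

    def test_sample_sizes_follow_configuration(self):
        b = simgen.make_scenario("null", seed=6)
        sizes = {s: g.n_samples for s, (g, _) in b.studies.items()}
        assert sizes == simgen.DEFAULT_SAMPLE_SIZES
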