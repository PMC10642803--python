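"""REML engine: external oracle, balanced-data identities, EM, LRT, PEV."""

import numpy as np
import pandas as pd
import pytest

import metsel
from metsel import anova_components
from metsel.mixed_model import em_loglik_path
from metsel.synthetic import SimulationSpec, TraitSim
from conftest import FRY_LIKE


@pytest.fixture(scope="module")
def oracle_dataset():
    """Tiny fixture whose REML solution was computed independently."""
    spec = SimulationSpec(g=6, e=5, b=2, seed=7, block_sd_scale=0.4,
                          traits=(FRY_LIKE,))
    dataset, _ = metsel.simulate_met(spec)
    return dataset


class TestAgainstIndependentReml:
    """Frozen reference values from an independent mixed-model REML
    implementation (lme4::lmer with the identical design coding) on the
    6 x 5 x 2 fixture."""

    LME4 = {
        "sigma2_g": 6.673232, "sigma2_e": 35.539898,
        "sigma2_gxe": 2.821618, "sigma2_eps": 15.318693,
        "loglik": -172.8144, "mu": 21.50786,
        "blups": [3.5918998, -1.3135103, 1.1058777,
                  -2.9696708, -0.7709835, 0.3563871],
    }

    def test_components_and_loglik(self, oracle_dataset):
        fit = metsel.fit_random_model(oracle_dataset, "FRY", with_blues=False)
        c = fit.components
        for key in ("sigma2_g", "sigma2_e", "sigma2_gxe", "sigma2_eps"):
            assert getattr(c, key) == pytest.approx(self.LME4[key], rel=1e-4)
        assert c.loglik == pytest.approx(self.LME4["loglik"], abs=1e-3)
        assert fit.mu == pytest.approx(self.LME4["mu"], abs=1e-4)

    def test_genotype_blups(self, oracle_dataset):
        fit = metsel.fit_random_model(oracle_dataset, "FRY", with_blues=False)
        np.testing.assert_allclose(
            fit.blups_genotype.to_numpy(), self.LME4["blups"], atol=1e-5)


class TestBalancedIdentities:
    def test_reml_equals_anova_under_balance(self, small_balanced, small_fit):
        dataset, _ = small_balanced
        anova = anova_components(dataset, "FRY")
        reml = small_fit.components.as_dict()
        for key, val in anova.items():
            assert reml[key] == pytest.approx(val, rel=1e-6)

    def test_component_sum_matches_plot_variance_decomposition(self, small_balanced, small_fit):
        dataset, effects = small_balanced
        c = small_fit.components
        e = effects["FRY"]
        # plot-level variance after removing the environment structure
        df = dataset.records
        adj = (df["FRY"].to_numpy() - FRY_LIKE.mean
               - e.environment[df["environment"]].to_numpy())
        total = c.sigma2_g + c.sigma2_gxe + c.sigma2_eps
        assert total == pytest.approx(adj.var(ddof=1), rel=0.25)

    def test_blup_shrinkage_vs_blues(self, small_fit):
        """Genotype BLUPs are shrunken: their spread never exceeds the BLUEs'."""
        assert small_fit.blups_genotype.var() <= small_fit.blues_genotype.var()


class TestRecoveryAndBoundary:
    def test_boundary_when_no_genetic_variance(self):
        """sigma_g^2 = 0 simulations are estimated at/near the boundary."""
        tr = TraitSim("Y", mean=10.0, var_g=0.0, var_e=5.0, var_gxe=2.0,
                      var_eps=4.0)
        near_zero = 0
        n_seeds = 10
        for seed in range(n_seeds):
            ds, _ = metsel.simulate_met(
                SimulationSpec(g=12, e=24, b=2, seed=seed, traits=(tr,)))
            fit = metsel.fit_random_model(ds, "Y", with_blues=False)
            c = fit.components
            near_zero += c.sigma2_g < 0.05 * c.sigma2_eps
        assert near_zero >= 0.7 * n_seeds

    def test_trait_with_zero_variance_errors(self):
        rows = []
        for g in ("G1", "G2"):
            for e in ("E1", "E2", "E3"):
                rows.append({"genotype": g, "environment": e, "block": "B1",
                             "Y": 5.0})
        ds = metsel.METDataset(pd.DataFrame(rows))
        with pytest.raises(ValueError, match="zero variance"):
            metsel.fit_random_model(ds, "Y")


class TestEMReference:
    def test_em_matches_profile_optimizer(self, small_balanced):
        dataset, _ = small_balanced
        em = metsel.fit_random_model(dataset, "FRY", method="em",
                                     tol=1e-10, max_iter=5000, with_blues=False)
        prof = metsel.fit_random_model(dataset, "FRY", with_blues=False)
        for key, val in prof.components.as_dict().items():
            assert em.components.as_dict()[key] == pytest.approx(val, rel=1e-4)

    def test_em_loglik_monotone(self, small_balanced):
        dataset, _ = small_balanced
        path = em_loglik_path(dataset, "FRY", n_iter=30)
        assert all(b >= a - 1e-8 for a, b in zip(path, path[1:]))


class TestLRT:
    def test_model_against_itself_is_zero(self, small_balanced):
        """Refitting the identical model reproduces the same -2 logL."""
        dataset, _ = small_balanced
        a = metsel.fit_random_model(dataset, "FRY", with_blues=False)
        b = metsel.fit_random_model(dataset, "FRY", with_blues=False)
        assert a.components.loglik == pytest.approx(b.components.loglik, abs=1e-6)

    def test_power_for_large_genetic_variance(self):
        tr = TraitSim("Y", mean=10.0, var_g=8.0, var_e=4.0, var_gxe=1.0,
                      var_eps=2.0)
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            ds, _ = metsel.simulate_met(
                SimulationSpec(g=12, e=10, b=2, seed=seed, traits=(tr,)))
            r = metsel.lrt(ds, "Y", "genotype")
            hits += r.p_value < 0.001
        assert hits >= 0.95 * n_seeds

    def test_plain_reference_is_conservative_under_null(self):
        """At a boundary null, the plain chi-square(1) p-value rejects at
        no more than the nominal rate (here over a modest seed batch)."""
        tr = TraitSim("Y", mean=10.0, var_g=4.0, var_e=8.0, var_gxe=0.0,
                      var_eps=4.0)
        rej = 0
        n = 60
        for seed in range(n):
            ds, _ = metsel.simulate_met(
                SimulationSpec(g=8, e=6, b=2, seed=1000 + seed, traits=(tr,)))
            rej += metsel.lrt(ds, "Y", "gei").p_value <= 0.05
        assert rej / n <= 0.08

    def test_block_term_reports_wald_f(self, small_balanced):
        dataset, _ = small_balanced
        r = metsel.lrt(dataset, "FRY", "block")
        assert r.kind == "wald_f" and r.df == 8  # e * (b - 1) contrasts
        assert 0 <= r.p_value <= 1


class TestSelectiveAccuracy:
    def test_limits(self, small_fit):
        fit = small_fit
        s2g = fit.components.sigma2_g
        zero_pev = fit.pev_genotype * 0.0
        full_pev = fit.pev_genotype * 0.0 + s2g
        import dataclasses
        f1 = dataclasses.replace(fit, pev_genotype=zero_pev)
        f0 = dataclasses.replace(fit, pev_genotype=full_pev)
        assert metsel.selective_accuracy(f1) == pytest.approx(1.0)
        assert metsel.selective_accuracy(f0) == pytest.approx(0.0)

    def test_full_scale_accuracy_is_high(self, full_scale_fit):
        """22 x 47 x 3 at published-magnitude components gives the very
        high selective accuracy such trial series report (>= 0.95)."""
        _, _, fit = full_scale_fit
        assert metsel.selective_accuracy(fit) >= 0.95

    def test_pev_within_bounds(self, small_fit):
        pev = small_fit.pev_genotype
        assert (pev > 0).all()
        assert (pev <= small_fit.components.sigma2_g + 1e-9).all()
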