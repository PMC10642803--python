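"""Factor model, ideotype scoring, MTMPS distance and gain tables."""

import numpy as np
import pandas as pd
import pytest

import metsel
from metsel.mtmps import varimax, _display_signs
from conftest import TABLE3_SDI2_LOADINGS, TABLE3_SDI2_EIGENVALUES


class TestFactorModel:
    def test_identity_correlation_keeps_unit_eigenvalues(self):
        rng = np.random.default_rng(0)
        # independent columns -> near-identity correlation
        X = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("ABCD"))
        model = metsel.fit_factor_model(X, n_factors=4)
        assert np.allclose(model.eigenvalues, 1.0, atol=0.25)
        # rotation of near-orthogonal loadings preserves communalities
        assert np.allclose(model.communalities, 1.0, atol=1e-6)

    def test_eigenvalues_sum_to_p(self, correlated_mps_matrix):
        model = metsel.fit_factor_model(correlated_mps_matrix)
        assert model.eigenvalues.sum() == pytest.approx(7.0, abs=1e-9)
        full = metsel.explained_variance_pct(model.eigenvalues, 7)
        assert full.sum() == pytest.approx(100.0, abs=1e-9)

    def test_communalities_invariant_under_rotation(self, correlated_mps_matrix):
        model = metsel.fit_factor_model(correlated_mps_matrix)
        before = (model.loadings_unrotated ** 2).sum(axis=1)
        after = model.communalities
        np.testing.assert_allclose(before, after, atol=1e-9)
        assert ((after >= 0) & (after <= 1 + 1e-12)).all()

    def test_varimax_increases_criterion(self, correlated_mps_matrix):
        model = metsel.fit_factor_model(correlated_mps_matrix)

        def criterion(L):
            sq = L ** 2
            return float((sq.var(axis=0)).sum())

        assert criterion(model.loadings.to_numpy()) >= \
            criterion(model.loadings_unrotated.to_numpy()) - 1e-10

    def test_kaiser_retention_and_loading_recovery(self):
        """A known 3-factor simple structure is retained (eigenvalue >= 1)
        and recovered up to sign/permutation with Tucker congruence >= 0.95."""
        rng = np.random.default_rng(12)
        q, p = 300, 9
        true = np.zeros((p, 3))
        for j in range(p):
            true[j, j % 3] = 0.85
        F = rng.normal(size=(q, 3))
        X = pd.DataFrame(F @ true.T + 0.4 * rng.normal(size=(q, p)),
                         columns=[f"T{j}" for j in range(p)])
        model = metsel.fit_factor_model(X)
        assert model.n_factors == 3
        L = model.loadings.to_numpy()
        # best-match congruence per true factor
        used = set()
        for k in range(3):
            cong = [
                abs(true[:, k] @ L[:, j])
                / np.sqrt((true[:, k] ** 2).sum() * (L[:, j] ** 2).sum())
                for j in range(3)
            ]
            j = int(np.argmax(cong))
            assert cong[j] >= 0.95
            assert j not in used
            used.add(j)

    def test_published_table_internal_consistency(self):
        """Printed varimax loadings and eigenvalues are self-consistent:
        explained % = lambda/p*100 and communality = row sum of squares."""
        expl = metsel.explained_variance_pct(TABLE3_SDI2_EIGENVALUES, p=7)
        assert expl[0] == pytest.approx(52.0, abs=0.05)
        comm = metsel.communalities_from_loadings(TABLE3_SDI2_LOADINGS)
        assert comm["DRY"] == pytest.approx(0.98, abs=0.01)


class TestIdeotypeAndDistance:
    def test_genotype_at_ideotype_has_zero_distance(self, correlated_mps_matrix):
        X = correlated_mps_matrix.copy()
        X.loc["G01"] = 100.0  # best possible on every trait
        model = metsel.fit_factor_model(X)
        result = metsel.mtmps(model)
        assert result.distances["G01"] == pytest.approx(0.0, abs=1e-9)
        assert result.ranking["G01"] == 1

    def test_sign_flip_leaves_distances_unchanged(self, correlated_mps_matrix):
        model = metsel.fit_factor_model(correlated_mps_matrix)
        r1 = metsel.mtmps(model)
        flipped = model
        flipped.loadings.iloc[:, 0] *= -1.0
        flipped.scores.iloc[:, 0] *= -1.0
        r2 = metsel.mtmps(flipped)
        pd.testing.assert_series_equal(r1.distances, r2.distances, atol=1e-9,
                                       check_exact=False)

    def test_two_trait_hand_computed_scores(self):
        """2-trait toy: F = Z R^-1 A reproduces a hand linear-algebra result."""
        X = pd.DataFrame({"A": [0.0, 50.0, 100.0], "B": [90.0, 70.0, 0.0]},
                         index=["G1", "G2", "G3"])
        model = metsel.fit_factor_model(X, n_factors=1)
        R = model.correlation.to_numpy()
        Z = ((X - X.mean()) / X.std(ddof=1)).to_numpy()
        A = model.loadings.to_numpy()
        expect = Z @ np.linalg.inv(R) @ A
        np.testing.assert_allclose(model.scores.to_numpy(), expect, atol=1e-10)
        ideo = metsel.ideotype_scores(model)
        z_i = ((100.0 - X.mean()) / X.std(ddof=1)).to_numpy()
        np.testing.assert_allclose(
            ideo.to_numpy(), z_i @ np.linalg.inv(R) @ A, atol=1e-10)

    def test_distance_homogeneity(self, correlated_mps_matrix):
        model = metsel.fit_factor_model(correlated_mps_matrix)
        r = metsel.mtmps(model)
        doubled = model
        doubled.scores.loc[:, :] = 2.0 * model.scores.to_numpy()
        r2 = metsel.mtmps(doubled, ideotype=2.0 * r.ideotype)
        pd.testing.assert_series_equal(2.0 * r.distances, r2.distances,
                                       atol=1e-9, check_exact=False)

    def test_selection_count_at_30pct_of_22(self, correlated_mps_matrix):
        model = metsel.fit_factor_model(correlated_mps_matrix)
        result = metsel.mtmps(model, intensity=0.30)
        assert len(result.selected) == 7  # ceiling(0.30 * 22)


class TestContributions:
    def test_sum_to_one_for_all_genotypes(self, correlated_mps_matrix):
        model = metsel.fit_factor_model(correlated_mps_matrix)
        result = metsel.mtmps(model)
        np.testing.assert_allclose(result.contributions.sum(axis=1), 1.0,
                                   atol=1e-12)
        assert (result.contributions.to_numpy() >= 0).all()

    def test_single_factor_deviation(self):
        model = _toy_model()
        scores = pd.DataFrame({"FA1": [0.0, 1.0], "FA2": [0.0, 0.0]},
                              index=["G1", "G2"])
        model.scores = scores
        result = metsel.mtmps(
            model, ideotype=pd.Series({"FA1": 2.0, "FA2": 0.0}))
        assert result.contributions.loc["G2"].tolist() == [1.0, 0.0]

    def test_equal_deviations_uniform(self):
        model = _toy_model()
        model.scores = pd.DataFrame({"FA1": [1.0], "FA2": [1.0]}, index=["G1"])
        result = metsel.mtmps(model, ideotype=pd.Series({"FA1": 0.0, "FA2": 0.0}))
        np.testing.assert_allclose(result.contributions.loc["G1"], [0.5, 0.5])


def _toy_model():
    """Minimal FactorModel shell for distance/contribution arithmetic."""
    from metsel.mtmps import FactorModel
    p = 2
    return FactorModel(
        correlation=pd.DataFrame(np.eye(p), index=["A", "B"], columns=["A", "B"]),
        eigenvalues=pd.Series([1.0, 1.0], index=["PC1", "PC2"]),
        n_factors=2,
        loadings_unrotated=pd.DataFrame(np.eye(p), index=["A", "B"],
                                        columns=["FA1", "FA2"]),
        loadings=pd.DataFrame(np.eye(p), index=["A", "B"],
                              columns=["FA1", "FA2"]),
        communalities=pd.Series([1.0, 1.0], index=["A", "B"]),
        explained_pct=pd.Series([50.0, 50.0], index=["FA1", "FA2"]),
        cumulative_pct=pd.Series([50.0, 100.0], index=["FA1", "FA2"]),
        scores=pd.DataFrame(np.zeros((1, 2)), index=["G1"],
                            columns=["FA1", "FA2"]),
        means=pd.Series([50.0, 50.0], index=["A", "B"]),
        sds=pd.Series([10.0, 10.0], index=["A", "B"]),
    )


class TestSelectionGains:
    def test_published_magnitude_percentage(self):
        # symmetric pair around Xo = 23.80; selecting G2 gives GS = 4.62
        means = pd.DataFrame({"FRY": [23.80 - 4.62, 23.80 + 4.62]},
                             index=["G1", "G2"])
        table = metsel.selection_gains(means, ["G2"], {"FRY": "higher"})
        assert table.loc["FRY", "Xo"] == pytest.approx(23.80)
        assert table.loc["FRY", "GS"] == pytest.approx(4.62, abs=1e-9)
        assert table.loc["FRY", "SG_pct"] == pytest.approx(19.40, abs=0.1)
        assert bool(table.loc["FRY", "goal_met"])

    def test_decrease_direction_goal(self):
        means = pd.DataFrame({"PIA": [2.0, 3.1]}, index=["G1", "G2"])
        table = metsel.selection_gains(means, ["G1"], {"PIA": "lower"})
        assert table.loc["PIA", "GS"] < 0
        assert bool(table.loc["PIA", "goal_met"])
        assert table.loc["PIA", "direction"] == "decrease"

    def test_select_all_zero_gain(self):
        means = pd.DataFrame({"A": [1.0, 2.0], "B": [5.0, 7.0]},
                             index=["G1", "G2"])
        table = metsel.selection_gains(means, ["G1", "G2"], {})
        assert (table["GS"] == 0).all()
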