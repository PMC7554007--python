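import numpy as np
import pandas as pd
import pytest

from radsurv.factor_model import (
    FactorModel,
    MLFactorAnalysis,
    bartlett_scores,
    batch_effect_manova,
    factor_scores,
    fit_factor_model,
    regularized_correlation,
    select_factor_count,
    tucker_congruence,
    varimax,
)
from radsurv.synthetic_data import TabularCohortSpec, generate_tabular_cohort


def _cohort(n=1000, seed=0, **kw):
    df, truth = generate_tabular_cohort(TabularCohortSpec(n=n, seed=seed, **kw))
    X = df[[c for c in df if c.startswith("feat_")]]
    return X, truth


class TestRegularizedCorrelation:
    def test_full_shrinkage_gives_identity(self):
        X, _ = _cohort(n=50)
        R, lam = regularized_correlation(X, penalty=1.0)
        np.testing.assert_allclose(R, np.eye(X.shape[1]), atol=1e-12)

    def test_zero_shrinkage_gives_sample_correlation(self):
        X, _ = _cohort(n=50)
        R, _ = regularized_correlation(X, penalty=0.0)
        np.testing.assert_allclose(R, np.corrcoef(X.T), atol=1e-12)

    def test_auto_selects_small_penalty_when_n_large(self):
        rng = np.random.default_rng(0)
        m_true = rng.normal(size=(20, 20))
        cov = m_true @ m_true.T + 5 * np.eye(20)
        d = np.sqrt(np.diag(cov))
        R_true = cov / np.outer(d, d)
        X = rng.multivariate_normal(np.zeros(20), R_true, size=2000)
        R, lam = regularized_correlation(X, penalty="auto", seed=1)
        assert lam < 0.1
        assert np.linalg.norm(R - R_true, "fro") < 0.05 * np.linalg.norm(
            R_true, "fro"
        ) + 0.6

    def test_shrinkage_monotone_in_offdiagonals(self):
        X, _ = _cohort(n=200)
        prev = None
        for lam in (0.0, 0.3, 0.6, 1.0):
            R, _ = regularized_correlation(X, penalty=lam)
            off = np.abs(R - np.diag(np.diag(R))).sum()
            if prev is not None:
                assert off <= prev + 1e-12
            prev = off

    def test_nonfinite_rejected(self):
        X = np.ones((10, 3))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            regularized_correlation(X, penalty=0.5)


class TestFactorFit:
    def test_identity_correlation_single_factor_is_null(self):
        model = fit_factor_model(np.eye(12), 1)
        assert np.abs(model.loadings.to_numpy()).max() < 0.05
        assert (model.uniquenesses > 0.95).all()

    def test_fitted_correlation_has_unit_diagonal(self):
        X, _ = _cohort(n=400, seed=1)
        R, _ = regularized_correlation(X, penalty=0.05)
        model = fit_factor_model(R, 7)
        np.testing.assert_allclose(
            np.diag(model.fitted_correlation()), 1.0, atol=1e-4
        )

    def test_loading_recovery_with_congruence(self):
        X, truth = _cohort(n=5000, seed=2, p=20, m=3,
                           beta_factors=(0.0, 0.0, 0.0))
        R, _ = regularized_correlation(X, penalty=0.0)
        model = fit_factor_model(R, 3)
        cong, per = tucker_congruence(
            model.loadings.to_numpy(), truth["loadings"]
        )
        assert (per >= 0.95).all()

    def test_rank_one_structure_selects_single_factor(self):
        rho = 0.6
        R = rho * np.ones((10, 10)) + (1 - rho) * np.eye(10)
        m, _ = select_factor_count(R, rule="variance", target=0.5)
        assert m == 1

    def test_kaiser_on_identity_errors(self):
        with pytest.raises(ValueError, match="no eigenvalue"):
            select_factor_count(np.eye(8), rule="kaiser")

    def test_seven_factor_recovery(self):
        X, _ = _cohort(n=2000, seed=3)
        R, _ = regularized_correlation(X, penalty="auto", seed=3)
        m, diag = select_factor_count(R, rule="variance", target=0.75)
        assert m == 7

    def test_varimax_preserves_total_explained_variance(self):
        X, _ = _cohort(n=800, seed=4)
        R, _ = regularized_correlation(X, penalty=0.02)
        raw = fit_factor_model(R, 7, rotation="none")
        rot = fit_factor_model(R, 7, rotation="varimax")
        assert raw.cumulative_variance == pytest.approx(
            rot.cumulative_variance, abs=1e-6
        )

    def test_varimax_on_single_factor_is_identity(self):
        L = np.random.default_rng(0).normal(size=(10, 1))
        np.testing.assert_allclose(varimax(L), L)

    def test_not_positive_definite_rejected(self):
        R = np.ones((4, 4))
        with pytest.raises(ValueError, match="positive definite"):
            fit_factor_model(R, 1)


class TestScores:
    def test_noiseless_scores_recover_factors(self):
        rng = np.random.default_rng(5)
        L = np.zeros((12, 3))
        for j in range(12):
            L[j, j % 3] = 0.95
        F = rng.standard_normal((40, 3))
        Z = F @ L.T  # noiseless common-factor data
        psi = np.full(12, 0.005)
        rec = bartlett_scores(Z, L, psi)
        np.testing.assert_allclose(rec, F, atol=1e-6)

    def test_training_scores_centered(self):
        X, _ = _cohort(n=300, seed=6)
        fa = MLFactorAnalysis(n_factors=7, shrinkage=0.05).fit(X)
        S = fa.transform(X)
        assert np.abs(S.mean(axis=0)).max() < 1e-10

    def test_frozen_transform_matches_training_row(self):
        X, _ = _cohort(n=300, seed=7)
        fa = MLFactorAnalysis(n_factors=7, shrinkage=0.05).fit(X)
        one = fa.transform(X.iloc[[13]])
        pd.testing.assert_frame_equal(one, fa.transform(X).iloc[[13]])

    def test_serialization_round_trip(self, tmp_path):
        X, _ = _cohort(n=300, seed=8)
        fa = MLFactorAnalysis(n_factors=7, shrinkage=0.05).fit(X)
        path = tmp_path / "model.json"
        fa.model_.to_json(path)
        back = FactorModel.from_json(path)
        S1 = factor_scores(X, back)
        S2 = fa.transform(X)
        np.testing.assert_allclose(S1.to_numpy(), S2.to_numpy(), atol=1e-9)

    def test_feature_mismatch_rejected(self):
        X, _ = _cohort(n=200, seed=9)
        fa = MLFactorAnalysis(n_factors=7, shrinkage=0.05).fit(X)
        with pytest.raises(ValueError, match="columns"):
            fa.transform(X.iloc[:, :-1])


class TestManova:
    def _scores(self, n, shift=None, seed=0, m=4):
        rng = np.random.default_rng(seed)
        S = rng.standard_normal((n, m))
        g = np.array(["a"] * (n // 2) + ["b"] * (n - n // 2))
        if shift is not None:
            S[g == "b", shift[0]] += shift[1]
        return pd.DataFrame(S, columns=[f"factor_{i+1}" for i in range(m)]), g

    def test_identical_groups_zero_trace(self):
        S, _ = self._scores(20, seed=1)
        both = pd.concat([S, S], ignore_index=True)
        g = np.array(["a"] * 20 + ["b"] * 20)
        res = batch_effect_manova(both, g)
        assert res["pillai_trace"] == pytest.approx(0.0, abs=1e-12)

    def test_null_trace_small_and_p_unremarkable(self):
        S, g = self._scores(400, seed=2)
        res = batch_effect_manova(S, g)
        assert res["pillai_trace"] < 0.05
        assert res["p_value"] > 0.001

    def test_shifted_factor_detected_and_isolated(self):
        S, g = self._scores(300, shift=(2, 2.0), seed=3)
        res = batch_effect_manova(S, g)
        assert res["p_value"] < 0.001
        uni = res["univariate_p"]
        assert uni["factor_3"] < 0.001
        assert min(uni[f] for f in ("factor_1", "factor_2", "factor_4")) > 1e-4

    def test_null_p_values_roughly_uniform(self):
        # calibration: repeated null MANOVAs give uniform p-values
        from scipy.stats import kstest

        ps = []
        for seed in range(200):
            S, g = self._scores(60, seed=seed + 100, m=3)
            ps.append(batch_effect_manova(S, g)["p_value"])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_too_small_groups_rejected(self):
        S, g = self._scores(8, m=4)
        with pytest.raises(ValueError, match="members"):
            batch_effect_manova(S, np.array(["a"] * 4 + ["b"] * 4))
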