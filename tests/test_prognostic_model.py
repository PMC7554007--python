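import numpy as np
import pandas as pd
import pytest

from radsurv.prognostic_model import (
    CoxRisk,
    bootstrap_ci,
    compare_models,
    fit_cox,
    integrated_auc,
    median_split_km,
    recalibrate_clinical,
    report_frame,
    run_study,
)
from radsurv.synthetic_data import paper_shaped_scenario


def _binary_cohort(n, beta, seed=0, censor_rate=0.045, base=0.1):
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, 0.5, n).astype(float)
    t_ev = rng.exponential(1.0 / (base * np.exp(beta * x)))
    t_c = rng.exponential(1.0 / censor_rate, n) if censor_rate else np.full(n, np.inf)
    t = np.minimum(t_ev, t_c)
    e = (t_ev <= t_c).astype(int)
    return pd.DataFrame({"x": x}), pd.DataFrame({"time": t, "event": e})


class TestCoxFit:
    def test_recovers_log_hazard_ratio_two(self):
        X, y = _binary_cohort(2000, np.log(2.0), seed=1)
        model = fit_cox(X, y)
        assert abs(float(model.coef_["x"]) - np.log(2.0)) < 0.1

    def test_null_covariate_centered_at_zero(self):
        betas = []
        for seed in range(15):
            X, y = _binary_cohort(400, 0.0, seed=seed)
            betas.append(float(fit_cox(X, y).coef_["x"]))
        assert abs(np.mean(betas)) < 0.05

    def test_all_censored_rejected(self):
        X = pd.DataFrame({"x": [0.0, 1.0, 0.0]})
        y = pd.DataFrame({"time": [1, 2, 3], "event": [0, 0, 0]})
        with pytest.raises(ValueError, match="events"):
            fit_cox(X, y)

    def test_missing_covariates_rejected(self):
        X = pd.DataFrame({"x": [0.0, np.nan, 1.0]})
        y = pd.DataFrame({"time": [1, 2, 3], "event": [1, 1, 0]})
        with pytest.raises(ValueError, match="missing"):
            fit_cox(X, y)

    def test_linear_predictor_is_linear_in_coefficients(self):
        X, y = _binary_cohort(300, 0.5, seed=2)
        model = fit_cox(X, y)
        eta = model.predict(X)
        np.testing.assert_allclose(
            eta, X["x"].to_numpy() * float(model.coef_["x"]), atol=1e-12
        )


class TestRecalibration:
    def test_refit_on_same_data_reproduces_coefficients(self):
        X, y = _binary_cohort(500, 0.7, seed=3)
        model = fit_cox(X, y)
        recal = recalibrate_clinical(model, X, y)
        assert float(recal.coef_["x"]) == pytest.approx(
            float(model.coef_["x"]), abs=1e-8
        )

    def test_tracks_validation_effect(self):
        X1, y1 = _binary_cohort(1500, 0.2, seed=4)
        X2, y2 = _binary_cohort(1500, 1.2, seed=5)
        recal = recalibrate_clinical(fit_cox(X1, y1), X2, y2)
        assert abs(float(recal.coef_["x"]) - 1.2) < 0.15

    def test_roster_mismatch_rejected(self):
        X, y = _binary_cohort(100, 0.5, seed=6)
        model = fit_cox(X, y)
        with pytest.raises(ValueError, match="lacks"):
            recalibrate_clinical(model, X.rename(columns={"x": "z"}), y)


class TestIntegratedAUC:
    def test_perfect_ranking_gives_one(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(1.0, 300)
        y = pd.DataFrame({"time": t, "event": np.ones(300, int)})
        assert integrated_auc(-t, y) == pytest.approx(1.0)

    def test_null_risk_centered_at_half(self):
        rng = np.random.default_rng(8)
        vals = []
        for _ in range(60):
            t = rng.exponential(1.0, 300)
            y = pd.DataFrame({"time": t, "event": np.ones(300, int)})
            vals.append(integrated_auc(rng.normal(size=300), y))
        assert np.mean(vals) == pytest.approx(0.5, abs=0.02)

    def test_invariant_to_monotone_transform_of_risk(self):
        rng = np.random.default_rng(9)
        t = rng.exponential(1.0, 200)
        e = rng.binomial(1, 0.7, 200)
        y = pd.DataFrame({"time": t, "event": e})
        risk = rng.normal(size=200)
        a = integrated_auc(risk, y)
        b = integrated_auc(np.exp(2.0 * risk) + 3.0, y)
        assert a == pytest.approx(b, abs=1e-12)

    def test_single_time_no_censoring_equals_mann_whitney(self):
        # cumulative/dynamic AUC at time t with no censoring reduces to the
        # Mann-Whitney statistic between cases (T <= t) and controls (T > t)
        from scipy.stats import rankdata

        rng = np.random.default_rng(10)
        t = rng.exponential(1.0, 150)
        risk = rng.normal(size=150)
        t_star = np.median(t)
        y = pd.DataFrame({"time": t, "event": np.ones(150, int)})
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        s = Surv.from_arrays(np.ones(150, bool), t)
        auc, _ = cumulative_dynamic_auc(s, s, risk, [t_star])
        cases = risk[t <= t_star]
        controls = risk[t > t_star]
        r = rankdata(np.r_[cases, controls])
        u = r[: len(cases)].sum() - len(cases) * (len(cases) + 1) / 2
        mw = u / (len(cases) * len(controls))
        assert auc[0] == pytest.approx(mw, abs=1e-12)

    def test_heavily_censored_matches_pair_counting_oracle(self):
        # with risk = -time, IPCW weights act on fully concordant pairs and
        # AUC(t) is 1 at every usable time, so the integral is exactly 1
        rng = np.random.default_rng(11)
        t_ev = rng.exponential(1.0, 400)
        t_c = rng.exponential(0.7, 400)
        t = np.minimum(t_ev, t_c)
        e = (t_ev <= t_c).astype(int)
        y = pd.DataFrame({"time": t, "event": e})
        assert integrated_auc(-t, y) == pytest.approx(1.0, abs=1e-6)

    def test_no_events_rejected(self):
        y = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0]})
        with pytest.raises(ValueError):
            integrated_auc(np.array([0.1, 0.2]), y)


class TestBootstrap:
    def test_constant_statistic_zero_width(self):
        df = pd.DataFrame({"v": np.arange(50.0)})
        lo, hi = bootstrap_ci(lambda d: 3.14, df, B=200, seed=0)
        assert lo == hi == 3.14

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame({"v": rng.normal(size=80)})
        stat = lambda d: float(d["v"].mean())
        assert bootstrap_ci(stat, df, B=300, seed=42) == bootstrap_ci(
            stat, df, B=300, seed=42
        )

    def test_mean_ci_covers_truth_about_95_percent(self):
        rng = np.random.default_rng(13)
        cover = 0
        reps = 300
        for _ in range(reps):
            df = pd.DataFrame({"v": rng.normal(0.0, 1.0, 60)})
            lo, hi = bootstrap_ci(
                lambda d: float(d["v"].mean()), df, B=200,
                seed=int(rng.integers(2**31)),
            )
            cover += lo <= 0.0 <= hi
        assert cover / reps == pytest.approx(0.95, abs=0.04)

    def test_failing_statistic_rejected(self):
        df = pd.DataFrame({"v": np.arange(10.0)})

        def bad(d):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="failed"):
            bootstrap_ci(bad, df, B=100, seed=0)

    def test_small_b_rejected(self):
        df = pd.DataFrame({"v": np.arange(10.0)})
        with pytest.raises(ValueError):
            bootstrap_ci(lambda d: 0.0, df, B=50, seed=0)


class TestMedianSplitKM:
    def test_strong_signal_separates_arms(self):
        rng = np.random.default_rng(14)
        t = rng.exponential(1.0, 100)
        y = pd.DataFrame({"time": t, "event": np.ones(100, int)})
        out = median_split_km(-t, y)
        assert out["p_value"] < 0.001
        assert out["n_low"] + out["n_high"] == 100

    def test_null_risk_p_uniformish(self):
        rng = np.random.default_rng(15)
        ps = []
        for _ in range(100):
            t = rng.exponential(1.0, 60)
            y = pd.DataFrame({"time": t, "event": np.ones(60, int)})
            ps.append(median_split_km(rng.normal(size=60), y)["p_value"])
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01

    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(16)
        t = rng.exponential(1.0, 80)
        risk = rng.normal(size=80)
        y = pd.DataFrame({"time": t, "event": np.ones(80, int)})
        out = median_split_km(risk, y)
        km = out["km_low"]
        arm_t = np.sort(t[risk <= np.median(risk)])
        for q in arm_t[:-1]:
            emp = np.mean(arm_t > q)
            assert km.predict(q) == pytest.approx(emp, abs=1e-10)

    def test_constant_risk_rejected(self):
        y = pd.DataFrame({"time": np.arange(1.0, 11.0), "event": np.ones(10, int)})
        with pytest.raises(ValueError, match="degenerate"):
            median_split_km(np.ones(10), y)


class TestCompareModels:
    def test_identical_models_null_difference(self):
        rng = np.random.default_rng(17)
        t = rng.exponential(1.0, 120)
        e = rng.binomial(1, 0.7, 120)
        y = pd.DataFrame({"time": t, "event": e})
        risk = rng.normal(size=120)
        out = compare_models(risk, risk.copy(), y, B=200, seed=0)
        assert out["delta_iauc"] == 0.0
        assert out["p_value"] == pytest.approx(1.0)

    def test_informative_model_beats_noise(self):
        rng = np.random.default_rng(18)
        t = rng.exponential(1.0, 400)
        y = pd.DataFrame({"time": t, "event": np.ones(400, int)})
        out = compare_models(-t, rng.normal(size=400), y, B=300, seed=1)
        assert out["delta_iauc"] > 0.2
        assert out["p_value"] < 0.05

    def test_seed_reproducible(self):
        rng = np.random.default_rng(19)
        t = rng.exponential(1.0, 100)
        y = pd.DataFrame({"time": t, "event": np.ones(100, int)})
        a = rng.normal(size=100)
        b = rng.normal(size=100)
        r1 = compare_models(a, b, y, B=200, seed=5)
        r2 = compare_models(a, b, y, B=200, seed=5)
        assert r1 == r2


class TestRunStudy:
    def test_report_structure_and_ranges(self):
        train, val, _ = paper_shaped_scenario(seed=3)
        train, val = _with_factor_scores(train, val)
        reports = run_study(train, val, B=0)
        table = report_frame(reports)
        assert set(table["endpoint"]) == {"os", "rfs"}
        assert set(table["model"]) == {"radiomic", "clinical", "combined"}
        assert table["iAUC"].between(0, 1).all()

    def test_signal_ordering_radiomic_beats_clinical(self):
        wins = 0
        for seed in range(5):
            train, val, _ = paper_shaped_scenario(seed=seed + 50)
            train, val = _with_factor_scores(train, val)
            rep = run_study(train, val, endpoints=("os",), B=0)["os"]
            e = rep["validation"].entries
            wins += e["radiomic"]["iauc"] > e["clinical"]["iauc"]
        assert wins >= 4

    def test_cohort_overlap_rejected(self):
        train, val, _ = paper_shaped_scenario(seed=4)
        train, _ = _with_factor_scores(train, val)
        with pytest.raises(ValueError, match="overlap"):
            run_study(train, train, B=0)

    def test_empty_validation_rejected(self):
        train, val, _ = paper_shaped_scenario(seed=5)
        train, val = _with_factor_scores(train, val)
        with pytest.raises(ValueError, match="empty"):
            run_study(train, val.iloc[:0], B=0)


def _with_factor_scores(train, val):
    """Replace raw features by factor scores: the factor model is fit on the
    training cohort and frozen for validation scoring."""
    from radsurv.factor_model import MLFactorAnalysis

    feats = [c for c in train.columns if c.startswith("feat_")]
    fa = MLFactorAnalysis(n_factors=7, shrinkage=0.05).fit(train[feats])

    def attach(df):
        out = fa.transform(df[feats])
        for c in df.columns:
            if not c.startswith("feat_"):
                out[c] = df[c]
        return out

    return attach(train), attach(val)


class TestKMPlot:
    def test_plot_km_writes_figure(self, tmp_path):
        from radsurv.prognostic_model import plot_km

        rng = np.random.default_rng(20)
        t = rng.exponential(1.0, 60)
        e = rng.binomial(1, 0.7, 60)
        y = pd.DataFrame({"time": t, "event": e})
        split = median_split_km(rng.normal(size=60), y)
        out = tmp_path / "km.svg"
        plot_km(split, str(out), title="validation")
        assert out.exists() and out.stat().st_size > 0
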