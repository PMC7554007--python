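"""Cox survival models on factor scores and clinical covariates, scored by
integrated time-dependent AUC.

Risk models are Cox proportional-hazards fits (partial likelihood, Efron tie
handling, via lifelines). Discrimination is the cumulative/dynamic
time-dependent AUC(t) with inverse-probability-of-censoring weights,
integrated over the observed event-time window (2.5th–97.5th percentile of
event times by default) with weights proportional to the empirical event
density. Confidence intervals are nonparametric patient-level bootstrap
percentile intervals; risk groups are stratified at the median linear
predictor and compared by log-rank test; nested models are compared by a
paired bootstrap of the iAUC difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.base import BaseEstimator
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

__all__ = [
    "CoxRisk",
    "fit_cox",
    "recalibrate_clinical",
    "integrated_auc",
    "bootstrap_ci",
    "median_split_km",
    "plot_km",
    "compare_models",
    "run_study",
    "PerformanceReport",
]


def _as_time_event(y) -> tuple[np.ndarray, np.ndarray]:
    """Accept (n,2) arrays, DataFrames with time/event, or sksurv arrays."""
    if isinstance(y, pd.DataFrame):
        tcol = "time" if "time" in y else y.columns[0]
        ecol = "event" if "event" in y else y.columns[1]
        return y[tcol].to_numpy(float), y[ecol].to_numpy(int)
    y = np.asarray(y)
    if y.dtype.names:  # structured (sksurv) array
        ecol, tcol = y.dtype.names[:2]
        return y[tcol].astype(float), y[ecol].astype(int)
    return y[:, 0].astype(float), y[:, 1].astype(int)


class CoxRisk(BaseEstimator):
    """Cox proportional-hazards risk model (sklearn-style wrapper).

    ``fit(X, y)`` takes a covariate DataFrame and survival outcomes
    ``y`` (any form accepted by ``_as_time_event``); ``predict(X)`` returns
    the linear predictor eta = beta' x (higher = higher hazard).
    """

    def __init__(self, penalizer: float = 0.0, ties: str = "efron"):
        self.penalizer = penalizer
        self.ties = ties

    def fit(self, X: pd.DataFrame, y) -> "CoxRisk":
        X = pd.DataFrame(X)
        time, event = _as_time_event(y)
        if event.sum() == 0:
            raise ValueError("no events: Cox model is not identifiable")
        if X.isna().any().any():
            raise ValueError("missing covariate values")
        df = X.copy()
        df["_time"], df["_event"] = time, event
        fitter = CoxPHFitter(penalizer=self.penalizer)
        fitter.fit(df, duration_col="_time", event_col="_event")  # Efron ties
        self.model_ = fitter
        self.coef_ = fitter.params_.copy()
        self.se_ = fitter.standard_errors_.copy()
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        X = pd.DataFrame(X)
        missing = set(self.feature_names_in_) - set(X.columns)
        if missing:
            raise ValueError(f"covariate roster mismatch; missing {sorted(missing)}")
        return (
            X[list(self.feature_names_in_)].to_numpy(float)
            @ self.coef_.to_numpy()
        )


def fit_cox(X: pd.DataFrame, y, penalizer: float = 0.0) -> CoxRisk:
    """Fit a Cox model; returns the fitted :class:`CoxRisk`."""
    return CoxRisk(penalizer=penalizer).fit(X, y)


def recalibrate_clinical(model: CoxRisk, X_val: pd.DataFrame, y_val) -> CoxRisk:
    """Refit the model's coefficients on a validation cohort, keeping the
    covariate roster fixed."""
    roster = list(model.feature_names_in_)
    missing = set(roster) - set(pd.DataFrame(X_val).columns)
    if missing:
        raise ValueError(f"validation cohort lacks covariates {sorted(missing)}")
    return CoxRisk(penalizer=model.penalizer).fit(
        pd.DataFrame(X_val)[roster], y_val
    )


def _event_time_window(
    time: np.ndarray, event: np.ndarray, window: tuple[float, float] | None
) -> np.ndarray:
    """Evaluation times: unique event times inside the window, strictly
    below the last observed follow-up time (IPCW requirement)."""
    et = np.sort(np.unique(time[event == 1]))
    if et.size == 0:
        raise ValueError("no events: iAUC undefined")
    if window is None:
        lo, hi = np.percentile(time[event == 1], [2.5, 97.5])
    else:
        lo, hi = window
    tmax = time.max()
    keep = (et >= lo) & (et <= hi) & (et < tmax)
    if not keep.any():
        # degenerate small samples: fall back to all event times before tmax
        keep = et < tmax
    if not keep.any():
        raise ValueError("no usable event time inside the evaluation window")
    return et[keep]


def integrated_auc(
    risk: np.ndarray,
    y,
    y_train=None,
    window: tuple[float, float] | None = None,
) -> float:
    """IPCW cumulative/dynamic AUC(t) integrated over event times.

    AUC(t) is evaluated at each unique event time in the window and averaged
    with weights proportional to the empirical event density (the number of
    events at each time). ``y_train`` supplies the censoring distribution
    for the IPC weights (defaults to ``y`` itself).
    """
    time, event = _as_time_event(y)
    risk = np.asarray(risk, dtype=float)
    times = _event_time_window(time, event, window)
    if y_train is None:
        t_tr, e_tr = time, event
    else:
        t_tr, e_tr = _as_time_event(y_train)
    surv_train = Surv.from_arrays(e_tr.astype(bool), t_tr)
    surv_test = Surv.from_arrays(event.astype(bool), time)
    auc_t, _ = cumulative_dynamic_auc(surv_train, surv_test, risk, times)
    weights = np.array([np.sum(time[event == 1] == t) for t in times], float)
    good = np.isfinite(auc_t)
    if not good.any():
        raise ValueError("AUC undefined at every evaluation time")
    iauc = float(np.sum(auc_t[good] * weights[good]) / np.sum(weights[good]))
    return min(max(iauc, 0.0), 1.0)


def bootstrap_ci(
    statistic: Callable[[pd.DataFrame], float],
    data: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    max_failure_rate: float = 0.10,
) -> tuple[float, float]:
    """Nonparametric patient-level bootstrap percentile interval."""
    if B < 100:
        raise ValueError("B must be >= 100")
    rng = np.random.default_rng(seed)
    n = len(data)
    stats_, failures = [], 0
    for _ in range(B):
        idx = rng.integers(0, n, n)
        try:
            stats_.append(float(statistic(data.iloc[idx])))
        except Exception:
            failures += 1
    if failures > max_failure_rate * B:
        raise RuntimeError(
            f"statistic failed on {failures}/{B} bootstrap resamples"
        )
    lo, hi = np.percentile(stats_, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def median_split_km(risk: np.ndarray, y) -> dict:
    """Kaplan-Meier curves for risk groups split at the median linear
    predictor, with a two-sample log-rank test."""
    time, event = _as_time_event(y)
    risk = np.asarray(risk, dtype=float)
    med = np.median(risk)
    hi = risk > med
    if hi.sum() < 2 or (~hi).sum() < 2:
        if np.allclose(risk, risk[0]):
            raise ValueError("degenerate split: all risk scores equal")
        hi = risk >= med  # ties at the median: put them in the high arm
        if hi.sum() < 2 or (~hi).sum() < 2:
            raise ValueError("degenerate split: fewer than 2 patients per arm")
    km_low, km_high = KaplanMeierFitter(), KaplanMeierFitter()
    km_low.fit(time[~hi], event[~hi], label="low risk")
    km_high.fit(time[hi], event[hi], label="high risk")
    lr = logrank_test(time[~hi], time[hi], event[~hi], event[hi])
    return {
        "km_low": km_low,
        "km_high": km_high,
        "p_value": float(lr.p_value),
        "n_low": int((~hi).sum()),
        "n_high": int(hi.sum()),
        "median_risk": float(med),
    }


def plot_km(split: dict, path: str, title: str | None = None) -> None:
    """Render a median-split Kaplan-Meier plot (censoring ticks, log-rank p)
    to SVG/PNG/PDF, as produced by :func:`median_split_km`."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    split["km_low"].plot_survival_function(ax=ax, show_censors=True)
    split["km_high"].plot_survival_function(ax=ax, show_censors=True)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    label = f"log-rank p = {split['p_value']:.3g}"
    ax.set_title(f"{title} ({label})" if title else label)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def compare_models(
    risk_a: np.ndarray,
    risk_b: np.ndarray,
    y,
    B: int = 1000,
    seed: int = 0,
    y_train=None,
) -> dict:
    """Paired bootstrap of the iAUC difference between two risk scores on
    the same patients; two-sided p from the bootstrap sign proportion."""
    time, event = _as_time_event(y)
    ydf = pd.DataFrame({"time": time, "event": event})
    risk_a = np.asarray(risk_a, float)
    risk_b = np.asarray(risk_b, float)
    if len(risk_a) != len(ydf) or len(risk_b) != len(ydf):
        raise ValueError("models must score the same patients")
    delta = integrated_auc(risk_a, ydf, y_train) - integrated_auc(
        risk_b, ydf, y_train
    )
    rng = np.random.default_rng(seed)
    n = len(ydf)
    deltas = []
    for _ in range(B):
        idx = rng.integers(0, n, n)
        yb = ydf.iloc[idx]
        if yb["event"].sum() == 0:
            continue
        try:
            deltas.append(
                integrated_auc(risk_a[idx], yb, y_train)
                - integrated_auc(risk_b[idx], yb, y_train)
            )
        except ValueError:
            continue
    deltas = np.asarray(deltas)
    if deltas.size == 0:
        raise RuntimeError("all bootstrap resamples failed")
    p_low = float(np.mean(deltas <= 0.0))
    p_high = float(np.mean(deltas >= 0.0))
    p = min(1.0, 2.0 * min(p_low, p_high))
    return {
        "delta_iauc": float(delta),
        "p_value": p,
        "ci": (float(np.percentile(deltas, 2.5)), float(np.percentile(deltas, 97.5))),
        "n_resamples": int(deltas.size),
    }


CLINICAL_COVARIATES = ["n_stage", "age", "gender"]


@dataclass
class PerformanceReport:
    """iAUC (with bootstrap CI), KM median-split log-rank p per model."""

    endpoint: str
    cohort: str
    entries: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for model, e in self.entries.items():
            rows.append(
                {
                    "endpoint": self.endpoint,
                    "cohort": self.cohort,
                    "model": model,
                    "iAUC": e["iauc"],
                    "ci_low": e.get("ci", (np.nan, np.nan))[0],
                    "ci_high": e.get("ci", (np.nan, np.nan))[1],
                    "logrank_p": e.get("logrank_p", np.nan),
                }
            )
        return pd.DataFrame(rows)


def _factor_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("factor_")]


def _model_rosters(df: pd.DataFrame, models: Sequence[str]) -> dict[str, list[str]]:
    rosters: dict[str, list[str]] = {}
    fac = _factor_columns(df)
    for m in models:
        if m == "radiomic":
            rosters[m] = fac
        elif m == "clinical":
            rosters[m] = [c for c in CLINICAL_COVARIATES if c in df.columns]
        elif m == "volume":
            if "log_volume" in df.columns:
                rosters[m] = ["log_volume"]
        elif m == "combined":
            rosters[m] = fac + [c for c in CLINICAL_COVARIATES if c in df.columns]
        else:
            raise ValueError(f"unknown model {m!r}")
    return {k: v for k, v in rosters.items() if v}


def run_study(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    endpoints: Iterable[str] = ("os", "rfs"),
    models: Sequence[str] = ("radiomic", "clinical", "volume", "combined"),
    B: int = 1000,
    seed: int = 0,
    recalibrate: bool = True,
) -> dict:
    """Fit radiomic / clinical / volume / combined Cox models on the
    training cohort and evaluate on training (resubstitution) and
    validation.

    The radiomic risk score is frozen for validation; clinical coefficients
    are recalibrated on the validation cohort (roster fixed), and the
    combined model is recalibrated with the frozen radiomic linear predictor
    entering as a single covariate alongside the clinical variables. Set
    ``B=0`` to skip bootstrap confidence intervals.

    Cohort tables use columns time_<ep>, event_<ep> per endpoint plus
    covariates (factor_* scores, n_stage, age, gender, optional log_volume).
    """
    if len(validation) == 0:
        raise ValueError("empty validation cohort")
    overlap = set(train.index) & set(validation.index)
    if overlap:
        raise ValueError(f"cohorts overlap on patients {sorted(overlap)[:5]}")

    reports: dict[str, dict[str, PerformanceReport]] = {}
    for ep in endpoints:
        tcol, ecol = f"time_{ep}", f"event_{ep}"
        for col in (tcol, ecol):
            if col not in train.columns or col not in validation.columns:
                raise ValueError(f"missing outcome column {col}")
        y_tr = train[[tcol, ecol]].rename(columns={tcol: "time", ecol: "event"})
        y_va = validation[[tcol, ecol]].rename(
            columns={tcol: "time", ecol: "event"}
        )
        rosters = _model_rosters(train, models)
        fitted = {m: fit_cox(train[r], y_tr) for m, r in rosters.items()}

        rep_tr = PerformanceReport(endpoint=ep, cohort="training")
        rep_va = PerformanceReport(endpoint=ep, cohort="validation")
        for m, cox in fitted.items():
            roster = rosters[m]
            risk_tr = cox.predict(train[roster])
            entry_tr = {"iauc": integrated_auc(risk_tr, y_tr)}

            # validation risk: frozen radiomic, recalibrated clinical parts
            if m == "radiomic" or not recalibrate:
                risk_va = cox.predict(validation[roster])
                val_model = cox
            elif m in ("clinical", "volume"):
                val_model = recalibrate_clinical(cox, validation[roster], y_va)
                risk_va = val_model.predict(validation[roster])
            else:  # combined: frozen radiomic linear predictor + clinical
                rad = fitted.get("radiomic")
                clin_cols = [c for c in roster if not c.startswith("factor_")]
                if rad is None:
                    val_model = recalibrate_clinical(cox, validation[roster], y_va)
                    risk_va = val_model.predict(validation[roster])
                else:
                    Xc_tr = train[clin_cols].copy()
                    Xc_tr["radiomic_lp"] = rad.predict(train[_factor_columns(train)])
                    Xc_va = validation[clin_cols].copy()
                    Xc_va["radiomic_lp"] = rad.predict(
                        validation[_factor_columns(validation)]
                    )
                    val_model = fit_cox(Xc_va, y_va)
                    risk_va = val_model.predict(Xc_va)
            entry_va = {"iauc": integrated_auc(risk_va, y_va)}
            try:
                entry_va["logrank_p"] = median_split_km(risk_va, y_va)["p_value"]
            except ValueError:
                entry_va["logrank_p"] = np.nan

            if B:
                def stat_train(df, _cox=cox, _roster=roster):
                    return integrated_auc(
                        _cox.predict(df[_roster]),
                        df[["time", "event"]],
                    )

                tr_df = train[roster].copy()
                tr_df[["time", "event"]] = y_tr.to_numpy()
                entry_tr["ci"] = bootstrap_ci(stat_train, tr_df, B=B, seed=seed)

                risk_series = pd.Series(np.asarray(risk_va), index=validation.index)

                def stat_val(df, _r=risk_series):
                    return integrated_auc(
                        _r.loc[df.index].to_numpy()
                        if df.index.is_unique
                        else _r.to_numpy()[
                            [_r.index.get_loc(i) for i in df.index]
                        ],
                        df[["time", "event"]],
                    )

                va_df = validation[roster].copy()
                va_df[["time", "event"]] = y_va.to_numpy()
                entry_va["ci"] = bootstrap_ci(stat_val, va_df, B=B, seed=seed)

            rep_tr.entries[m] = entry_tr
            rep_va.entries[m] = entry_va
        reports[ep] = {"training": rep_tr, "validation": rep_va}
    return reports


def report_frame(reports: dict) -> pd.DataFrame:
    """Flatten a run_study result into one tidy table."""
    frames = []
    for ep, pair in reports.items():
        for rep in pair.values():
            frames.append(rep.to_frame())
    return pd.concat(frames, ignore_index=True)
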