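"""Regularized correlation, maximum-likelihood factor analysis, factor
scores, and batch-effect testing.

The feature matrix (patients x filtered core features) is compressed into m
latent factors via the common-factor model

    R  ≈  Λ Λᵀ + diag(Ψ),

with Λ the p x m loading matrix and Ψ the per-feature unique variances.
Estimation maximizes the Wishart likelihood of a *regularized* correlation
matrix R(λ) = (1-λ)·R_sample + λ·I (convex shrinkage toward identity, λ
chosen by cross-validated Gaussian log-likelihood when "auto"). The ML fit
concentrates the likelihood over Ψ (Lawley/Jöreskog): for fixed Ψ the
optimal loadings come from the eigendecomposition of Ψ^{-1/2} R Ψ^{-1/2},
leaving a smooth objective in log Ψ minimized with L-BFGS-B. Loadings are
varimax-rotated, sign-fixed, and ordered by explained variance. Per-patient
scores are Bartlett weighted-least-squares estimates computed on
training-standardized features (the standardization is frozen for external
validation cohorts). MANOVA on the scores tests scanner vendor / field
strength batch effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.multivariate.manova import MANOVA

__all__ = [
    "regularized_correlation",
    "fit_factor_model",
    "select_factor_count",
    "varimax",
    "bartlett_scores",
    "FactorModel",
    "MLFactorAnalysis",
    "batch_effect_manova",
    "tucker_congruence",
]


# ---------------------------------------------------------------------------
# regularized correlation


def _gauss_loglik(Z: np.ndarray, R: np.ndarray) -> float:
    sign, logdet = np.linalg.slogdet(R)
    if sign <= 0:
        return -np.inf
    Rinv = np.linalg.inv(R)
    quad = float(np.einsum("ij,jk,ik->", Z, Rinv, Z)) / len(Z)
    return -0.5 * (logdet + quad)


def regularized_correlation(
    X: pd.DataFrame | np.ndarray,
    penalty: float | str = "auto",
    k_folds: int = 5,
    seed: int = 0,
    grid: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, float]:
    """Shrinkage correlation estimate R(λ) = (1-λ) R_sample + λ I.

    ``penalty="auto"`` selects λ on a log-spaced grid by K-fold
    cross-validated Gaussian log-likelihood of held-out standardized rows.
    Returns (R, λ).
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite entries")
    n, p = X.shape
    mu, sd = X.mean(axis=0), X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance feature column")
    Z = (X - mu) / sd
    R_sample = np.corrcoef(X, rowvar=False)

    if penalty != "auto":
        lam = float(penalty)
        if not 0.0 <= lam <= 1.0:
            raise ValueError("penalty must be in [0, 1]")
        return (1 - lam) * R_sample + lam * np.eye(p), lam

    if grid is None:
        grid = np.concatenate([np.logspace(-3, -0.05, 12), [0.5, 0.75, 1.0]])
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k_folds)
    scores = np.zeros(len(grid))
    for fold in folds:
        train = np.setdiff1d(order, fold)
        mu_t = X[train].mean(axis=0)
        sd_t = X[train].std(axis=0, ddof=1)
        sd_t[sd_t == 0] = 1.0
        Zt = (X[train] - mu_t) / sd_t
        Zv = (X[fold] - mu_t) / sd_t
        Rt = np.corrcoef(Zt, rowvar=False)
        for g, lam in enumerate(grid):
            scores[g] += _gauss_loglik(Zv, (1 - lam) * Rt + lam * np.eye(p))
    lam = float(grid[int(np.argmax(scores))])
    return (1 - lam) * R_sample + lam * np.eye(p), lam


# ---------------------------------------------------------------------------
# maximum-likelihood factor analysis on a correlation matrix


# tiny log-barrier pushing uniquenesses toward 1 where the likelihood is
# flat (e.g. a diagonal R admits a manifold of exact solutions); far below
# the curvature of any informative fit
_PSI_BARRIER = 1e-7


def _concentrated_objective(y: np.ndarray, R: np.ndarray, m: int):
    psi = np.exp(y)
    d = 1.0 / np.sqrt(psi)
    A = R * np.outer(d, d)
    w, V = np.linalg.eigh(A)  # ascending
    w = w[::-1]
    V = V[:, ::-1]
    tail = slice(m, None)
    wt = np.maximum(w[tail], 1e-12)
    f = float(np.sum(wt - np.log(wt) - 1.0)) - _PSI_BARRIER * float(y.sum())
    # d f / d log psi_j = -sum_{k>m} (theta_k - 1) v_jk^2
    g = -np.einsum("k,jk->j", w[tail] - 1.0, V[:, tail] ** 2) - _PSI_BARRIER
    return f, g


def _loadings_from_psi(psi: np.ndarray, R: np.ndarray, m: int) -> np.ndarray:
    d = 1.0 / np.sqrt(psi)
    A = R * np.outer(d, d)
    w, V = np.linalg.eigh(A)
    w, V = w[::-1][:m], V[:, ::-1][:, :m]
    gain = np.sqrt(np.maximum(w - 1.0, 0.0))
    return (V * gain) * np.sqrt(psi)[:, None]


def varimax(L: np.ndarray, max_iter: int = 200, tol: float = 1e-8) -> np.ndarray:
    """Orthogonal varimax rotation (SVD algorithm, no Kaiser normalization)."""
    p, m = L.shape
    if m < 2:
        return L.copy()
    T = np.eye(m)
    d_old = 0.0
    for _ in range(max_iter):
        B = L @ T
        U, s, Vt = np.linalg.svd(
            L.T @ (B**3 - B * np.mean(B**2, axis=0, keepdims=True))
        )
        T = U @ Vt
        d = s.sum()
        if d_old != 0 and d < d_old * (1 + tol):
            break
        d_old = d
    return L @ T


class HeywoodError(RuntimeError):
    """A uniqueness collapsed to (or below) zero during estimation."""


@dataclass
class FactorModel:
    """Fitted factor solution: rotated loadings, uniquenesses, diagnostics."""

    loadings: pd.DataFrame  # features x m
    uniquenesses: pd.Series  # per feature, in (0, 1]
    m: int
    explained_variance: np.ndarray  # per-factor proportion of total variance
    shrinkage: float = 0.0
    feature_means: Optional[pd.Series] = None
    feature_sds: Optional[pd.Series] = None
    labels: list[str] = field(default_factory=list)
    heywood_features: list[str] = field(default_factory=list)

    @property
    def cumulative_variance(self) -> float:
        return float(self.explained_variance.sum())

    def fitted_correlation(self) -> np.ndarray:
        L = self.loadings.to_numpy()
        return L @ L.T + np.diag(self.uniquenesses.to_numpy())

    def to_json(self, path: str) -> None:
        payload = {
            "m": self.m,
            "features": list(self.loadings.index),
            "loadings": self.loadings.to_numpy().tolist(),
            "uniquenesses": self.uniquenesses.to_numpy().tolist(),
            "explained_variance": self.explained_variance.tolist(),
            "shrinkage": self.shrinkage,
            "feature_means": None
            if self.feature_means is None
            else self.feature_means.to_numpy().tolist(),
            "feature_sds": None
            if self.feature_sds is None
            else self.feature_sds.to_numpy().tolist(),
            "labels": self.labels,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "FactorModel":
        with open(path) as fh:
            d = json.load(fh)
        feats = d["features"]
        return cls(
            loadings=pd.DataFrame(
                d["loadings"], index=feats,
                columns=[f"factor_{i+1}" for i in range(d["m"])],
            ),
            uniquenesses=pd.Series(d["uniquenesses"], index=feats),
            m=d["m"],
            explained_variance=np.asarray(d["explained_variance"]),
            shrinkage=d.get("shrinkage", 0.0),
            feature_means=None
            if d.get("feature_means") is None
            else pd.Series(d["feature_means"], index=feats),
            feature_sds=None
            if d.get("feature_sds") is None
            else pd.Series(d["feature_sds"], index=feats),
            labels=d.get("labels", []),
        )


def fit_factor_model(
    R: np.ndarray | pd.DataFrame,
    m: int,
    psi_floor: float = 0.005,
    rotation: str = "varimax",
    on_heywood: str = "floor",
    seed: int = 0,
    max_restarts: int = 5,
) -> FactorModel:
    """ML factor analysis of a correlation matrix with ``m`` factors.

    Starts from the Jöreskog principal-axis uniqueness heuristic; on
    optimizer failure, restarts from seed-controlled jittered starts (max
    ``max_restarts``). ``on_heywood``: "floor" keeps uniquenesses clamped at
    ``psi_floor`` and records the features; "error" raises
    :class:`HeywoodError` naming them.
    """
    feats = list(R.index) if isinstance(R, pd.DataFrame) else [
        f"f{i}" for i in range(np.asarray(R).shape[0])
    ]
    R = np.asarray(R, dtype=float)
    p = R.shape[0]
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > p:
        raise ValueError("more factors than features")
    w_R = np.linalg.eigvalsh(R)
    if w_R.min() <= 0:
        raise ValueError("correlation matrix is not positive definite")

    try:
        start_psi = (1.0 - m / (2.0 * p)) / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:  # pragma: no cover
        start_psi = np.full(p, 0.5)
    start_psi = np.clip(start_psi, psi_floor, 1.0)

    rng = np.random.default_rng(seed)
    bounds = [(np.log(psi_floor), 0.0)] * p
    res = None
    for attempt in range(max_restarts + 1):
        y0 = np.log(start_psi)
        if attempt > 0:
            y0 = y0 + rng.normal(0.0, 0.3, size=p)
            y0 = np.clip(y0, np.log(psi_floor), 0.0)
        res = optimize.minimize(
            _concentrated_objective,
            y0,
            args=(R, m),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-13, "gtol": 1e-9},
        )
        if res.success or res.fun < 1e8:
            break
    psi = np.exp(res.x)

    heywood = [feats[j] for j in np.where(psi <= psi_floor * (1 + 1e-6))[0]]
    if heywood and on_heywood == "error":
        raise HeywoodError(f"Heywood case for features: {heywood}")

    L = _loadings_from_psi(psi, R, m)
    if rotation == "varimax":
        L = varimax(L)
    elif rotation not in (None, "none"):
        raise ValueError(f"unknown rotation {rotation!r}")
    # sign fix: each factor's largest-|loading| entry positive
    for k in range(L.shape[1]):
        jmax = int(np.argmax(np.abs(L[:, k])))
        if L[jmax, k] < 0:
            L[:, k] = -L[:, k]
    ev = (L**2).sum(axis=0) / p
    order = np.argsort(ev)[::-1]
    L, ev = L[:, order], ev[order]

    return FactorModel(
        loadings=pd.DataFrame(
            L, index=feats, columns=[f"factor_{i+1}" for i in range(m)]
        ),
        uniquenesses=pd.Series(psi, index=feats),
        m=m,
        explained_variance=ev,
        heywood_features=heywood,
    )


def select_factor_count(
    R: np.ndarray | pd.DataFrame,
    rule: str = "variance",
    target: float = 0.75,
    n_obs: Optional[int] = None,
    alpha: float = 0.05,
    max_m: Optional[int] = None,
    **fit_kwargs,
) -> tuple[int, dict]:
    """Choose the number of latent factors.

    Rules: ``"variance"`` (default) — smallest m whose ML solution reaches
    cumulative explained variance >= ``target``; ``"kaiser"`` — count of
    eigenvalues of R above 1; ``"lrt"`` — first m not rejected by the
    Bartlett-corrected likelihood-ratio test (requires ``n_obs``). Returns
    (m, diagnostics); raises if no admissible m satisfies the rule.
    """
    Rm = np.asarray(R, dtype=float)
    p = Rm.shape[0]
    cap = max_m if max_m is not None else max(1, p // 2)
    diag: dict = {"rule": rule}

    if rule == "kaiser":
        eig = np.linalg.eigvalsh(Rm)[::-1]
        m = int((eig > 1.0).sum())
        diag["eigenvalues"] = eig
        if m == 0:
            raise ValueError("Kaiser rule found no eigenvalue above 1 "
                             "(no common variance)")
        return m, diag

    if rule == "variance":
        cumvar = {}
        for m in range(1, cap + 1):
            model = fit_factor_model(Rm, m, **fit_kwargs)
            cumvar[m] = model.cumulative_variance
            if cumvar[m] >= target:
                diag["cumulative_variance"] = cumvar
                return m, diag
        diag["cumulative_variance"] = cumvar
        raise ValueError(
            f"no m <= {cap} reaches cumulative explained variance {target}; "
            f"best {max(cumvar.values()):.3f}"
        )

    if rule == "lrt":
        if n_obs is None:
            raise ValueError("likelihood-ratio rule requires n_obs")
        pvals = {}
        for m in range(1, cap + 1):
            model = fit_factor_model(Rm, m, **fit_kwargs)
            Sigma = model.fitted_correlation()
            sign, logdet_S = np.linalg.slogdet(Sigma)
            _, logdet_R = np.linalg.slogdet(Rm)
            fmin = logdet_S - logdet_R + float(
                np.trace(np.linalg.solve(Sigma, Rm))
            ) - p
            df = ((p - m) ** 2 - (p + m)) / 2.0
            if df <= 0:
                break
            chi2 = (n_obs - 1 - (2 * p + 5) / 6.0 - 2 * m / 3.0) * fmin
            pvals[m] = float(stats.chi2.sf(max(chi2, 0.0), df))
            if pvals[m] > alpha:
                diag["p_values"] = pvals
                return m, diag
        diag["p_values"] = pvals
        raise ValueError(f"likelihood-ratio rule rejected all m <= {cap}")

    raise ValueError(f"unknown rule {rule!r}")


def bartlett_scores(Z: np.ndarray, L: np.ndarray, psi: np.ndarray) -> np.ndarray:
    """Bartlett WLS factor scores F = (Lᵀ Ψ⁻¹ L)⁻¹ Lᵀ Ψ⁻¹ zᵀ per row of Z."""
    W = L.T / psi  # m x p
    M = W @ L
    return np.linalg.solve(M, W @ Z.T).T


class MLFactorAnalysis(BaseEstimator, TransformerMixin):
    """Sklearn-style estimator: shrinkage correlation + ML factor analysis.

    Parameters
    ----------
    n_factors : int or "auto"
        Number of latent factors; "auto" selects the smallest m reaching
        ``variance_target`` cumulative explained variance.
    shrinkage : float in [0, 1] or "auto"
        Convex shrinkage weight toward the identity; "auto" by K-fold
        cross-validated Gaussian log-likelihood.
    variance_target : float
        Cumulative explained-variance target for automatic factor-count
        selection (default 0.75).
    rotation : "varimax" or "none"
    psi_floor : float
        Lower clamp for uniquenesses (Heywood guard).
    random_state : int
        Seed for CV fold assignment and optimizer restarts.

    Fitted attributes: ``model_`` (:class:`FactorModel`), ``R_``,
    ``shrinkage_``, ``n_factors_``, ``mean_``, ``scale_``,
    ``feature_names_in_``. ``transform`` returns Bartlett factor scores on
    the frozen training standardization.
    """

    def __init__(
        self,
        n_factors: int | str = "auto",
        shrinkage: float | str = "auto",
        variance_target: float = 0.75,
        rotation: str = "varimax",
        psi_floor: float = 0.005,
        selection_rule: str = "variance",
        random_state: int = 0,
    ):
        self.n_factors = n_factors
        self.shrinkage = shrinkage
        self.variance_target = variance_target
        self.rotation = rotation
        self.psi_floor = psi_floor
        self.selection_rule = selection_rule
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "MLFactorAnalysis":
        X = pd.DataFrame(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.mean_ = X.mean(axis=0)
        self.scale_ = X.std(axis=0, ddof=1)
        if (self.scale_ == 0).any():
            raise ValueError("zero-variance feature column")
        R, lam = regularized_correlation(
            X.to_numpy(), penalty=self.shrinkage, seed=self.random_state
        )
        Rdf = pd.DataFrame(R, index=X.columns, columns=X.columns)
        if self.n_factors == "auto":
            m, diag = select_factor_count(
                Rdf,
                rule=self.selection_rule,
                target=self.variance_target,
                n_obs=len(X),
                psi_floor=self.psi_floor,
                rotation=self.rotation,
                seed=self.random_state,
            )
            self.selection_diagnostics_ = diag
        else:
            m = int(self.n_factors)
        model = fit_factor_model(
            Rdf, m, psi_floor=self.psi_floor, rotation=self.rotation,
            seed=self.random_state,
        )
        model.shrinkage = lam
        model.feature_means = self.mean_
        model.feature_sds = self.scale_
        self.model_ = model
        self.R_ = Rdf
        self.shrinkage_ = lam
        self.n_factors_ = m
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        X = pd.DataFrame(X)
        if list(X.columns) != list(self.feature_names_in_):
            raise ValueError("feature columns do not match the fitted model")
        Z = ((X - self.mean_) / self.scale_).to_numpy()
        F = bartlett_scores(
            Z,
            self.model_.loadings.to_numpy(),
            self.model_.uniquenesses.to_numpy(),
        )
        return pd.DataFrame(F, index=X.index, columns=self.model_.loadings.columns)


def factor_scores(
    X: pd.DataFrame, model: FactorModel
) -> pd.DataFrame:
    """Bartlett scores of ``X`` under a fitted model's frozen training
    standardization."""
    if model.feature_means is None or model.feature_sds is None:
        raise ValueError("model carries no training standardization")
    if list(X.columns) != list(model.loadings.index):
        raise ValueError("feature columns do not match the model")
    Z = ((X - model.feature_means) / model.feature_sds).to_numpy()
    F = bartlett_scores(
        Z, model.loadings.to_numpy(), model.uniquenesses.to_numpy()
    )
    return pd.DataFrame(F, index=X.index, columns=model.loadings.columns)


def tucker_congruence(A: np.ndarray, B: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean Tucker congruence between two loading matrices after optimal
    column matching (Hungarian assignment on |congruence|) and sign
    alignment. Returns (mean congruence, per-factor congruences)."""
    from scipy.optimize import linear_sum_assignment

    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    na = A / np.linalg.norm(A, axis=0, keepdims=True)
    nb = B / np.linalg.norm(B, axis=0, keepdims=True)
    C = na.T @ nb
    r, c = linear_sum_assignment(-np.abs(C))
    vals = np.abs(C[r, c])
    return float(vals.mean()), vals


def batch_effect_manova(
    scores: pd.DataFrame, grouping: pd.Series | np.ndarray
) -> dict:
    """One-way MANOVA of factor scores on a batch variable.

    Returns Pillai's trace with its F approximation and p-value, plus
    per-factor univariate one-way ANOVA p-values.
    """
    scores = pd.DataFrame(scores)
    g = pd.Series(np.asarray(grouping), index=scores.index, name="group")
    levels = g.unique()
    m = scores.shape[1]
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    counts = g.value_counts()
    if (counts < m + 1).any():
        raise ValueError(
            f"every group needs >= {m + 1} members for {m} factors; "
            f"smallest has {counts.min()} — consider merging groups"
        )
    # identical group means: between-group SSP vanishes and the test is
    # trivially null — short-circuit before the numerical machinery
    grand = scores.mean(axis=0).to_numpy()
    H = np.zeros((m, m))
    for lev in levels:
        d = scores[g == lev].mean(axis=0).to_numpy() - grand
        H += (g == lev).sum() * np.outer(d, d)
    if np.abs(H).max() < 1e-12:
        return {
            "pillai_trace": 0.0,
            "F": 0.0,
            "p_value": 1.0,
            "univariate_p": {c: 1.0 for c in scores.columns},
            "groups": {str(k): int(v) for k, v in counts.items()},
        }

    df = scores.copy()
    df.columns = [f"s{i}" for i in range(m)]
    df["group"] = g.values
    lhs = " + ".join(df.columns[:-1])
    try:
        mv = MANOVA.from_formula(f"{lhs} ~ C(group)", data=df)
        tbl = mv.mv_test().results["C(group)"]["stat"]
    except Exception as exc:
        raise ValueError(
            f"MANOVA failed (singular within-group covariance?): {exc}"
        ) from exc
    pillai = tbl.loc["Pillai's trace"]
    uni = {
        col: float(
            stats.f_oneway(
                *[scores[col][g == lev].to_numpy() for lev in levels]
            ).pvalue
        )
        for col in scores.columns
    }
    return {
        "pillai_trace": float(pillai["Value"]),
        "F": float(pillai["F Value"]),
        "p_value": float(pillai["Pr > F"]),
        "univariate_p": uni,
        "groups": {str(k): int(v) for k, v in counts.items()},
    }
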