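"""Synthetic ground-truth inputs: textured tumor phantoms and tabular
cohorts with known latent-factor structure and survival linkage.

Phantoms are (optionally lobulated) ellipsoids on a 3D grid filled with a
controllable texture — constant, iid noise, a Gaussian random field with a
physical correlation length (Fourier-domain filtering of white noise with an
isotropic squared-exponential spectrum), or a checkerboard — over a flat
background. Tabular cohorts draw features from the common-factor model
x = Λ f + Ψ^{1/2} ε with standard-normal factors and noise, link survival to
the factors (and clinical covariates) through a Cox model with an
exponential baseline hazard, and censor independently. Every generator is a
pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .volume_io import SegmentationMask, VolumeGrid

__all__ = [
    "PhantomSpec",
    "generate_phantom",
    "TabularCohortSpec",
    "generate_tabular_cohort",
    "paper_shaped_scenario",
]


# ---------------------------------------------------------------------------
# image mode


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of one textured ellipsoidal tumor phantom."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    semi_axes: tuple[float, float, float] = (20.0, 16.0, 12.0)  # mm
    lobulation: float = 0.0  # relative radial perturbation amplitude
    texture: str = "grf"  # constant | noise | grf | checkerboard
    correlation_length: float = 4.0  # mm, for grf texture
    background: float = 0.0
    intensity_range: tuple[float, float] = (100.0, 300.0)
    seed: int = 0


def _grf(shape, spacing, corr_mm, rng) -> np.ndarray:
    """Gaussian random field: white noise filtered with an isotropic
    squared-exponential spectrum (correlation length in mm)."""
    white = rng.standard_normal(shape)
    W = np.fft.fftn(white)
    k2 = np.zeros(shape)
    for ax, (n, d) in enumerate(zip(shape, spacing)):
        freq = np.fft.fftfreq(n, d=d)
        sl = [None] * 3
        sl[ax] = slice(None)
        k2 = k2 + (2 * np.pi * freq[tuple(sl)]) ** 2
    amp = np.exp(-k2 * corr_mm**2 / 4.0)  # sqrt of SE spectral density
    out = np.real(np.fft.ifftn(W * amp))
    sd = out.std()
    return out / sd if sd > 0 else out


def generate_phantom(
    spec: PhantomSpec,
) -> tuple[VolumeGrid, SegmentationMask, dict]:
    """Deterministic phantom (volume, mask, ground-truth record)."""
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.shape)
    spacing = tuple(spec.spacing)
    a, b, c = spec.semi_axes
    half_extent = np.array([(s - 1) * d / 2.0 for s, d in zip(shape, spacing)])
    if np.any(np.array([a, b, c]) * (1 + abs(spec.lobulation)) >= half_extent):
        raise ValueError(
            f"ellipsoid semi-axes {spec.semi_axes} (with lobulation) exceed "
            f"the grid half-extent {tuple(half_extent)}"
        )

    coords = [
        (np.arange(n) - (n - 1) / 2.0) * d for n, d in zip(shape, spacing)
    ]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    rho = np.sqrt((X / a) ** 2 + (Y / b) ** 2 + (Z / c) ** 2)
    if spec.lobulation:
        r = np.sqrt(X**2 + Y**2 + Z**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = np.arccos(np.clip(np.where(r > 0, Z / np.maximum(r, 1e-12), 1.0), -1, 1))
            phi = np.arctan2(Y, X)
        boundary = 1.0 + spec.lobulation * np.sin(3 * theta) * np.cos(3 * phi)
    else:
        boundary = 1.0
    mask_arr = rho <= boundary

    lo, hi = spec.intensity_range
    if spec.texture == "constant":
        tex = np.full(shape, (lo + hi) / 2.0)
    elif spec.texture == "noise":
        tex = rng.uniform(lo, hi, size=shape)
    elif spec.texture == "grf":
        g = _grf(shape, spacing, spec.correlation_length, rng)
        g = (g - g.min()) / max(g.max() - g.min(), 1e-12)
        tex = lo + (hi - lo) * g
    elif spec.texture == "checkerboard":
        idx = sum(np.indices(shape))
        tex = np.where(idx % 2 == 0, hi, lo).astype(float)
    else:
        raise ValueError(f"unknown texture {spec.texture!r}")

    values = np.where(mask_arr, tex, float(spec.background))
    vol = VolumeGrid(values, spacing=spacing)
    mask = SegmentationMask(mask_arr, spacing=spacing)
    truth = {
        "analytic_volume_mm3": 4.0 / 3.0 * np.pi * a * b * c,
        "semi_axes_mm": (a, b, c),
        "texture": spec.texture,
        "correlation_length_mm": spec.correlation_length,
        "intensity_range": spec.intensity_range,
        "n_voxels": int(mask_arr.sum()),
        "seed": spec.seed,
    }
    return vol, mask, truth


# ---------------------------------------------------------------------------
# table mode


@dataclass(frozen=True)
class TabularCohortSpec:
    """Cohort of patients with factor-structured features and Cox-linked
    survival.

    ``loading_strength`` builds a simple-structure Λ (each feature loads on
    one factor) when no explicit loading matrix is given; ``beta_factors``
    are the log hazard ratios per unit factor score; censoring is
    independent exponential with rate chosen to hit ``censoring_rate`` in
    expectation given the realized hazards.
    """

    n: int = 200
    p: int = 50
    m: int = 7
    loading_strength: float = 0.9
    loadings: Optional[np.ndarray] = None
    beta_factors: tuple[float, ...] = (0.7, 0.5, 0.0, 0.0, 0.0, 0.0, 0.0)
    beta_clinical: tuple[float, float, float] = (0.1, 0.01, 0.0)  # n_stage, age, gender
    baseline_hazard: float = 0.12  # events per year
    censoring_rate: float = 0.45
    age_mean: float = 63.0
    age_sd: float = 10.0
    gender_p_male: float = 0.6
    n_stage_probs: tuple[float, ...] = (0.5, 0.15, 0.3, 0.05)
    seed: int = 0


def _build_loadings(spec: TabularCohortSpec) -> np.ndarray:
    if spec.loadings is not None:
        L = np.asarray(spec.loadings, dtype=float)
        if L.shape != (spec.p, spec.m):
            raise ValueError(f"loadings must be {spec.p}x{spec.m}")
        return L
    L = np.zeros((spec.p, spec.m))
    for j in range(spec.p):
        L[j, j % spec.m] = spec.loading_strength
    return L


def _censor_rate_for(target: float, hazards: np.ndarray) -> float:
    """Exponential censoring rate mu with E[censored fraction] = target,
    given realized event hazards: P(C < T) = mean(mu / (mu + lambda_i))."""
    from scipy.optimize import brentq

    if target <= 0:
        return 0.0
    if target >= 1:
        raise ValueError("censoring_rate must be < 1")

    def f(log_mu):
        mu = np.exp(log_mu)
        return float(np.mean(mu / (mu + hazards))) - target

    lo, hi = np.log(hazards.min()) - 15, np.log(hazards.max()) + 15
    return float(np.exp(brentq(f, lo, hi)))


def generate_tabular_cohort(
    spec: TabularCohortSpec,
) -> tuple[pd.DataFrame, dict]:
    """One cohort table plus the generating ground truth.

    Columns: feat_001..feat_p, age, gender, n_stage, time_os, event_os,
    time_rfs, event_rfs (both endpoints share the generative model but use
    independent censoring draws).
    """
    rng = np.random.default_rng(spec.seed)
    L = _build_loadings(spec)
    psi = 1.0 - (L**2).sum(axis=1)
    if np.any(psi <= 0):
        raise ValueError(
            "implied uniquenesses not positive: loadings imply a "
            "non-positive-definite feature covariance"
        )
    F = rng.standard_normal((spec.n, spec.m))
    eps = rng.standard_normal((spec.n, spec.p))
    Xf = F @ L.T + eps * np.sqrt(psi)

    age = rng.normal(spec.age_mean, spec.age_sd, spec.n)
    gender = rng.binomial(1, spec.gender_p_male, spec.n)
    n_stage = rng.choice(
        len(spec.n_stage_probs), size=spec.n, p=spec.n_stage_probs
    )

    bf = np.asarray(spec.beta_factors, dtype=float)
    if bf.size != spec.m:
        raise ValueError("beta_factors length must equal m")
    bc = np.asarray(spec.beta_clinical, dtype=float)
    clin = np.column_stack([n_stage, age - spec.age_mean, gender])
    eta = F @ bf + clin @ bc
    hazards = spec.baseline_hazard * np.exp(eta)

    df = pd.DataFrame(
        Xf, columns=[f"feat_{j + 1:03d}" for j in range(spec.p)]
    )
    df["age"] = age
    df["gender"] = gender
    df["n_stage"] = n_stage
    mu = _censor_rate_for(spec.censoring_rate, hazards)
    for ep in ("os", "rfs"):
        t_event = rng.exponential(1.0 / hazards)
        if mu > 0:
            t_cens = rng.exponential(1.0 / mu, spec.n)
        else:
            t_cens = np.full(spec.n, np.inf)
        t = np.minimum(t_event, t_cens)
        df[f"time_{ep}"] = t
        df[f"event_{ep}"] = (t_event <= t_cens).astype(int)
    df.index = [f"pt_{spec.seed}_{i:04d}" for i in range(spec.n)]

    truth = {
        "loadings": L,
        "uniquenesses": psi,
        "factors": F,
        "beta_factors": bf,
        "beta_clinical": bc,
        "baseline_hazard": spec.baseline_hazard,
        "censor_rate_param": mu,
        "linear_predictor": eta,
        "seed": spec.seed,
    }
    return df, truth


def paper_shaped_scenario(
    seed: int = 0,
    n_train: int = 102,
    n_validation: int = 76,
    signal: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Paired train/validation cohorts shaped like a two-center study:
    p = 50 features, m = 7 latent factors with prognostic signal on two
    factors and weakly prognostic clinical covariates.

    ``signal=False`` removes all survival signal (null calibration)."""
    bf = (0.7, 0.5, 0.0, 0.0, 0.0, 0.0, 0.0) if signal else (0.0,) * 7
    bc = (0.15, 0.01, 0.05) if signal else (0.0, 0.0, 0.0)
    base = dict(
        p=50,
        m=7,
        loading_strength=0.9,
        beta_factors=bf,
        beta_clinical=bc,
        baseline_hazard=0.12,
        censoring_rate=0.45,
    )
    train, truth_tr = generate_tabular_cohort(
        TabularCohortSpec(n=n_train, seed=seed * 2 + 1, **base)
    )
    val, truth_va = generate_tabular_cohort(
        TabularCohortSpec(n=n_validation, seed=seed * 2 + 2, **base)
    )
    return train, val, {"train": truth_tr, "validation": truth_va}
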