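"""Gray-level run-length matrix (GLRLM) texture features.

A run is a maximal segment of collinear, face/edge/corner-consecutive
in-mask voxels sharing one gray level. Matrices are built per direction (13
unique directions in 3D; 4 in-plane directions in 2D, runs confined to
axial slices and counted across all slices), then either the 16 features
are averaged over directions (``averaged``) or the matrices are summed and
the features computed once (``merged``; the run-percentage denominator then
counts each voxel once per direction).
"""

from __future__ import annotations

import numpy as np

from ..volume_io import DiscreteVOI
from .glcm import DIRECTIONS_2D, DIRECTIONS_3D
from .ids import GLRLM_NAMES

__all__ = ["glrlm_matrices", "glrlm_features_from_matrix", "glrlm_features"]


def _shift(arr: np.ndarray, d: tuple[int, int, int], fill) -> np.ndarray:
    """Value at v becomes arr[v - d]; voxels shifted in from outside get fill."""
    out = np.full_like(arr, fill)
    src, dst = [], []
    for step, size in zip(d, arr.shape):
        step = int(step)
        if abs(step) >= size:
            return out
        if step >= 0:
            src.append(slice(0, size - step))
            dst.append(slice(step, size))
        else:
            src.append(slice(-step, size))
            dst.append(slice(0, size + step))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _direction_runs(
    levels: np.ndarray, inside: np.ndarray, d: tuple[int, int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """(levels, lengths) of all maximal runs along direction d."""
    prev_lev = _shift(levels, d, 0)
    prev_in = _shift(inside, d, False)
    # voxel continues the run arriving from v - d
    cont = inside & prev_in & (levels == prev_lev)

    # run length ending at v: 1 + number of consecutive `cont` steps backwards
    length = inside.astype(np.int64)
    alive = cont.copy()
    k = 1
    while alive.any():
        length += alive
        alive = alive & _shift(cont, tuple(k * c for c in d), False)
        k += 1

    nxt = _shift(cont, tuple(-c for c in d), False)  # cont at v + d
    ends = inside & ~nxt
    return levels[ends], length[ends]


def glrlm_matrices(
    dvoi: DiscreteVOI, dimensionality: str = "3D"
) -> list[np.ndarray]:
    """Run-length count matrices r[level-1, length-1], one per direction."""
    dirs = DIRECTIONS_3D if dimensionality == "3D" else DIRECTIONS_2D
    n = dvoi.n_bins
    levels, inside = dvoi.levels, dvoi.inside
    if levels.ndim == 1:  # intensity-only VOI: treat as one 1D line
        levels = levels.reshape(-1, 1, 1)
        inside = inside.reshape(-1, 1, 1)
    mats = []
    for d in dirs:
        lev, ln = _direction_runs(levels, inside, d)
        m = np.zeros((n, int(ln.max()) if ln.size else 1), dtype=np.int64)
        np.add.at(m, (lev - 1, ln - 1), 1)
        mats.append(m)
    return mats


def glrlm_features_from_matrix(r: np.ndarray, n_voxels: int) -> dict[str, float]:
    """The 16 GLRLM features from one run-length count matrix.

    ``n_voxels`` is the run-percentage denominator (VOI voxel count, times
    the number of directions for a merged matrix).
    """
    r = np.asarray(r, dtype=float)
    n_runs = r.sum()
    if n_runs == 0:
        raise ValueError("empty run-length matrix")
    p = r / n_runs
    ng, nl = r.shape
    i = np.arange(1, ng + 1, dtype=float)  # gray levels
    j = np.arange(1, nl + 1, dtype=float)  # run lengths
    rg = r.sum(axis=1)
    rl = r.sum(axis=0)
    mu_i = float((p.sum(axis=1) * i).sum())
    mu_j = float((p.sum(axis=0) * j).sum())
    pz = p[p > 0]

    inv_i2 = 1.0 / i**2
    inv_j2 = 1.0 / j**2
    feats = {
        "short_run_emphasis": float((rl * inv_j2).sum() / n_runs),
        "long_run_emphasis": float((rl * j**2).sum() / n_runs),
        "low_gray_level_run_emphasis": float((rg * inv_i2).sum() / n_runs),
        "high_gray_level_run_emphasis": float((rg * i**2).sum() / n_runs),
        "short_run_low_gray_level_emphasis": float(
            (r * np.outer(inv_i2, inv_j2)).sum() / n_runs
        ),
        "short_run_high_gray_level_emphasis": float(
            (r * np.outer(i**2, inv_j2)).sum() / n_runs
        ),
        "long_run_low_gray_level_emphasis": float(
            (r * np.outer(inv_i2, j**2)).sum() / n_runs
        ),
        "long_run_high_gray_level_emphasis": float(
            (r * np.outer(i**2, j**2)).sum() / n_runs
        ),
        "gray_level_nonuniformity": float((rg**2).sum() / n_runs),
        "gray_level_nonuniformity_normalized": float((rg**2).sum() / n_runs**2),
        "run_length_nonuniformity": float((rl**2).sum() / n_runs),
        "run_length_nonuniformity_normalized": float((rl**2).sum() / n_runs**2),
        "run_percentage": float(n_runs / n_voxels),
        "gray_level_variance": float((p * ((i[:, None] - mu_i) ** 2)).sum()),
        "run_length_variance": float((p * ((j[None, :] - mu_j) ** 2)).sum()),
        "run_entropy": float(-(pz * np.log2(pz)).sum()),
    }
    assert set(feats) == set(GLRLM_NAMES)
    return feats


def _pad_merge(mats: list[np.ndarray]) -> np.ndarray:
    ng = mats[0].shape[0]
    nl = max(m.shape[1] for m in mats)
    out = np.zeros((ng, nl), dtype=np.int64)
    for m in mats:
        out[:, : m.shape[1]] += m
    return out


def glrlm_features(
    dvoi: DiscreteVOI,
    dimensionality: str = "3D",
    aggregation: str = "averaged",
) -> dict[str, float]:
    """The 16 GLRLM features under the given direction aggregation."""
    mats = glrlm_matrices(dvoi, dimensionality)
    n_vox = int(dvoi.inside.sum())
    if n_vox == 0:
        raise ValueError("empty VOI")
    if aggregation == "merged":
        return glrlm_features_from_matrix(_pad_merge(mats), n_vox * len(mats))
    if aggregation != "averaged":
        raise ValueError(f"unknown aggregation {aggregation!r}")
    per_dir = [glrlm_features_from_matrix(m, n_vox) for m in mats]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLRLM_NAMES}
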