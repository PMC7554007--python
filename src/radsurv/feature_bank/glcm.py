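"""Gray-level co-occurrence matrix (GLCM) texture features.

Symmetric co-occurrence counts at a fixed voxel offset (default distance 1
in index space) restricted to mask-foreground voxel pairs. 3D uses the 13
unique lattice directions; 2D uses the 4 unique in-plane (x-y) directions,
with per-slice matrices summed across all slices. Two aggregations:

* ``averaged`` — the 25 features are computed per direction matrix and then
  averaged over directions;
* ``merged`` — direction matrices are summed, normalized once, and the
  features computed from the merged matrix.

Degenerate-input conventions: a single-level VOI has correlation 1 and both
information-correlation measures 0.
"""

from __future__ import annotations

import numpy as np

from ..volume_io import DiscreteVOI
from .ids import GLCM_NAMES

__all__ = [
    "DIRECTIONS_3D",
    "DIRECTIONS_2D",
    "glcm_matrices",
    "glcm_features_from_matrix",
    "glcm_features",
]

# one representative of each +/- direction pair
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)
DIRECTIONS_2D: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (1, 1, 0),
    (1, -1, 0),
)


def _offset_pairs(levels: np.ndarray, inside: np.ndarray, d: tuple[int, int, int]):
    """Index pairs (a, b) of level values at voxels v and v+d, both in-mask."""
    sl_a, sl_b = [], []
    for step, size in zip(d, levels.shape):
        step = int(step)
        if step >= 0:
            sl_a.append(slice(0, size - step))
            sl_b.append(slice(step, size))
        else:
            sl_a.append(slice(-step, size))
            sl_b.append(slice(0, size + step))
    a, b = tuple(sl_a), tuple(sl_b)
    ok = inside[a] & inside[b]
    return levels[a][ok], levels[b][ok]


def glcm_matrices(
    dvoi: DiscreteVOI, dimensionality: str = "3D", distance: int = 1
) -> list[np.ndarray]:
    """Symmetric co-occurrence count matrices, one per direction.

    Matrix entry ``[i-1, j-1]`` counts ordered in-mask pairs with levels
    (i, j) at the direction offset, symmetrized by adding the transpose.
    """
    if distance < 1:
        raise ValueError("neighbour distance must be >= 1")
    dirs = DIRECTIONS_3D if dimensionality == "3D" else DIRECTIONS_2D
    n = dvoi.n_bins
    out = []
    for d in dirs:
        dd = tuple(distance * c for c in d)
        a, b = _offset_pairs(dvoi.levels, dvoi.inside, dd)
        m = np.zeros((n, n), dtype=np.int64)
        np.add.at(m, (a - 1, b - 1), 1)
        out.append(m + m.T)
    return out


def glcm_features_from_matrix(counts: np.ndarray) -> dict[str, float]:
    """The 25 GLCM features from one (symmetric) count or probability matrix."""
    total = counts.sum()
    if total == 0:
        raise ValueError("empty co-occurrence matrix (no valid voxel pair)")
    p = counts.astype(float) / total
    n = p.shape[0]
    lv = np.arange(1, n + 1, dtype=float)
    ii = lv[:, None] * np.ones((1, n))
    jj = ii.T

    px = p.sum(axis=1)
    mu = float((lv * px).sum())
    sigma2 = float(((lv - mu) ** 2 * px).sum())

    k_diff = np.arange(n, dtype=float)  # |i-j| = 0..n-1
    p_diff = np.zeros(n)
    k_sum = np.arange(2, 2 * n + 1, dtype=float)  # i+j = 2..2n
    p_sum = np.zeros(2 * n - 1)
    idx_d = np.abs(ii - jj).astype(int)
    idx_s = (ii + jj).astype(int) - 2
    np.add.at(p_diff, idx_d.ravel(), p.ravel())
    np.add.at(p_sum, idx_s.ravel(), p.ravel())

    def ent(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())

    da = float((k_diff * p_diff).sum())
    sa = float((k_sum * p_sum).sum())
    hxy = ent(p)
    hx = ent(px)
    pxy = px[:, None] * px[None, :]
    nz = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[nz] * np.log2(pxy[nz])).sum())
    nz2 = pxy > 0
    hxy2 = float(-(pxy[nz2] * np.log2(pxy[nz2])).sum())

    absdiff = np.abs(ii - jj)
    sqdiff = (ii - jj) ** 2
    off = ~np.eye(n, dtype=bool)

    corr = 1.0 if sigma2 == 0 else float(
        (((ii - mu) * (jj - mu) * p).sum()) / sigma2
    )
    imc1 = 0.0 if hx == 0 else (hxy - hxy1) / hx
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    feats = {
        "joint_maximum": float(p.max()),
        "joint_average": mu,
        "joint_variance": float((((ii - mu) ** 2) * p).sum()),
        "joint_entropy": hxy,
        "difference_average": da,
        "difference_variance": float(((k_diff - da) ** 2 * p_diff).sum()),
        "difference_entropy": ent(p_diff),
        "sum_average": sa,
        "sum_variance": float(((k_sum - sa) ** 2 * p_sum).sum()),
        "sum_entropy": ent(p_sum),
        "angular_second_moment": float((p**2).sum()),
        "contrast": float((sqdiff * p).sum()),
        "dissimilarity": float((absdiff * p).sum()),
        "inverse_difference": float((p / (1.0 + absdiff)).sum()),
        "inverse_difference_normalized": float((p / (1.0 + absdiff / n)).sum()),
        "inverse_difference_moment": float((p / (1.0 + sqdiff)).sum()),
        "inverse_difference_moment_normalized": float((p / (1.0 + sqdiff / n**2)).sum()),
        "inverse_variance": float((p[off] / sqdiff[off]).sum()),
        "correlation": corr,
        "autocorrelation": float((ii * jj * p).sum()),
        "cluster_tendency": float(((ii + jj - 2 * mu) ** 2 * p).sum()),
        "cluster_shade": float(((ii + jj - 2 * mu) ** 3 * p).sum()),
        "cluster_prominence": float(((ii + jj - 2 * mu) ** 4 * p).sum()),
        "information_correlation1": imc1,
        "information_correlation2": imc2,
    }
    assert set(feats) == set(GLCM_NAMES)
    return feats


def glcm_features(
    dvoi: DiscreteVOI,
    dimensionality: str = "3D",
    aggregation: str = "averaged",
    distance: int = 1,
) -> dict[str, float]:
    """The 25 GLCM features under the given direction aggregation."""
    mats = glcm_matrices(dvoi, dimensionality, distance)
    mats = [m for m in mats if m.sum() > 0]
    if not mats:
        raise ValueError("no valid voxel pair in any direction")
    if aggregation == "merged":
        return glcm_features_from_matrix(np.sum(mats, axis=0))
    if aggregation != "averaged":
        raise ValueError(f"unknown aggregation {aggregation!r}")
    per_dir = [glcm_features_from_matrix(m) for m in mats]
    return {k: float(np.mean([f[k] for f in per_dir])) for k in GLCM_NAMES}
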