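"""Fractal features of the segmentation mask (4 features).

Box counting runs over dyadic box sizes s in {1, 2, 4, ...} up to half the
largest bounding-box edge, with the box grid anchored at the bounding-box
corner; N(s) counts boxes intersecting the mask.

* fractal dimension (fitted): minus the slope of the ordinary least-squares
  line of log N(s) on log s over all scales;
* fractal dimension (calculated): the mean of the per-adjacent-scale-pair
  slopes -(Delta log N)/(Delta log s);
* fractal abundance: exp of the fitted intercept, i.e. the fitted N at s = 1
  (natural-log fit);
* fractal lacunarity: gliding-box lacunarity 1 + var(M)/mean(M)^2 of box
  masses M at the smallest scale s* > 1 (s* = 2), over all boxes fully
  inside the bounding box.
"""

from __future__ import annotations

import numpy as np

from ..volume_io import SegmentationMask

__all__ = ["fractal_features", "box_counts", "gliding_box_lacunarity"]


def _bbox_crop(mask: SegmentationMask) -> np.ndarray:
    from scipy import ndimage

    sl = ndimage.find_objects(mask.values.astype(np.int8))[0]
    return mask.values[sl]


def box_counts(sub: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Dyadic box sizes and intersect counts N(s) over the bounding box."""
    max_edge = max(sub.shape)
    sizes = []
    s = 1
    while s <= max_edge / 2:
        sizes.append(s)
        s *= 2
    if len(sizes) < 2:
        raise ValueError("mask too small for box counting (need >= 2 scales)")
    counts = []
    for s in sizes:
        n = 0
        pads = [(0, (-d) % s) for d in sub.shape]
        a = np.pad(sub, pads)
        view = a.reshape(
            a.shape[0] // s, s, a.shape[1] // s, s, a.shape[2] // s, s
        )
        n = int(view.any(axis=(1, 3, 5)).sum())
        counts.append(n)
    return np.asarray(sizes, dtype=float), np.asarray(counts, dtype=float)


def gliding_box_lacunarity(sub: np.ndarray, s: int = 2) -> float:
    """Lacunarity 1 + var(M)/mean(M)^2 of gliding s^3 box masses."""
    if any(d < s for d in sub.shape):
        return 1.0
    c = sub.astype(np.int64)
    for axis in range(3):
        c = np.cumsum(c, axis=axis)
    c = np.pad(c, ((1, 0), (1, 0), (1, 0)))
    # inclusion-exclusion over the integral image for all fully-inside boxes
    def S(i, j, k):
        return c[i : i + c.shape[0] - s, j : j + c.shape[1] - s, k : k + c.shape[2] - s]

    masses = (
        S(s, s, s) - S(0, s, s) - S(s, 0, s) - S(s, s, 0)
        + S(s, 0, 0) + S(0, s, 0) + S(0, 0, s) - S(0, 0, 0)
    ).astype(float)
    mean = masses.mean()
    if mean == 0:
        return 1.0
    return float(1.0 + masses.var(ddof=0) / mean**2)


def fractal_features(mask: SegmentationMask) -> dict[str, float]:
    if mask.n_foreground == 0:
        raise ValueError("empty mask")
    sub = _bbox_crop(mask)
    sizes, counts = box_counts(sub)
    ls, ln = np.log(sizes), np.log(counts)
    slope, intercept = np.polyfit(ls, ln, 1)
    pair_slopes = -np.diff(ln) / np.diff(ls)
    return {
        "fractal_dimension_calculated": float(pair_slopes.mean()),
        "fractal_dimension_fitted": float(-slope),
        "fractal_abundance": float(np.exp(intercept)),
        "fractal_lacunarity": gliding_box_lacunarity(sub, s=2),
    }
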