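"""First-order intensity statistics (35 features).

Nine statistics of the entire image (computed before any gray-level
normalization), twenty statistics of the raw tumor-VOI intensities, and
entropy/uniformity of the VOI at each of the three gray-level bin counts.

Conventions (fixed and documented here):

* quantiles (median, IQR) use the linear-interpolation rule;
* skewness and kurtosis are population moments (biased, ``n`` denominator);
  on constant data both skewness and kurtosis are reported as 0 (excess
  kurtosis as well);
* the coefficient of variation is reported in percent; a zero mean makes it
  undefined and the configured sentinel policy applies (default: value 0);
* "values over 0.5" statistics scale the whole image linearly onto [0, 1]
  and keep the strictly-greater-than-0.5 voxels (background suppression); a
  constant image has no such voxels and the sentinel policy applies;
* Max_star averages the largest VOI voxel (first in lexicographic voxel
  order if tied) with its six face neighbours, reading neighbour intensities
  from the image and ignoring neighbours outside the grid;
* the mean Laplacian uses the 6-neighbour discrete Laplacian with zero-flux
  boundary at the mask edge (out-of-mask neighbours take the centre value);
* entropy is in bits; a single-level VOI has entropy 0 and uniformity 1.
"""

from __future__ import annotations

import numpy as np

from ..volume_io import (
    DiscreteVOI,
    SegmentationMask,
    TumorVOI,
    VolumeGrid,
    discretize,
)
from .ids import BIN_COUNTS

__all__ = ["first_order_features", "entropy_bits", "uniformity"]


def entropy_bits(levels: np.ndarray) -> float:
    """Shannon entropy (bits) of a discrete gray-level sample."""
    _, counts = np.unique(np.asarray(levels).ravel(), return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def uniformity(levels: np.ndarray) -> float:
    """Sum of squared gray-level probabilities (a.k.a. energy)."""
    _, counts = np.unique(np.asarray(levels).ravel(), return_counts=True)
    p = counts / counts.sum()
    return float((p * p).sum())


def _over_half_stats(image: np.ndarray, sentinel: float) -> dict[str, float]:
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        sel = np.empty(0)
    else:
        scaled = (image - lo) / (hi - lo)
        sel = image[scaled > 0.5]
    if sel.size == 0:
        return {
            "image_maximum_over_half": sentinel,
            "image_median_over_half": sentinel,
            "image_mean_over_half": sentinel,
        }
    return {
        "image_maximum_over_half": float(sel.max()),
        "image_median_over_half": float(np.median(sel)),
        "image_mean_over_half": float(sel.mean()),
    }


def _max_star(vol: VolumeGrid, mask: SegmentationMask) -> float:
    vals = vol.values
    inside = mask.values
    flat = np.where(inside.ravel(), vals.ravel(), -np.inf)
    idx = int(np.argmax(flat))  # first lexicographic argmax within the mask
    i, j, k = np.unravel_index(idx, vals.shape)
    acc = [vals[i, j, k]]
    for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)):
        ii, jj, kk = i + d[0], j + d[1], k + d[2]
        if 0 <= ii < vals.shape[0] and 0 <= jj < vals.shape[1] and 0 <= kk < vals.shape[2]:
            acc.append(vals[ii, jj, kk])
    return float(np.mean(acc))


def _mean_laplacian(vol: VolumeGrid, mask: SegmentationMask) -> float:
    vals = vol.values.astype(float)
    inside = mask.values
    lap = np.zeros_like(vals)
    for axis in range(3):
        for shift in (1, -1):
            nb = np.roll(vals, shift, axis=axis)
            nb_in = np.roll(inside, shift, axis=axis)
            # rolled-around voxels are outside the grid, hence outside the mask
            edge = [slice(None)] * 3
            edge[axis] = 0 if shift == 1 else -1
            nb_in = nb_in.copy()
            nb_in[tuple(edge)] = False
            contrib = np.where(nb_in, nb, vals)  # zero-flux at mask boundary
            lap += contrib - vals
    return float(lap[inside].mean())


def first_order_features(
    vol: VolumeGrid,
    mask: SegmentationMask,
    voi: TumorVOI | None = None,
    bin_counts: tuple[int, ...] = BIN_COUNTS,
    sentinel: float = 0.0,
) -> dict[str, float]:
    """Compute the 35 first-order features.

    Returns a name -> value mapping using the canonical first-order names
    (binned statistics as ``entropy@<bins>`` / ``uniformity@<bins>``).
    """
    if voi is None:
        from ..volume_io import extract_voi

        voi = extract_voi(vol, mask)
    x = voi.intensities
    if x.size == 0:
        raise ValueError("empty VOI")

    img = vol.values
    out: dict[str, float] = {
        "image_maximum": float(img.max()),
        "image_minimum": float(img.min()),
        "image_range": float(img.max() - img.min()),
        "image_mean": float(img.mean()),
        "image_median": float(np.median(img)),
        "image_sd": float(img.std(ddof=0)),
    }
    out.update(_over_half_stats(img, sentinel))

    mean = float(x.mean())
    med = float(np.median(x))
    var = float(x.var(ddof=0))
    sd = float(np.sqrt(var))
    q75, q25 = np.percentile(x, [75, 25])  # linear interpolation
    if sd > 0:
        z = (x - mean) / sd
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4))
    else:
        skew, kurt = 0.0, 0.0
    vvol = voi.voxel_volume
    out.update(
        {
            "maximum": float(x.max()),
            "minimum": float(x.min()),
            "range": float(x.max() - x.min()),
            "mean": mean,
            "median": med,
            "sd": sd,
            "iqr": float(q75 - q25),
            "cov_percent": (100.0 * sd / mean) if mean != 0 else sentinel,
            "skewness": skew,
            "kurtosis": kurt,
            "excess_kurtosis": kurt - 3.0 if sd > 0 else 0.0,
            "median_ad_median": float(np.median(np.abs(x - med))),
            "mean_ad_median": float(np.mean(np.abs(x - med))),
            "mean_ad_mean": float(np.mean(np.abs(x - mean))),
            "mean_laplacian": _mean_laplacian(vol, mask),
            "total_energy": float(np.sum(x**2) * vvol),
            "variance": var,
            "rms": float(np.sqrt(np.mean(x**2))),
            "max_star": _max_star(vol, mask),
            "integrated_intensity": mean * x.size * vvol,
        }
    )

    for b in bin_counts:
        dv: DiscreteVOI = discretize(voi, b)
        levels = dv.foreground_levels
        out[f"entropy@{b}"] = entropy_bits(levels)
        out[f"uniformity@{b}"] = uniformity(levels)
    return out
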