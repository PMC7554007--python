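"""Spatial autocorrelation of VOI intensities: Moran's I and Geary's C.

Spatial weights are binary rook contiguity on the voxel lattice: w_ij = 1
iff voxels i and j are face-adjacent (6-neighbourhood) and both inside the
mask. Both statistics are undefined for a constant VOI and raise.
"""

from __future__ import annotations

import numpy as np

from ..volume_io import SegmentationMask, VolumeGrid, check_alignment

__all__ = ["spatial_autocorrelation", "UndefinedStatisticError"]


class UndefinedStatisticError(ValueError):
    """Statistic undefined on this input (e.g. zero variance)."""


def spatial_autocorrelation(
    vol: VolumeGrid, mask: SegmentationMask
) -> tuple[float, float]:
    """Return (Moran's I, Geary's C) of the in-mask intensities.

    I = (n/W) * sum_ij w_ij (x_i - m)(x_j - m) / sum_i (x_i - m)^2
    C = ((n-1)/(2W)) * sum_ij w_ij (x_i - x_j)^2 / sum_i (x_i - m)^2

    with W the total weight sum over ordered pairs.
    """
    check_alignment(vol, mask)
    inside = mask.values
    n = int(inside.sum())
    if n < 2:
        raise UndefinedStatisticError("need at least 2 VOI voxels")
    x = vol.values.astype(float)
    m = x[inside].mean()
    denom = float(((x[inside] - m) ** 2).sum())
    if denom == 0:
        raise UndefinedStatisticError("zero-variance VOI: Moran/Geary undefined")

    dev = np.where(inside, x - m, 0.0)
    W = 0.0
    cross = 0.0  # sum_ij w_ij (x_i - m)(x_j - m), ordered pairs
    sqdiff = 0.0  # sum_ij w_ij (x_i - x_j)^2, ordered pairs
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        a, b = tuple(sl_a), tuple(sl_b)
        pair = inside[a] & inside[b]
        npairs = int(pair.sum())
        W += 2 * npairs  # each unordered neighbour pair counts twice
        cross += 2 * float((dev[a] * dev[b])[pair].sum())
        sqdiff += 2 * float(((x[a] - x[b]) ** 2)[pair].sum())
    if W == 0:
        raise UndefinedStatisticError("no adjacent voxel pair inside the mask")

    moran = (n / W) * cross / denom
    geary = ((n - 1) / (2 * W)) * sqdiff / denom
    return float(moran), float(geary)
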