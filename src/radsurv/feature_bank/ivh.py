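"""Intensity-volume histogram (IVH) area under the curve.

The VOI intensities are min-max scaled to [0, 1]; the IVH curve
nu(t) = fraction of VOI voxels with scaled intensity >= t is integrated by
the trapezoid rule over a uniform 1000-point threshold grid on [0, 1]. A
constant VOI is all-maximum by convention, giving AUC = 1.
"""

from __future__ import annotations

import numpy as np

from ..volume_io import TumorVOI

__all__ = ["ivh_auc"]

N_GRID = 1000


def ivh_auc(voi: TumorVOI) -> float:
    x = np.asarray(voi.intensities, dtype=float)
    if x.size == 0:
        raise ValueError("empty VOI")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return 1.0
    s = np.sort((x - lo) / (hi - lo))
    t = np.linspace(0.0, 1.0, N_GRID)
    # fraction of voxels with scaled intensity >= t
    nu = 1.0 - np.searchsorted(s, t, side="left") / s.size
    return float(np.trapezoid(nu, t))
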