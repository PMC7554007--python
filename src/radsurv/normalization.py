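"""Gray-level normalization variants and their concordance assessment.

Five registered intensity transforms span linear, robust-linear and
rank-based families; the registry is pluggable (``register_method``). The
concordance check quantifies, per feature, how strongly the patient ranking
is preserved across extraction conditions (raw plus each normalization)
using Kendall's coefficient of concordance W — the robustness argument for
modelling on unnormalized intensities when W is high.
"""

from __future__ import annotations

from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .volume_io import VolumeGrid

__all__ = [
    "NORMALIZATION_METHODS",
    "register_method",
    "normalize",
    "kendalls_w",
    "normalization_concordance",
]


def _spread_guard(spread: float, name: str) -> None:
    if spread == 0:
        raise ValueError(f"zero-spread image: {name} normalization undefined")


def _minmax(x: np.ndarray, **_) -> np.ndarray:
    lo, hi = x.min(), x.max()
    _spread_guard(hi - lo, "minmax")
    return (x - lo) / (hi - lo)


def _zscore(x: np.ndarray, **_) -> np.ndarray:
    sd = x.std(ddof=0)
    _spread_guard(sd, "zscore")
    return (x - x.mean()) / sd


def _median_iqr(x: np.ndarray, **_) -> np.ndarray:
    q75, q25 = np.percentile(x, [75, 25])
    _spread_guard(q75 - q25, "median_iqr")
    return (x - np.median(x)) / (q75 - q25)


def _percentile_clip_rescale(x: np.ndarray, p_low: float = 1.0,
                             p_high: float = 99.0, **_) -> np.ndarray:
    lo, hi = np.percentile(x, [p_low, p_high])
    _spread_guard(hi - lo, "percentile_clip_rescale")
    return (np.clip(x, lo, hi) - lo) / (hi - lo)


def _histogram_equalization(x: np.ndarray, **_) -> np.ndarray:
    # rank-based (average ranks on ties) mapping onto [0, 1]
    flat = x.ravel()
    _spread_guard(flat.max() - flat.min(), "histogram_equalization")
    r = rankdata(flat, method="average")
    return ((r - 1) / (flat.size - 1)).reshape(x.shape)


NORMALIZATION_METHODS: dict[str, Callable[..., np.ndarray]] = {
    "minmax": _minmax,
    "zscore": _zscore,
    "median_iqr": _median_iqr,
    "percentile_clip_rescale": _percentile_clip_rescale,
    "histogram_equalization": _histogram_equalization,
}


def register_method(name: str, fn: Callable[..., np.ndarray]) -> None:
    """Register (or replace) a normalization method in the registry."""
    NORMALIZATION_METHODS[name] = fn


def normalize(vol: VolumeGrid, method: str, **params) -> VolumeGrid:
    """Apply a registered gray-level normalization to the whole image."""
    if method not in NORMALIZATION_METHODS:
        raise ValueError(
            f"unknown normalization {method!r}; "
            f"registered: {sorted(NORMALIZATION_METHODS)}"
        )
    out = NORMALIZATION_METHODS[method](vol.values.astype(float), **params)
    return VolumeGrid(out, spacing=vol.spacing, origin=vol.origin,
                      orientation=vol.orientation)


def kendalls_w(ratings: np.ndarray) -> float:
    """Tie-corrected Kendall coefficient of concordance.

    ``ratings`` is an (m raters, n subjects) array; each rater ranks the n
    subjects. Returns W in [0, 1]; 1 iff all rankings are identical (no
    ties), 0 when rank sums are perfectly balanced.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2:
        raise ValueError("ratings must be 2D (raters x subjects)")
    m, n = ratings.shape
    if m < 2 or n < 2:
        raise ValueError("need at least 2 raters and 2 subjects")
    ranks = np.vstack([rankdata(row, method="average") for row in ratings])
    rank_sums = ranks.sum(axis=0)
    S = float(((rank_sums - rank_sums.mean()) ** 2).sum())
    ties = 0.0
    for row in ranks:
        _, counts = np.unique(row, return_counts=True)
        ties += float((counts**3 - counts).sum())
    denom = m**2 * (n**3 - n) - m * ties
    if denom <= 0:  # all raters tie every subject: no information
        return 1.0
    return float(12.0 * S / denom)


def normalization_concordance(
    feature_tables: Mapping[str, pd.DataFrame] | Iterable[pd.DataFrame],
    feature_subset: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Per-feature Kendall's W across extraction conditions.

    Each table is patients x features (same index and columns); conditions
    act as raters ranking the patients. Returns a frame indexed by feature
    with column ``W``; overall mean/SD are in ``.attrs``.
    """
    if isinstance(feature_tables, Mapping):
        tables = list(feature_tables.values())
    else:
        tables = list(feature_tables)
    if len(tables) < 2:
        raise ValueError("need at least 2 conditions")
    base = tables[0]
    if len(base.index) < 2:
        raise ValueError("need at least 2 patients")
    for t in tables[1:]:
        if not (t.index.equals(base.index) and t.columns.equals(base.columns)):
            raise ValueError("all condition tables must share patients and features")
    cols = list(feature_subset) if feature_subset is not None else list(base.columns)
    w = {
        c: kendalls_w(np.vstack([t[c].to_numpy() for t in tables])) for c in cols
    }
    out = pd.DataFrame({"W": pd.Series(w)})
    out.attrs["mean_W"] = float(out["W"].mean())
    out.attrs["sd_W"] = float(out["W"].std(ddof=1)) if len(out) > 1 else 0.0
    return out
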