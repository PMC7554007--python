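"""Core-feature consolidation, interobserver stability, redundancy filtering.

The 545 raw features contain systematic variants of the same quantity
(3 bin counts x 2 aggregations x 2 dimensionalities for texture; 3 bin
counts for first-order entropy/uniformity). Consolidation averages the
variants of each (family, name) group into one core feature. Interobserver
stability scores each core feature by Kendall's W across two observers'
segmentations against a 0.7 concordance bar. Redundancy filtering then
iteratively drops the most globally correlated member of any feature pair
whose |Pearson r| exceeds a threshold (default 0.95).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .feature_bank.ids import FeatureId, all_feature_ids
from .normalization import kendalls_w

__all__ = [
    "consolidate",
    "core_grouping",
    "StabilityReport",
    "interobserver_stability",
    "RedundancyFilter",
    "redundancy_filter",
]


def core_grouping(
    feature_ids: list[str] | None = None,
    grouping_key=None,
) -> dict[str, list[str]]:
    """Map core-feature name -> raw variant ids.

    The default key collapses all bin/aggregation/dimensionality variants of
    one (family, name) pair; pass ``grouping_key`` (FeatureId -> hashable)
    to override.
    """
    if feature_ids is None:
        feature_ids = [str(f) for f in all_feature_ids()]
    key = grouping_key or (lambda fid: fid.core_key)
    groups: dict = {}
    for s in feature_ids:
        fid = FeatureId.parse(s)
        groups.setdefault(key(fid), []).append(s)
    return {
        (k if isinstance(k, str) else ".".join(map(str, k))): v
        for k, v in groups.items()
    }


def consolidate(
    features: pd.Series | pd.DataFrame,
    grouping_key=None,
) -> tuple[pd.Series | pd.DataFrame, dict[str, list[str]]]:
    """Average variant features into core features.

    Accepts one raw feature vector (Series) or a patients x features matrix
    (DataFrame). The full raw enumeration must be present when the input
    columns are raw ids; already-consolidated inputs pass through unchanged
    (idempotence). Returns (core data, grouping map).
    """
    is_series = isinstance(features, pd.Series)
    cols = list(features.index if is_series else features.columns)
    try:
        parsed_all = all(FeatureId.parse(c).n_bins is None and "." in c for c in cols)
    except (ValueError, IndexError):
        parsed_all = True  # non-raw ids: treat as already consolidated
    if parsed_all:
        return features.copy(), {c: [c] for c in cols}

    expected = {str(f) for f in all_feature_ids()}
    missing = expected - set(cols)
    if missing:
        raise ValueError(
            f"incomplete raw feature set; missing {len(missing)} ids, "
            f"e.g. {sorted(missing)[:3]}"
        )
    groups = core_grouping(cols, grouping_key)
    frame = features.to_frame().T if is_series else features
    out = pd.DataFrame(
        {core: frame[members].mean(axis=1) for core, members in groups.items()},
        index=frame.index,
    )
    if is_series:
        return out.iloc[0].rename(features.name), groups
    return out, groups


@dataclass
class StabilityReport:
    """Per-core-feature interobserver concordance."""

    W: pd.Series
    threshold: float
    passed: pd.Series = field(init=False)
    mean_W: float = field(init=False)
    sd_W: float = field(init=False)

    def __post_init__(self) -> None:
        self.passed = self.W >= self.threshold
        self.mean_W = float(self.W.mean())
        self.sd_W = float(self.W.std(ddof=1)) if len(self.W) > 1 else 0.0


def interobserver_stability(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    threshold: float = 0.7,
) -> StabilityReport:
    """Kendall's W per feature across two observers' patient rankings."""
    if not table_a.index.equals(table_b.index):
        raise ValueError("observer tables must cover the same patients")
    if not table_a.columns.equals(table_b.columns):
        raise ValueError("observer tables must cover the same features")
    w = pd.Series(
        {
            c: kendalls_w(
                np.vstack([table_a[c].to_numpy(), table_b[c].to_numpy()])
            )
            for c in table_a.columns
        }
    )
    return StabilityReport(W=w, threshold=threshold)


class RedundancyFilter(BaseEstimator, TransformerMixin):
    """Iterative pairwise-correlation feature filter (sklearn transformer).

    While any feature pair has |Pearson r| > ``tau``, remove the feature of
    the worst pair with the largest mean absolute correlation to all
    remaining features; ties break by lexicographic feature id. Fitted
    attributes: ``survivors_`` (ordered kept ids), ``removal_log_`` (ordered
    list of dicts with the removed id, its partner and the trigger
    correlation).
    """

    def __init__(self, tau: float = 0.95):
        self.tau = tau

    def fit(self, X: pd.DataFrame, y=None) -> "RedundancyFilter":
        X = pd.DataFrame(X)
        if X.shape[1] < 2 or X.shape[0] < 3:
            raise ValueError("need >= 2 features and >= 3 patients")
        sd = X.std(ddof=0)
        dead = sd[sd == 0].index.tolist()
        if dead:
            raise ValueError(f"zero-variance columns: {dead[:5]}")
        if X.isna().any().any():
            raise ValueError("missing values are not allowed before filtering")

        corr = X.corr().abs()
        cols = list(X.columns)
        log: list[dict] = []
        while True:
            sub = corr.loc[cols, cols].to_numpy().copy()
            np.fill_diagonal(sub, 0.0)
            if sub.max() <= self.tau:
                break
            i, j = np.unravel_index(np.argmax(sub), sub.shape)
            mean_abs = sub.mean(axis=0) * len(cols) / max(len(cols) - 1, 1)
            # drop the member of the offending pair with larger global
            # redundancy; lexicographic tie-break
            cand = sorted(
                (cols[i], cols[j]),
                key=lambda c: (-mean_abs[cols.index(c)], c),
            )
            drop = cand[0]
            keep = cand[1]
            log.append(
                {
                    "removed": drop,
                    "partner": keep,
                    "correlation": float(corr.loc[drop, keep]),
                }
            )
            cols.remove(drop)
        self.survivors_ = cols
        self.removal_log_ = log
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(X)[self.survivors_]


def redundancy_filter(
    core: pd.DataFrame, tau: float = 0.95
) -> tuple[pd.DataFrame, list[dict]]:
    """Functional wrapper over :class:`RedundancyFilter`."""
    f = RedundancyFilter(tau=tau).fit(core)
    return f.transform(core), f.removal_log_
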