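"""Assemble the complete 545-feature vector for one tumor."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..volume_io import (
    SegmentationMask,
    VolumeGrid,
    check_alignment,
    discretize,
    extract_voi,
    resample_isotropic,
)
from .autocorrelation import spatial_autocorrelation
from .first_order import first_order_features
from .fractal import fractal_features
from .glcm import glcm_features
from .glrlm import glrlm_features
from .ids import (
    AGGREGATIONS,
    BIN_COUNTS,
    DIMENSIONALITIES,
    FeatureId,
    all_feature_ids,
)
from .ivh import ivh_auc
from .morphology import morphology_features

__all__ = ["ExtractionConfig", "RadiomicsExtractor", "extract_all",
           "to_long_frame"]


@dataclass(frozen=True)
class ExtractionConfig:
    """Extraction settings for the raw feature bank.

    ``resample_mm``: optional isotropic resampling spacing; default off, so
    features are computed on the native (possibly anisotropic) grid with the
    physical spacing carried into morphology. ``distance``: texture
    neighbour offset in voxels. ``sentinel``: value substituted where a
    statistic is undefined (e.g. coefficient of variation at mean 0) when
    ``undefined="sentinel"``; set ``undefined="error"`` to raise instead.
    """

    bin_counts: tuple[int, ...] = BIN_COUNTS
    distance: int = 1
    resample_mm: float | None = None
    undefined: str = "sentinel"
    sentinel: float = 0.0

    def hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


class RadiomicsExtractor:
    """Configured extractor producing complete 545-entry feature vectors."""

    def __init__(self, config: ExtractionConfig | None = None):
        self.config = config or ExtractionConfig()

    def extract(self, vol: VolumeGrid, mask: SegmentationMask) -> pd.Series:
        cfg = self.config
        check_alignment(vol, mask)
        if mask.n_foreground == 0:
            raise ValueError("empty segmentation mask")
        if cfg.resample_mm is not None:
            vol = resample_isotropic(vol, cfg.resample_mm, "linear")
            mask = resample_isotropic(mask, cfg.resample_mm)
        voi = extract_voi(vol, mask)

        values: dict[str, float] = {}

        def put(fid: FeatureId, v: float, current=None) -> None:
            if not np.isfinite(v):
                if cfg.undefined == "error":
                    raise ValueError(f"feature {fid} is undefined on this input")
                v = cfg.sentinel
            values[str(fid)] = float(v)

        fo = first_order_features(vol, mask, voi, cfg.bin_counts, cfg.sentinel)
        for name, v in fo.items():
            if "@" in name:
                base, b = name.split("@")
                fid = FeatureId("first_order", base, n_bins=int(b))
            else:
                region = "entire_image" if name.startswith("image_") else "voi"
                fid = FeatureId("first_order", name, source_region=region)
            put(fid, v)

        try:
            moran, geary = spatial_autocorrelation(vol, mask)
        except ValueError as exc:
            if cfg.undefined == "error":
                raise ValueError(f"autocorrelation undefined: {exc}") from exc
            moran = geary = cfg.sentinel
        put(FeatureId("autocorrelation", "morans_i"), moran)
        put(FeatureId("autocorrelation", "gearys_c"), geary)

        put(FeatureId("ivh", "ivh_auc"), ivh_auc(voi))

        for name, v in morphology_features(mask).items():
            put(FeatureId("morphology", name), v)
        for name, v in fractal_features(mask).items():
            put(FeatureId("fractal", name), v)

        for b in cfg.bin_counts:
            dvoi = discretize(vol, b, mask)
            for dim in DIMENSIONALITIES:
                for agg in AGGREGATIONS:
                    try:
                        gl = glcm_features(dvoi, dim, agg, cfg.distance)
                        rl = glrlm_features(dvoi, dim, agg)
                    except ValueError as exc:
                        raise ValueError(
                            f"texture failure at bins={b} {dim} {agg}: {exc}"
                        ) from exc
                    for name, v in gl.items():
                        put(FeatureId("glcm", name, b, agg, dim), v)
                    for name, v in rl.items():
                        put(FeatureId("glrlm", name, b, agg, dim), v)

        expected = [str(f) for f in all_feature_ids()]
        missing = set(expected) - set(values)
        if missing:  # pragma: no cover - structural guard
            raise RuntimeError(f"incomplete feature vector, missing {sorted(missing)[:5]}")
        s = pd.Series([values[k] for k in expected], index=expected, name="value")
        s.attrs["config_hash"] = cfg.hash()
        return s


def extract_all(
    vol: VolumeGrid,
    mask: SegmentationMask,
    config: ExtractionConfig | None = None,
) -> pd.Series:
    """Complete raw feature vector (545 entries, canonical id order)."""
    return RadiomicsExtractor(config).extract(vol, mask)


def to_long_frame(features: pd.Series, patient_id: str = "patient") -> pd.DataFrame:
    """Long-form table (patient_id, family, name, n_bins, aggregation,
    dimensionality, value) from a feature vector."""
    rows = []
    for key, v in features.items():
        fid = FeatureId.parse(key)
        rows.append(
            {
                "patient_id": patient_id,
                "family": fid.family,
                "name": fid.name,
                "n_bins": fid.n_bins,
                "aggregation": fid.aggregation,
                "dimensionality": fid.dimensionality,
                "value": v,
            }
        )
    return pd.DataFrame(rows)
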