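"""Structured feature identifiers and the full 545-feature enumeration."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

FAMILIES = (
    "first_order",
    "autocorrelation",
    "ivh",
    "morphology",
    "fractal",
    "glcm",
    "glrlm",
)

BIN_COUNTS = (32, 64, 128)
AGGREGATIONS = ("averaged", "merged")
DIMENSIONALITIES = ("2D", "3D")

# whole-image statistics, computed before any normalization
FIRST_ORDER_IMAGE_NAMES = (
    "image_maximum",
    "image_minimum",
    "image_range",
    "image_mean",
    "image_median",
    "image_sd",
    "image_maximum_over_half",
    "image_median_over_half",
    "image_mean_over_half",
)

# VOI statistics on raw (undiscretized) intensities
FIRST_ORDER_VOI_NAMES = (
    "maximum",
    "minimum",
    "range",
    "mean",
    "median",
    "sd",
    "iqr",
    "cov_percent",
    "skewness",
    "kurtosis",
    "excess_kurtosis",
    "median_ad_median",
    "mean_ad_median",
    "mean_ad_mean",
    "mean_laplacian",
    "total_energy",
    "variance",
    "rms",
    "max_star",
    "integrated_intensity",
)

# VOI statistics on discretized gray levels, one per bin count
FIRST_ORDER_BINNED_NAMES = ("entropy", "uniformity")

AUTOCORRELATION_NAMES = ("morans_i", "gearys_c")

IVH_NAMES = ("ivh_auc",)

MORPHOLOGY_NAMES = (
    "volume",
    "surface_area",
    "surface_to_volume_ratio",
    "sphere_surface_ratio",
    "equivolumetric_sphere_radius",
    "compactness1",
    "compactness2",
    "spherical_disproportion",
    "sphericity",
    "asphericity",
    "max_3d_diameter",
)

FRACTAL_NAMES = (
    "fractal_dimension_calculated",
    "fractal_dimension_fitted",
    "fractal_abundance",
    "fractal_lacunarity",
)

GLCM_NAMES = (
    "joint_maximum",
    "joint_average",
    "joint_variance",
    "joint_entropy",
    "difference_average",
    "difference_variance",
    "difference_entropy",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "angular_second_moment",
    "contrast",
    "dissimilarity",
    "inverse_difference",
    "inverse_difference_normalized",
    "inverse_difference_moment",
    "inverse_difference_moment_normalized",
    "inverse_variance",
    "correlation",
    "autocorrelation",
    "cluster_tendency",
    "cluster_shade",
    "cluster_prominence",
    "information_correlation1",
    "information_correlation2",
)

GLRLM_NAMES = (
    "short_run_emphasis",
    "long_run_emphasis",
    "low_gray_level_run_emphasis",
    "high_gray_level_run_emphasis",
    "short_run_low_gray_level_emphasis",
    "short_run_high_gray_level_emphasis",
    "long_run_low_gray_level_emphasis",
    "long_run_high_gray_level_emphasis",
    "gray_level_nonuniformity",
    "gray_level_nonuniformity_normalized",
    "run_length_nonuniformity",
    "run_length_nonuniformity_normalized",
    "run_percentage",
    "gray_level_variance",
    "run_length_variance",
    "run_entropy",
)


@dataclass(frozen=True, order=True)
class FeatureId:
    """Structured identity of one raw radiomic feature.

    Texture (glcm/glrlm) ids carry a bin count, an aggregation mode and a
    dimensionality; first-order entropy/uniformity carry a bin count only;
    all other families carry none of the three.
    """

    family: str
    name: str
    n_bins: Optional[int] = None
    aggregation: Optional[str] = None
    dimensionality: Optional[str] = None
    source_region: str = "voi"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.n_bins is not None and self.n_bins not in BIN_COUNTS:
            raise ValueError(f"n_bins must be one of {BIN_COUNTS}, got {self.n_bins}")
        if self.aggregation is not None and self.aggregation not in AGGREGATIONS:
            raise ValueError(f"bad aggregation {self.aggregation!r}")
        if self.dimensionality is not None and self.dimensionality not in DIMENSIONALITIES:
            raise ValueError(f"bad dimensionality {self.dimensionality!r}")

    def __str__(self) -> str:
        parts = [self.family, self.name]
        if self.n_bins is not None:
            parts.append(f"b{self.n_bins}")
        if self.aggregation is not None:
            parts.append(self.aggregation)
        if self.dimensionality is not None:
            parts.append(self.dimensionality)
        return ".".join(parts)

    @property
    def core_key(self) -> tuple[str, str]:
        """Grouping key under which bin/aggregation/dimensionality variants
        of the same underlying feature are consolidated."""
        return (self.family, self.name)

    @classmethod
    def parse(cls, s: str) -> "FeatureId":
        parts = s.split(".")
        family, name = parts[0], parts[1]
        n_bins = aggregation = dimensionality = None
        for tok in parts[2:]:
            if tok.startswith("b") and tok[1:].isdigit():
                n_bins = int(tok[1:])
            elif tok in AGGREGATIONS:
                aggregation = tok
            elif tok in DIMENSIONALITIES:
                dimensionality = tok
            else:
                raise ValueError(f"cannot parse feature id token {tok!r} in {s!r}")
        region = "entire_image" if name.startswith("image_") else "voi"
        return cls(family, name, n_bins, aggregation, dimensionality, region)


def all_feature_ids() -> list[FeatureId]:
    """Enumerate the full raw feature bank (545 ids, stable order)."""
    ids: list[FeatureId] = []
    for name in FIRST_ORDER_IMAGE_NAMES:
        ids.append(FeatureId("first_order", name, source_region="entire_image"))
    for name in FIRST_ORDER_VOI_NAMES:
        ids.append(FeatureId("first_order", name))
    for name in FIRST_ORDER_BINNED_NAMES:
        for b in BIN_COUNTS:
            ids.append(FeatureId("first_order", name, n_bins=b))
    for name in AUTOCORRELATION_NAMES:
        ids.append(FeatureId("autocorrelation", name))
    for name in IVH_NAMES:
        ids.append(FeatureId("ivh", name))
    for name in MORPHOLOGY_NAMES:
        ids.append(FeatureId("morphology", name))
    for name in FRACTAL_NAMES:
        ids.append(FeatureId("fractal", name))
    for family, names in (("glcm", GLCM_NAMES), ("glrlm", GLRLM_NAMES)):
        for b in BIN_COUNTS:
            for agg in AGGREGATIONS:
                for dim in DIMENSIONALITIES:
                    for name in names:
                        ids.append(
                            FeatureId(family, name, n_bins=b,
                                      aggregation=agg, dimensionality=dim)
                        )
    return ids


def family_counts() -> dict[str, int]:
    counts: dict[str, int] = {f: 0 for f in FAMILIES}
    for fid in all_feature_ids():
        counts[fid.family] += 1
    return counts
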