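"""Image-volume and mask handling.

3D scalar volumes with physical voxel spacing, binary tumor segmentations on
the same grid, and the tumor volume-of-interest (VOI) abstractions the
radiomic feature extractors consume: the raw intensity VOI and its
fixed-bin-number discretization to integer gray levels.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VolumeGrid",
    "SegmentationMask",
    "TumorVOI",
    "DiscreteVOI",
    "AlignmentError",
    "EmptyMaskError",
    "read_volume",
    "read_mask",
    "write_volume",
    "check_alignment",
    "resample_isotropic",
    "extract_voi",
    "discretize",
]

#: spatial agreement tolerance for grid compatibility checks (mm)
GRID_TOL_MM = 1e-3


class AlignmentError(ValueError):
    """Volume and mask do not live on the same grid."""


class EmptyMaskError(ValueError):
    """Segmentation mask contains no foreground voxel."""


@dataclass
class VolumeGrid:
    """A 3D scalar image with physical geometry.

    Parameters
    ----------
    values : ndarray of shape (nx, ny, nz)
        Voxel intensities in arbitrary units; must be finite.
    spacing : tuple of float
        Voxel edge lengths ``(dx, dy, dz)`` in mm, all strictly positive.
    origin : tuple of float
        Physical coordinates of voxel ``(0, 0, 0)`` in mm.
    orientation : str
        Axis orientation code (informational; arrays are kept in (x, y, z)
        index order and the x-y plane is an axial slice).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(
                f"expected a 3D scalar volume, got {self.values.ndim}D data"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))


@dataclass
class SegmentationMask:
    """Binary tumor segmentation on the same grid as its companion volume.

    Any nonzero voxel is foreground.
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 3:
            raise ValueError(f"expected a 3D mask, got {arr.ndim}D data")
        self.values = arr != 0
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_foreground(self) -> int:
        return int(self.values.sum())

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class TumorVOI:
    """Intensities of the mask-foreground voxels, in stable lexicographic
    voxel-index order, plus the mask bounding box and parent-grid geometry."""

    intensities: np.ndarray
    bounding_box: tuple[slice, slice, slice]
    spacing: tuple[float, float, float]
    parent_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float).ravel()

    @property
    def n_voxels(self) -> int:
        return self.intensities.size

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class DiscreteVOI:
    """Integer gray levels (1..n_bins) over the VOI.

    ``levels`` is a 3D array cropped to the mask bounding box with 0 outside
    the mask, so texture engines can walk spatial neighbourhoods; ``inside``
    is the matching boolean foreground array.
    """

    levels: np.ndarray
    inside: np.ndarray
    n_bins: int
    intensity_range: tuple[float, float]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=np.int32)
        self.inside = np.asarray(self.inside, dtype=bool)
        if self.levels.shape != self.inside.shape:
            raise ValueError("levels and inside must share a shape")
        fg = self.levels[self.inside]
        if fg.size and (fg.min() < 1 or fg.max() > self.n_bins):
            raise ValueError("foreground levels outside [1, n_bins]")

    @property
    def foreground_levels(self) -> np.ndarray:
        """Levels of foreground voxels in lexicographic voxel order."""
        return self.levels[self.inside]


def _affine_from(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def read_volume(path: str | os.PathLike) -> VolumeGrid:
    """Read a NIfTI-1/2 scalar volume.

    Spacing is taken from the header zooms; intensities are returned
    unmodified (no scaling beyond the NIfTI slope/intercept nibabel applies).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
    except Exception as exc:  # zero-byte / truncated / non-NIfTI files
        raise IOError(f"could not read NIfTI volume from {path}: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(
            f"{path}: expected a 3D scalar image, got {data.ndim}D after squeeze"
        )
    zooms = img.header.get_zooms()[:3]
    origin = tuple(float(v) for v in np.asarray(img.affine)[:3, 3])
    ax = "".join(nib.aff2axcodes(img.affine))
    return VolumeGrid(
        values=np.asarray(data, dtype=float),
        spacing=tuple(float(z) for z in zooms),
        origin=origin,
        orientation=ax,
    )


def read_mask(path: str | os.PathLike) -> SegmentationMask:
    """Read a NIfTI segmentation; any nonzero voxel is foreground."""
    vol = read_volume(path)
    return SegmentationMask(
        values=vol.values != 0,
        spacing=vol.spacing,
        origin=vol.origin,
        orientation=vol.orientation,
    )


def write_volume(obj: VolumeGrid | SegmentationMask, path: str | os.PathLike) -> None:
    """Write a volume or mask as NIfTI-1 with a diagonal affine."""
    data = obj.values
    if data.dtype == bool:
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(np.asarray(data), _affine_from(obj.spacing, obj.origin))
    img.header.set_zooms(obj.spacing)
    nib.save(img, os.fspath(path))


def check_alignment(
    vol: VolumeGrid, mask: SegmentationMask, tol: float = GRID_TOL_MM
) -> tuple[VolumeGrid, SegmentationMask]:
    """Validate that volume and mask share shape, spacing and origin.

    Spacing/origin must agree within ``tol`` mm. Returns the pair unchanged;
    raises :class:`AlignmentError` naming the offending field otherwise.
    """
    if vol.shape != mask.shape:
        raise AlignmentError(f"shape mismatch: volume {vol.shape} vs mask {mask.shape}")
    for name, a, b in (("spacing", vol.spacing, mask.spacing),
                       ("origin", vol.origin, mask.origin)):
        if np.max(np.abs(np.subtract(a, b))) > tol:
            raise AlignmentError(f"{name} mismatch: volume {a} vs mask {b}")
    return vol, mask


def resample_isotropic(
    obj: VolumeGrid | SegmentationMask,
    target_spacing: float,
    method: str = "linear",
) -> VolumeGrid | SegmentationMask:
    """Resample a volume (tri-linear by default) or mask (always nearest
    neighbour) onto an isotropic grid with spacing ``target_spacing`` mm.

    The output grid covers the same physical extent; new shape is
    ``ceil(old_shape * old_spacing / target)`` per axis.
    """
    if target_spacing <= 0:
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    is_mask = isinstance(obj, SegmentationMask)
    orders = {"nearest": 0, "linear": 1, "cubic": 3}
    if method not in orders:
        raise ValueError(f"unknown interpolation method {method!r}")
    order = 0 if is_mask else orders[method]

    old_spacing = np.asarray(obj.spacing, dtype=float)
    old_shape = np.asarray(obj.shape, dtype=float)
    new_shape = np.maximum(1, np.ceil(old_shape * old_spacing / target_spacing)).astype(int)

    # sample at physical positions of the new voxel centres, expressed in old
    # voxel index coordinates (shared origin at voxel (0,0,0) centre)
    grids = [
        np.arange(n) * target_spacing / s for n, s in zip(new_shape, old_spacing)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    src = obj.values.astype(float)
    out = ndimage.map_coordinates(src, np.stack(coords), order=order, mode="nearest")

    t = float(target_spacing)
    if is_mask:
        return SegmentationMask(out > 0.5, spacing=(t, t, t), origin=obj.origin,
                                orientation=obj.orientation)
    return VolumeGrid(out, spacing=(t, t, t), origin=obj.origin,
                      orientation=obj.orientation)


def extract_voi(vol: VolumeGrid, mask: SegmentationMask) -> TumorVOI:
    """Collect the mask-foreground intensities (lexicographic voxel order)."""
    check_alignment(vol, mask)
    if mask.n_foreground == 0:
        raise EmptyMaskError("segmentation mask has no foreground voxel")
    bbox = ndimage.find_objects(mask.values.astype(np.int8))[0]
    return TumorVOI(
        intensities=vol.values[mask.values],
        bounding_box=bbox,
        spacing=vol.spacing,
        parent_shape=vol.shape,
    )


def discretize_values(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Fixed-bin-number gray-level discretization of raw intensities.

    Maps ``x`` onto integer levels ``1..n_bins`` with
    ``g = min(n_bins, 1 + floor(n_bins * (x - min) / (max - min)))``.
    A constant input maps every value to level 1.
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    x = np.asarray(x, dtype=float)
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        return np.ones(x.shape, dtype=np.int32)
    g = 1 + np.floor(n_bins * (x - lo) / (hi - lo))
    return np.minimum(g, n_bins).astype(np.int32)


def discretize(
    voi_or_vol,
    n_bins: int,
    mask: SegmentationMask | None = None,
) -> DiscreteVOI:
    """Discretize a tumor VOI to ``n_bins`` gray levels (fixed bin number).

    Two call forms:

    * ``discretize(vol, n_bins, mask)`` — spatial form; returns a
      :class:`DiscreteVOI` cropped to the mask bounding box, the form the
      texture engines need.
    * ``discretize(voi, n_bins)`` with a :class:`TumorVOI` — intensity-only
      form; the spatial arrays are 1D (the ordered intensity list).
    """
    if isinstance(voi_or_vol, TumorVOI):
        if voi_or_vol.n_voxels == 0:
            raise EmptyMaskError("VOI is empty")
        levels = discretize_values(voi_or_vol.intensities, n_bins)
        lo, hi = float(voi_or_vol.intensities.min()), float(voi_or_vol.intensities.max())
        inside = np.ones(levels.shape, dtype=bool)
        return DiscreteVOI(levels, inside, n_bins, (lo, hi),
                           spacing=voi_or_vol.spacing)
    vol: VolumeGrid = voi_or_vol
    if mask is None:
        raise ValueError("spatial discretization requires a mask")
    check_alignment(vol, mask)
    if mask.n_foreground == 0:
        raise EmptyMaskError("segmentation mask has no foreground voxel")
    bbox = ndimage.find_objects(mask.values.astype(np.int8))[0]
    sub_vals = vol.values[bbox]
    sub_mask = mask.values[bbox]
    fg = sub_vals[sub_mask]
    lo, hi = float(fg.min()), float(fg.max())
    levels = np.zeros(sub_vals.shape, dtype=np.int32)
    levels[sub_mask] = discretize_values(fg, n_bins)
    return DiscreteVOI(levels, sub_mask, n_bins, (lo, hi), spacing=vol.spacing)
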