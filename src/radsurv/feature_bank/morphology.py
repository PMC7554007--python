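"""Morphological (shape) features of the segmentation mask (11 features).

Volume is voxel count times physical voxel volume. Surface area comes from a
marching-cubes triangulation at iso-level 0.5 of the zero-padded mask,
anti-aliased with a small Gaussian (0.8 voxels) so the staircase artefact of
the binary lattice does not inflate the area of smooth shapes; structures
thin enough that smoothing removes the 0.5 level-crossing fall back to the
raw binary mesh. The maximum 3D diameter is the largest pairwise distance
between surface-mesh vertices, computed over the convex hull of the mesh for
tractability (hull vertices realize the diameter). The remaining features
are closed-form functions of volume V and surface area A; see
:func:`shape_descriptors`.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist
from skimage import measure

from ..volume_io import SegmentationMask

__all__ = ["morphology_features", "shape_descriptors", "mask_mesh"]


def shape_descriptors(volume: float, area: float) -> dict[str, float]:
    """Scale-free shape descriptors from a volume (mm^3) and area (mm^2).

    Separated from meshing so the formula layer can be verified against
    analytic solids (cube, ball) independently of triangulation error.
    """
    V, A = float(volume), float(area)
    r = (3.0 * V / (4.0 * np.pi)) ** (1.0 / 3.0)
    sphere_area = 4.0 * np.pi * r**2
    sphericity = np.pi ** (1.0 / 3.0) * (6.0 * V) ** (2.0 / 3.0) / A
    return {
        "volume": V,
        "surface_area": A,
        "surface_to_volume_ratio": A / V,
        "sphere_surface_ratio": A / sphere_area,
        "equivolumetric_sphere_radius": r,
        "compactness1": V / (np.sqrt(np.pi) * A ** 1.5),
        "compactness2": 36.0 * np.pi * V**2 / A**3,
        "spherical_disproportion": A / sphere_area,
        "sphericity": sphericity,
        "asphericity": (A**3 / (36.0 * np.pi * V**2)) ** (1.0 / 3.0) - 1.0,
        "max_3d_diameter": np.nan,  # filled in by the mesh layer
    }


MESH_SMOOTHING_VOXELS = 0.8


def mask_mesh(mask: SegmentationMask) -> tuple[np.ndarray, np.ndarray]:
    """Marching-cubes triangulation (vertices in mm, faces) of the mask."""
    padded = np.pad(mask.values.astype(float), 2)
    smoothed = ndimage.gaussian_filter(padded, MESH_SMOOTHING_VOXELS)
    if smoothed.max() <= 0.5:  # thin structure erased by anti-aliasing
        smoothed = padded
    verts, faces, _, _ = measure.marching_cubes(
        smoothed, level=0.5, spacing=mask.spacing
    )
    return verts, faces


def _max_diameter(verts: np.ndarray) -> float:
    if len(verts) < 2:
        return 0.0
    try:
        pts = verts[ConvexHull(verts).vertices]
    except Exception:  # degenerate (coplanar) vertex sets
        pts = verts
    if len(pts) > 4000:  # extremely irregular hulls: subsample deterministically
        pts = pts[:: len(pts) // 4000 + 1]
    return float(pdist(pts).max())


def morphology_features(mask: SegmentationMask) -> dict[str, float]:
    if mask.n_foreground == 0:
        raise ValueError("empty mask")
    V = mask.n_foreground * mask.voxel_volume
    verts, faces = mask_mesh(mask)
    A = float(measure.mesh_surface_area(verts, faces))
    out = shape_descriptors(V, A)
    out["max_3d_diameter"] = _max_diameter(verts)
    return out
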