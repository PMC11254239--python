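"""3-D shape descriptors of a binary region.

The 14-feature IBSI-style shape panel: mesh-based volume and surface
quantities (marching-cubes surface at the 0.5 iso-level), maximum 3-D
and per-plane 2-D diameters, and principal-moment axis lengths.
Masks too small to support a mesh (single voxel, or degenerate after
meshing) fall back to 0 for the mesh quantities, with a warning.
"""

from __future__ import annotations

import warnings
from typing import Dict, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist
from skimage import measure

SHAPE_NAMES = (
    "MeshVolume",
    "VoxelVolume",
    "SurfaceArea",
    "SurfaceVolumeRatio",
    "Sphericity",
    "Maximum3DDiameter",
    "Maximum2DDiameterSlice",
    "Maximum2DDiameterColumn",
    "Maximum2DDiameterRow",
    "MajorAxisLength",
    "MinorAxisLength",
    "LeastAxisLength",
    "Elongation",
    "Flatness",
)


#: Gaussian pre-smoothing (in voxels) of the binary indicator before
#: iso-surfacing; suppresses the staircase bias of the marching-cubes
#: surface area (a digitized ball otherwise overestimates area by ~8%).
_MESH_SMOOTH_SIGMA = 0.6


_MESH_PAD = 4  # keeps the smoothing kernel clear of the array border


def _mesh(mask: np.ndarray, spacing) -> Tuple[np.ndarray, np.ndarray]:
    padded = np.pad(mask.astype(np.float64), _MESH_PAD)
    if _MESH_SMOOTH_SIGMA > 0:
        padded = ndimage.gaussian_filter(padded, _MESH_SMOOTH_SIGMA)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    return verts, faces


def _mesh_volume(verts: np.ndarray, faces: np.ndarray) -> float:
    a = verts[faces[:, 0]]
    b = verts[faces[:, 1]]
    c = verts[faces[:, 2]]
    return abs(float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)


def _max_pairwise(points: np.ndarray) -> float:
    if len(points) < 2:
        return 0.0
    if len(points) > 10:
        try:
            hull = ConvexHull(points)
            points = points[hull.vertices]
        except QhullError:
            pass
    return float(pdist(points).max())


def shape_features(mask: np.ndarray, spacing_mm) -> Dict[str, float]:
    """Compute the 14 shape features of a binary mask.

    Axis lengths are ``4 * sqrt(eigenvalue)`` of the physical-coordinate
    covariance of voxel centers; elongation and flatness are the square
    roots of the corresponding eigenvalue ratios.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3-D")
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    spacing = tuple(float(s) for s in spacing_mm)
    voxel_volume = float(np.prod(spacing))

    out = dict.fromkeys(SHAPE_NAMES, 0.0)
    out["VoxelVolume"] = n * voxel_volume

    coords = np.argwhere(mask) * np.asarray(spacing)

    # principal moments
    if n >= 2:
        cov = np.cov(coords, rowvar=False, bias=True)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0.0, None)
        out["MajorAxisLength"] = 4.0 * float(np.sqrt(eig[0]))
        out["MinorAxisLength"] = 4.0 * float(np.sqrt(eig[1]))
        out["LeastAxisLength"] = 4.0 * float(np.sqrt(eig[2]))
        if eig[0] > 0:
            out["Elongation"] = float(np.sqrt(eig[1] / eig[0]))
            out["Flatness"] = float(np.sqrt(eig[2] / eig[0]))
    else:
        warnings.warn("single-voxel mask: degenerate axis lengths set to 0")

    try:
        verts, faces = _mesh(mask, spacing)
    except (ValueError, RuntimeError):  # pragma: no cover - tiny masks
        warnings.warn("marching cubes failed; mesh features set to 0")
        return out

    # marching_cubes on the padded array shifts coordinates by the pad
    verts = verts - _MESH_PAD * np.asarray(spacing)
    vol = _mesh_volume(verts, faces)
    area = float(measure.mesh_surface_area(verts, faces))
    out["MeshVolume"] = vol
    out["SurfaceArea"] = area
    if vol > 0:
        out["SurfaceVolumeRatio"] = area / vol
        out["Sphericity"] = float((36.0 * np.pi * vol**2) ** (1.0 / 3.0) / area)

    out["Maximum3DDiameter"] = _max_pairwise(verts)
    # maximum in-plane diameters: project surface vertices onto the three
    # orthogonal planes (slice = xy within a z plane, etc.); vertices are
    # grouped by their rounded plane coordinate
    for name, axis in (
        ("Maximum2DDiameterSlice", 2),
        ("Maximum2DDiameterColumn", 1),
        ("Maximum2DDiameterRow", 0),
    ):
        keep = [i for i in range(3) if i != axis]
        planes = np.round(verts[:, axis] / spacing[axis]).astype(int)
        best = 0.0
        for pv in np.unique(planes):
            pts = verts[planes == pv][:, keep]
            best = max(best, _max_pairwise(pts))
        out[name] = best
    return out
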