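"""Per-object 3D shape measurements for labeled adipocyte volumes.

Six quantities per object: volume V (voxel count × voxel volume),
equivalent diameter d_eq = (6V/π)^(1/3), surface area A (smoothed-mask
isosurface mesh), sphericity Ψ = π^(1/3)·(6V)^(2/3)/A (the surface area of
the volume-matched sphere over the object's surface area, so a perfect
sphere attains the maximum Ψ = 1), centroid (unweighted mean of voxel
centers, i.e. the binary center of gravity), and nearest object distance
NOD (Euclidean centroid-to-centroid distance to the closest other object).
Plus the aggregate object count and total object volume.

Surface areas come from a marching-cubes isosurface of the binary mask
(level 0.5, physical voxel spacing) followed by Taubin mesh smoothing,
which removes the voxel staircase without the systematic shrinkage of
Laplacian smoothing or the corner rounding of Gaussian field smoothing;
counting exposed voxel faces instead would overestimate A by ~50% for a
sphere and corrupt Ψ.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import trimesh
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage import measure as skmeasure

from .volumes import LabelVolume, ParameterError, voxel_volume

logger = logging.getLogger(__name__)

__all__ = [
    "measure_volume",
    "equivalent_diameter",
    "measure_surface_area",
    "sphericity",
    "nearest_object_distance",
    "total_object_volume",
    "measure_all",
    "NODUndefinedError",
]


class NODUndefinedError(ParameterError):
    """Nearest object distance requires at least two objects."""


def _as_label_array(labels) -> tuple[np.ndarray, tuple[float, float, float] | None]:
    if isinstance(labels, LabelVolume):
        return labels.data, labels.voxel_size
    return np.asarray(labels), None


def measure_volume(labels, voxel_size=None) -> pd.Series:
    """Per-label volume in µm³ (voxel count × dx·dy·dz), indexed by label id."""
    arr, vs = _as_label_array(labels)
    voxel_size = voxel_size or vs
    if voxel_size is None:
        raise ParameterError("voxel_size required")
    counts = np.bincount(arr.ravel())
    ids = np.flatnonzero(counts)
    ids = ids[ids > 0]
    return pd.Series(counts[ids] * voxel_volume(voxel_size), index=ids, name="volume_um3")


def equivalent_diameter(volume):
    """Diameter of the sphere with the same volume: (6V/π)^(1/3), in µm."""
    v = np.asarray(volume, dtype=float)
    if np.any(v <= 0):
        raise ParameterError("volume must be positive")
    out = (6.0 * v / np.pi) ** (1.0 / 3.0)
    return float(out) if np.isscalar(volume) or out.ndim == 0 else out


#: Taubin smoothing parameters: pass-band lambda/nu pair and iteration count.
#: 20 iterations suppress the marching-cubes staircase (~+9% area on a
#: digital sphere) to < 1% while keeping a cube's corners within ~2%.
TAUBIN_LAMB = 0.5
TAUBIN_NU = 0.53
TAUBIN_ITERS = 20


def _mesh_area_of_mask(mask: np.ndarray, spacing_zyx: tuple[float, float, float]) -> float:
    """Surface area of one binary mask: marching cubes + Taubin smoothing."""
    padded = np.pad(mask.astype(np.float32), 2)  # close the isosurface
    verts, faces, _, _ = skmeasure.marching_cubes(padded, level=0.5, spacing=spacing_zyx)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    trimesh.smoothing.filter_taubin(
        mesh, lamb=TAUBIN_LAMB, nu=TAUBIN_NU, iterations=TAUBIN_ITERS
    )
    return float(mesh.area)


def measure_surface_area(labels, voxel_size=None) -> pd.Series:
    """Per-label surface area in µm² from a Taubin-smoothed isosurface mesh.

    Objects too thin to mesh (fewer than 2 voxels along some axis, or no
    isosurface after smoothing) get NaN and a logged warning.
    """
    arr, vs = _as_label_array(labels)
    voxel_size = voxel_size or vs
    if voxel_size is None:
        raise ParameterError("voxel_size required")
    dx, dy, dz = voxel_size
    spacing = (dz, dy, dx)
    slices = ndi.find_objects(arr)
    out: dict[int, float] = {}
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        sub = arr[sl] == lab
        if min(sub.shape) < 2:
            logger.warning("object %d too thin to mesh (shape %s); area set to NaN",
                           lab, sub.shape)
            out[lab] = np.nan
            continue
        try:
            out[lab] = _mesh_area_of_mask(sub, spacing)
        except (ValueError, RuntimeError) as exc:
            logger.warning("meshing failed for object %d (%s); area set to NaN", lab, exc)
            out[lab] = np.nan
    return pd.Series(out, name="surface_area_um2", dtype=float)


def sphericity(volume, area):
    """Sphericity Ψ = π^(1/3)·(6V)^(2/3) / A; 1 for a perfect sphere."""
    v = np.asarray(volume, dtype=float)
    a = np.asarray(area, dtype=float)
    a1 = np.atleast_1d(a)
    if np.any(v <= 0) or np.any(a1[np.isfinite(a1)] <= 0):
        raise ParameterError("volume and area must be positive")
    out = np.pi ** (1.0 / 3.0) * (6.0 * v) ** (2.0 / 3.0) / a
    return float(out) if out.ndim == 0 else out


def nearest_object_distance(centroids) -> np.ndarray:
    """Per-object Euclidean distance (µm) to the nearest other centroid."""
    pts = np.asarray(centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise NODUndefinedError(
            "nearest object distance requires at least two centroids"
        )
    tree = cKDTree(pts)
    dist, _ = tree.query(pts, k=2)
    return dist[:, 1]


def total_object_volume(labels_or_mask, voxel_size=None) -> float:
    """Total foreground volume in µm³ (sum over all nonzero voxels)."""
    arr, vs = _as_label_array(labels_or_mask)
    voxel_size = voxel_size or vs
    if voxel_size is None:
        raise ParameterError("voxel_size required")
    return float(np.count_nonzero(arr) * voxel_volume(voxel_size))


def measure_all(labels, voxel_size=None, sample_id=None, group=None) -> pd.DataFrame:
    """Full per-object feature table for one labeled volume.

    Returns one row per label with columns ``label_id``, ``volume_um3``,
    ``equivalent_diameter_um``, ``surface_area_um2``, ``sphericity``,
    ``centroid_x_um``/``y``/``z``, ``nod_um``, ``sample_id``, ``group``.
    With fewer than two objects NOD is NaN (and logged).
    """
    arr, vs = _as_label_array(labels)
    voxel_size = voxel_size or vs
    if voxel_size is None:
        raise ParameterError("voxel_size required")
    dx, dy, dz = voxel_size

    vol = measure_volume(arr, voxel_size)
    ids = vol.index.to_numpy()
    if len(ids) == 0:
        return pd.DataFrame(
            columns=[
                "label_id", "volume_um3", "equivalent_diameter_um",
                "surface_area_um2", "sphericity", "centroid_x_um",
                "centroid_y_um", "centroid_z_um", "nod_um", "sample_id", "group",
            ]
        )
    area = measure_surface_area(arr, voxel_size).reindex(ids)

    # unweighted binary centroids, converted from (z, y, x) indices to µm
    com = np.array(ndi.center_of_mass(np.ones_like(arr, dtype=np.uint8), arr, ids))
    centroids = np.column_stack([com[:, 2] * dx, com[:, 1] * dy, com[:, 0] * dz])

    if len(ids) >= 2:
        nod = nearest_object_distance(centroids)
    else:
        logger.warning("single object: nearest object distance undefined, set to NaN")
        nod = np.full(len(ids), np.nan)

    df = pd.DataFrame(
        {
            "label_id": ids,
            "volume_um3": vol.to_numpy(),
            "equivalent_diameter_um": equivalent_diameter(vol.to_numpy()),
            "surface_area_um2": area.to_numpy(),
            "sphericity": np.pi ** (1.0 / 3.0)
            * (6.0 * vol.to_numpy()) ** (2.0 / 3.0)
            / area.to_numpy(),
            "centroid_x_um": centroids[:, 0],
            "centroid_y_um": centroids[:, 1],
            "centroid_z_um": centroids[:, 2],
            "nod_um": nod,
            "sample_id": sample_id,
            "group": group,
        }
    )
    df.attrs["voxel_size"] = tuple(voxel_size)
    df.attrs["object_count"] = int(len(ids))
    df.attrs["total_object_volume_um3"] = float(vol.sum())
    return df
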