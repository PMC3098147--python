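"""Mask geometry shared by the phantom generator and the quantification stage.

Coordinate convention: axis order (z, y, x), 0-based voxel indices, physical
position of a voxel center = (index + 0.5) * voxel_pitch (nm). Signed distances
to the nuclear surface are positive outside the nucleus and negative inside;
surface voxels (nucleus voxels with a non-nucleus face neighbour) are at
distance zero.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import ConfigError

__all__ = ["boundary_voxels", "signed_distance_map", "nucleus_distance"]


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Boolean map of mask voxels that touch the outside (face connectivity)."""
    mask = np.asarray(mask, dtype=bool)
    eroded = ndimage.binary_erosion(mask, structure=ndimage.generate_binary_structure(mask.ndim, 1),
                                    border_value=0)
    return mask & ~eroded


def signed_distance_map(mask: np.ndarray, voxel_pitch_nm: float) -> np.ndarray:
    """Signed Euclidean distance (nm) from every voxel center to the mask surface.

    Positive outside ``mask``, negative inside: the Euclidean distance
    transform of the complement minus the transform of the mask. Distances are
    measured between voxel centers, so values are accurate to about one voxel
    pitch and surface voxels sit within one pitch of zero.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ConfigError("mask is empty; signed distance is undefined")
    d_out = ndimage.distance_transform_edt(~mask, sampling=voxel_pitch_nm)
    d_in = ndimage.distance_transform_edt(mask, sampling=voxel_pitch_nm)
    return np.where(mask, -d_in, d_out)


def nucleus_distance(point_nm, nucleus_mask: np.ndarray, voxel_pitch_nm: float,
                     _distance_map: np.ndarray | None = None) -> float:
    """Signed distance (nm) from a physical point to the nuclear surface.

    The point is given in nm in (z, y, x) order. The distance map is sampled
    with linear interpolation at the exact physical position, so the result is
    accurate to within one voxel pitch (surface discretization). An optional
    precomputed map from :func:`signed_distance_map` avoids recomputing the
    transform per point.
    """
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if not nucleus_mask.any():
        raise ConfigError("nucleus mask is empty; distance is undefined")
    dmap = _distance_map if _distance_map is not None else signed_distance_map(nucleus_mask, voxel_pitch_nm)
    coords = np.asarray(point_nm, dtype=float) / voxel_pitch_nm - 0.5
    coords = np.clip(coords, 0.0, np.asarray(nucleus_mask.shape) - 1.0)
    return float(ndimage.map_coordinates(dmap, coords[:, None], order=1, mode="nearest")[0])
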