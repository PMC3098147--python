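"""Absorption-contrast transmission imaging forward model.

Parallel-beam Beer-Lambert projection of an attenuation volume (um^-1):
each frame pixel is exp(-L(theta)) with L the line integral of attenuation
along the ray. The rotation axis is the volume z axis (the image vertical
axis); at 0 deg the ray direction is along +x. Optional Poisson photon noise
emulates finite exposure, a Gaussian PSF of configurable FWHM emulates the
instrument's ~30 nm optical resolution, and flat-field normalization and
field-of-view patchworking mirror the standard acquisition steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigError, GeometryError, NormalizationError, PatchworkGapWarning

__all__ = ["ProjectionSet", "project", "add_photon_noise", "normalize_background", "patchwork"]

#: internal rotation offset: the rotate-and-sum projector integrates along the
#: image row axis (y); adding 90 deg makes the 0 deg ray run along +x.
_ANGLE_OFFSET_DEG = 90.0

#: full-field instrument defaults: 2048 x 2048 CCD over a 24 um field of view
#: (~11.7 nm detector pixels); tests and presets use much smaller frames.
DETECTOR_SHAPE = (2048, 2048)
FIELD_OF_VIEW_UM = 24.0
DETECTOR_PIXEL_NM = FIELD_OF_VIEW_UM * 1000.0 / DETECTOR_SHAPE[0]


@dataclass
class ProjectionSet:
    """Stack of normalized transmission frames with acquisition metadata."""

    images: np.ndarray             # (n_angles, n_rows=z, n_cols=detector)
    angles_deg: np.ndarray         # strictly increasing
    pixel_pitch_nm: float
    photon_count: float | None = None   # expected background photons/pixel
    geometry: str = "parallel"

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float64)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if self.images.ndim != 3:
            raise ConfigError("images must be a (n_angles, rows, cols) stack")
        if len(self.angles_deg) != self.images.shape[0]:
            raise ConfigError("number of angles must match number of frames")
        if len(self.angles_deg) > 1 and not np.all(np.diff(self.angles_deg) > 0):
            raise ConfigError("angles must be strictly increasing")

    @property
    def n_angles(self) -> int:
        return self.images.shape[0]


def _rotated_line_integrals(volume: np.ndarray, angle_deg: float) -> np.ndarray:
    """Line-integral frame (voxel units) at one ray angle via rotate-and-sum."""
    rot = ndimage.rotate(volume, -(angle_deg + _ANGLE_OFFSET_DEG), axes=(1, 2),
                         reshape=False, order=1, prefilter=False)
    return np.clip(rot, 0.0, None).sum(axis=1)


def project(attenuation: np.ndarray, angles_deg, voxel_pitch_nm,
            psf_fwhm_nm: float | None = None) -> ProjectionSet:
    """Beer-Lambert transmission frames of an attenuation volume.

    Parameters
    ----------
    attenuation : (z, y, x) array, um^-1, non-negative.
    angles_deg : projection angles in [0, 360), strictly increasing.
    voxel_pitch_nm : isotropic voxel pitch; a tuple of unequal pitches raises
        a :class:`GeometryError`.
    psf_fwhm_nm : optional Gaussian blur FWHM applied to each frame.
    """
    vol = np.asarray(attenuation, dtype=np.float64)
    if vol.ndim != 3:
        raise ConfigError("attenuation must be a 3D volume")
    if np.any(vol < 0):
        raise ConfigError("attenuation must be non-negative")
    pitch = np.atleast_1d(np.asarray(voxel_pitch_nm, dtype=float))
    if pitch.size > 1 and not np.allclose(pitch, pitch[0]):
        raise GeometryError("anisotropic voxel pitch is not supported")
    pitch_nm = float(pitch[0])
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if np.any((angles < 0) | (angles >= 360)):
        raise ConfigError("angles must lie in [0, 360)")
    pitch_um = pitch_nm / 1000.0
    frames = np.empty((len(angles), vol.shape[0], vol.shape[2]), dtype=np.float64)
    for i, a in enumerate(angles):
        line = _rotated_line_integrals(vol, a) * pitch_um
        frames[i] = np.exp(-np.clip(line, 0.0, None))
    if psf_fwhm_nm:
        sigma_px = psf_fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / pitch_nm
        for i in range(len(frames)):
            frames[i] = ndimage.gaussian_filter(frames[i], sigma_px)
    return ProjectionSet(images=frames, angles_deg=angles, pixel_pitch_nm=pitch_nm)


def add_photon_noise(projections: ProjectionSet, photon_count: float,
                     seed: int) -> ProjectionSet:
    """Poisson photon noise: pixel -> Poisson(N * T) / N for background count N."""
    if photon_count <= 0:
        raise ConfigError("photon_count must be positive")
    rng = np.random.default_rng(seed)
    noisy = rng.poisson(photon_count * np.clip(projections.images, 0.0, None)) / photon_count
    return replace(projections, images=noisy.astype(np.float64), photon_count=float(photon_count))


def normalize_background(raw_frame: np.ndarray, flatfield_frame: np.ndarray) -> np.ndarray:
    """Divide a raw frame by the background illumination (flat-field) frame."""
    raw = np.asarray(raw_frame, dtype=np.float64)
    flat = np.asarray(flatfield_frame, dtype=np.float64)
    if raw.shape != flat.shape:
        raise ConfigError("raw and flat-field frames must have the same shape")
    n_bad = int(np.count_nonzero(flat <= 0))
    if n_bad:
        raise NormalizationError(f"flat-field has {n_bad} non-positive pixel(s)")
    return raw / flat


def patchwork(tiles, integer_offsets) -> tuple[np.ndarray, np.ndarray]:
    """Mosaic overlapping detector tiles; overlapping pixels are averaged.

    ``integer_offsets`` are (row, col) positions of each tile's upper-left
    corner in mosaic coordinates. Returns (mosaic, coverage_count). Uncovered
    pixels interior to the tile bounding box trigger a
    :class:`PatchworkGapWarning` with the gap pixel count.
    """
    if len(tiles) == 0:
        raise ConfigError("patchwork requires at least one tile")
    if len(tiles) != len(integer_offsets):
        raise ConfigError("one offset per tile required")
    offs = [(int(r), int(c)) for r, c in integer_offsets]
    if any(r < 0 or c < 0 for r, c in offs):
        raise ConfigError("offsets must be non-negative")
    h = max(off[0] + t.shape[0] for t, off in zip(tiles, offs))
    w = max(off[1] + t.shape[1] for t, off in zip(tiles, offs))
    acc = np.zeros((h, w), dtype=np.float64)
    cov = np.zeros((h, w), dtype=np.int64)
    for t, (r, c) in zip(tiles, offs):
        acc[r:r + t.shape[0], c:c + t.shape[1]] += np.asarray(t, dtype=np.float64)
        cov[r:r + t.shape[0], c:c + t.shape[1]] += 1
    r0 = min(off[0] for off in offs)
    c0 = min(off[1] for off in offs)
    interior = cov[r0:h, c0:w]
    n_gaps = int(np.count_nonzero(interior == 0))
    if n_gaps:
        warnings.warn(f"patchwork mosaic has {n_gaps} uncovered interior pixel(s)",
                      PatchworkGapWarning)
    mosaic = np.divide(acc, cov, out=np.zeros_like(acc), where=cov > 0)
    return mosaic, cov
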