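"""Limited-angle filtered back-projection reconstruction.

Transmission frames are converted to per-slice sinograms (-log) and each
z-slice is reconstructed by ramp-filtered back-projection over exactly the
angles that were acquired — no in-painting of the missing wedge. With a 140
degree span (the instrument's mechanical limit) the missing wedge shows up as
anisotropic blur; the module reports the angular coverage alongside the
volume. Small negative values produced by the ramp filter are retained and
left to the downstream segmentation threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import iradon

from .errors import ConfigError, InsufficientAnglesError
from .optics import _ANGLE_OFFSET_DEG, ProjectionSet

__all__ = ["ReconVolume", "sinogramify", "reconstruct_fbp", "coverage_report"]

logger = logging.getLogger(__name__)


@dataclass
class ReconVolume:
    """Reconstructed attenuation volume (um^-1) with acquisition metadata."""

    volume: np.ndarray             # (z, y, x); may contain small negatives
    voxel_pitch_nm: float
    angular_coverage: dict = field(default_factory=dict)
    method: str = "fbp_ramp"


def sinogramify(projections: ProjectionSet, floor: float = 1e-8) -> np.ndarray:
    """-log of the transmission frames, reordered to (slice, angle, detector).

    Non-positive pixels (possible after Poisson noise) are clamped to
    ``floor`` before the log; the clamp count is logged.
    """
    imgs = np.asarray(projections.images, dtype=np.float64)
    n_clamped = int(np.count_nonzero(imgs < floor))
    if n_clamped:
        logger.warning("sinogramify: clamped %d non-positive pixel(s) to %.1e",
                       n_clamped, floor)
    sino = -np.log(np.clip(imgs, floor, None))
    return np.transpose(sino, (1, 0, 2))   # (slice, angle, detector column)


def reconstruct_fbp(sinograms: np.ndarray, angles_deg, pixel_pitch_nm: float,
                    apodization: str | None = None) -> ReconVolume:
    """Slice-by-slice filtered back-projection over the provided angles.

    Parameters
    ----------
    sinograms : (slice, angle, detector) line integrals, dimensionless
        (attenuation um^-1 times path length um).
    angles_deg : acquisition angles matching the sinogram's angle axis.
    apodization : ``None`` for a plain ramp filter, ``"hann"`` to apodize
        (recommended for noisy data).
    """
    sino = np.asarray(sinograms, dtype=np.float64)
    if sino.ndim == 2:
        sino = sino[None]
    if sino.ndim != 3:
        raise ConfigError("sinograms must be (slice, angle, detector)")
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if len(np.unique(angles)) < 2:
        raise InsufficientAnglesError("FBP requires at least 2 distinct angles")
    if len(angles) != sino.shape[1]:
        raise ConfigError("angle count must match the sinogram angle axis")
    filter_name = "hann" if apodization == "hann" else "ramp"
    pitch_um = pixel_pitch_nm / 1000.0
    theta = angles + _ANGLE_OFFSET_DEG     # projector's internal convention
    n_det = sino.shape[2]
    out = np.empty((sino.shape[0], n_det, n_det), dtype=np.float32)
    for z in range(sino.shape[0]):
        rec = iradon(sino[z].T / pitch_um, theta=theta, filter_name=filter_name,
                     circle=True, output_size=n_det)
        out[z] = rec.astype(np.float32)
    return ReconVolume(volume=out, voxel_pitch_nm=float(pixel_pitch_nm),
                       angular_coverage=coverage_report(angles),
                       method=f"fbp_{filter_name}")


def coverage_report(angles_deg) -> dict:
    """Angular-coverage summary: span, largest gap, limited-angle flag.

    The effective coverage is the angular span plus one mean inter-angle
    spacing (a series 0..179 deg at 1 deg steps tiles the full half-turn);
    ``limited_angle`` is true when it falls short of 180 degrees.
    """
    angles = np.sort(np.atleast_1d(np.asarray(angles_deg, dtype=float)))
    if angles.size == 0:
        return {"n_angles": 0, "span_deg": 0.0, "largest_gap_deg": 0.0,
                "mean_step_deg": 0.0, "limited_angle": True}
    span = float(angles[-1] - angles[0])
    gaps = np.diff(angles)
    largest_gap = float(gaps.max()) if gaps.size else 0.0
    mean_step = float(gaps.mean()) if gaps.size else 0.0
    limited = (span + mean_step) < 180.0 - 1e-9
    return {"n_angles": int(angles.size), "span_deg": span,
            "largest_gap_deg": largest_gap, "mean_step_deg": mean_step,
            "limited_angle": bool(limited)}
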