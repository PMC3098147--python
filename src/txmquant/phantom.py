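"""Synthetic cell phantoms with ground-truth nanoparticle clusters.

A phantom is a labeled voxel volume (background / cytoplasm / nucleus /
per-cluster ids >= 3) with an 8 keV linear-attenuation map and a ground-truth
catalog of rendered clusters. The scene emulates what absorption-contrast
transmission X-ray microscopy of a metal-nanoparticle-loaded cell assumes:

* one ellipsoidal cell containing an ellipsoidal nucleus,
* clusters rendered as mildly anisotropic gold-dense ellipsoids,
* the nucleus excludes particles (no cluster voxel inside the nuclear mask),
* cluster sizes drawn from a unimodal log-normal distribution,
* placement either uniform in the cytoplasm or in a thin perinuclear shell.

Coordinates are (z, y, x), physical position = (index + 0.5) * voxel_pitch nm.
Default attenuation values are linear coefficients at 8 keV: bulk gold
~0.4 um^-1 and soft tissue / water ~0.001 um^-1 (from standard mass-attenuation
tables); they are scene parameters, not fitted quantities.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import ConfigError, PlacementError
from .geometry import nucleus_distance, signed_distance_map
from .quant import cluster_size, fit_ellipsoid
from .records import ClusterRecord

__all__ = ["PhantomConfig", "CellPhantom", "sample_cluster_sizes", "build_phantom"]

LABEL_BACKGROUND, LABEL_CYTOPLASM, LABEL_NUCLEUS, LABEL_FIRST_CLUSTER = 0, 1, 2, 3


@dataclass
class PhantomConfig:
    """Scene parameters for one synthetic cell. All lengths in nm."""

    shape: tuple[int, int, int] = (128, 128, 128)
    voxel_pitch_nm: float = 15.0            # half the 30 nm instrument resolution
    cell_axes_nm: tuple[float, float, float] = (850.0, 850.0, 780.0)   # semi-axes
    nucleus_axes_nm: tuple[float, float, float] = (300.0, 300.0, 270.0)
    nucleus_offset_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_clusters: int = 40
    size_median_nm: float = 140.0           # log-normal median (exp of log-mean)
    size_log_sigma: float = 0.35
    min_size_nm: float | None = None        # truncate by resampling below this
    placement: str = "uniform_cytoplasm"    # or "perinuclear_shell"
    shell_inner_nm: float = 500.0
    shell_outer_nm: float = 1500.0
    mu_background: float = 0.0              # um^-1
    mu_cytoplasm: float = 0.001
    mu_nucleus: float = 0.0015
    mu_cluster: float = 0.4
    anisotropy: float = 0.15                # cluster axis jitter, +-fraction
    min_separation_nm: float = 60.0         # surface-to-surface, two resolution elements
    max_attempts: int = 1000
    seed: int = 0

    def validate(self) -> None:
        if self.voxel_pitch_nm <= 0:
            raise ConfigError("voxel pitch must be positive")
        if self.n_clusters < 0:
            raise ConfigError("n_clusters must be >= 0")
        if self.size_median_nm <= 0 or self.size_log_sigma < 0:
            raise ConfigError("size distribution parameters must be positive")
        if self.placement not in ("uniform_cytoplasm", "perinuclear_shell"):
            raise ConfigError(f"unknown placement mode {self.placement!r}")
        if self.placement == "perinuclear_shell" and not (0 < self.shell_inner_nm < self.shell_outer_nm):
            raise ConfigError("shell distances must satisfy 0 < inner < outer")
        if any(m < 0 for m in (self.mu_background, self.mu_cytoplasm, self.mu_nucleus, self.mu_cluster)):
            raise ConfigError("attenuation coefficients must be non-negative")
        if self.mu_cluster <= self.mu_cytoplasm:
            raise ConfigError("cluster attenuation must exceed cytoplasm attenuation")
        # nucleus strictly inside cell: check a dense sample of nucleus surface points
        u = np.linspace(0, np.pi, 24)
        v = np.linspace(0, 2 * np.pi, 48)
        uu, vv = np.meshgrid(u, v)
        nz, ny, nx = self.nucleus_axes_nm
        pts = np.stack([nz * np.cos(uu),
                        ny * np.sin(uu) * np.cos(vv),
                        nx * np.sin(uu) * np.sin(vv)], axis=-1).reshape(-1, 3)
        pts = pts + np.asarray(self.nucleus_offset_nm)
        q = np.sum((pts / np.asarray(self.cell_axes_nm)) ** 2, axis=1)
        if np.any(q >= 1.0):
            raise ConfigError("nucleus ellipsoid is not strictly inside the cell ellipsoid")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})
        cfg.validate()
        return cfg


@dataclass
class CellPhantom:
    """Labeled voxel scene + attenuation map + ground-truth cluster catalog."""

    label_volume: np.ndarray                # int32, labels per module convention
    attenuation_volume: np.ndarray          # float32, um^-1
    voxel_pitch_nm: float
    truth: list[ClusterRecord]
    config: PhantomConfig

    @property
    def cell_mask(self) -> np.ndarray:
        return self.label_volume >= LABEL_CYTOPLASM

    @property
    def nucleus_mask(self) -> np.ndarray:
        return self.label_volume == LABEL_NUCLEUS

    @property
    def cluster_mask(self) -> np.ndarray:
        return self.label_volume >= LABEL_FIRST_CLUSTER


def sample_cluster_sizes(size_median_nm: float, size_log_sigma: float, n: int,
                         seed: int | np.random.Generator = 0,
                         min_size_nm: float | None = None) -> np.ndarray:
    """Draw n cluster sizes (nm) from a log-normal distribution.

    The distribution family is fixed to log-normal: positive support and a
    single mode, matching the observed unimodal per-cell size histograms.
    Optional lower truncation (by resampling) keeps every cluster above the
    requested minimum. Deterministic for a given seed.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    if size_median_nm <= 0 or size_log_sigma < 0:
        raise ConfigError("log-normal parameters must be positive (sigma >= 0)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = rng.lognormal(mean=math.log(size_median_nm), sigma=size_log_sigma, size=n)
    if min_size_nm is not None:
        for _ in range(1000):
            low = out < min_size_nm
            if not low.any():
                break
            out[low] = rng.lognormal(mean=math.log(size_median_nm),
                                     sigma=size_log_sigma, size=int(low.sum()))
        else:
            raise ConfigError("min_size_nm truncates essentially all probability mass")
    return out


def _ellipsoid_mask(shape, center_vox, semi_axes_vox, rotation: np.ndarray | None):
    """Voxel mask of a rotated ellipsoid, restricted to its bounding box.

    Returns (slices, local_mask); voxel centers at index + 0.5.
    """
    r = float(np.max(semi_axes_vox)) + 1.0
    lo = [max(0, int(np.floor(c - r))) for c in center_vox]
    hi = [min(s, int(np.ceil(c + r)) + 1) for c, s in zip(center_vox, shape)]
    if any(l >= h for l, h in zip(lo, hi)):
        return None, None
    grids = np.meshgrid(*[np.arange(l, h) + 0.5 for l, h in zip(lo, hi)], indexing="ij")
    rel = np.stack([g - c for g, c in zip(grids, center_vox)], axis=-1)
    if rotation is not None:
        rel = rel @ rotation               # body frame coordinates
    q = np.sum((rel / np.asarray(semi_axes_vox)) ** 2, axis=-1)
    return tuple(slice(l, h) for l, h in zip(lo, hi)), q <= 1.0


def build_phantom(config: PhantomConfig) -> CellPhantom:
    """Render a cell phantom satisfying all scene invariants.

    Clusters are placed by rejection sampling: a candidate is accepted only if
    its rendered voxels lie inside the cell, none fall in the nucleus, and its
    surface stays ``min_separation_nm`` away from every previously placed
    cluster. After ``max_attempts`` failures for one cluster a
    :class:`PlacementError` names the shortfall. The truth catalog records the
    rendered (voxelized) geometry measured with the same moment-ellipsoid
    convention the quantification stage uses.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    pitch = config.voxel_pitch_nm
    shape = tuple(int(s) for s in config.shape)

    center_nm = np.array([s * pitch / 2.0 for s in shape])
    coords = np.meshgrid(*[(np.arange(s) + 0.5) * pitch for s in shape], indexing="ij")
    cell_q = sum(((g - c) / a) ** 2 for g, c, a in
                 zip(coords, center_nm, config.cell_axes_nm))
    nuc_center = center_nm + np.asarray(config.nucleus_offset_nm)
    nuc_q = sum(((g - c) / a) ** 2 for g, c, a in
                zip(coords, nuc_center, config.nucleus_axes_nm))
    del coords
    cell_mask = cell_q <= 1.0
    nucleus_mask = nuc_q <= 1.0
    if not nucleus_mask.any():
        raise ConfigError("nucleus does not intersect the voxel grid")

    label = np.zeros(shape, dtype=np.int32)
    label[cell_mask] = LABEL_CYTOPLASM
    label[nucleus_mask] = LABEL_NUCLEUS

    ndist_map = signed_distance_map(nucleus_mask, pitch)

    sizes = (sample_cluster_sizes(config.size_median_nm, config.size_log_sigma,
                                  config.n_clusters, rng, config.min_size_nm)
             if config.n_clusters else np.empty(0))

    occupancy = np.zeros(shape, dtype=bool)
    truth: list[ClusterRecord] = []
    sep_vox = config.min_separation_nm / pitch

    for i, s_nm in enumerate(sizes):
        placed = False
        for _ in range(config.max_attempts):
            # mild random axis anisotropy, renormalized so the axis mean is s_nm
            f = rng.uniform(1.0 - config.anisotropy, 1.0 + config.anisotropy, size=3)
            semi_nm = (s_nm / 2.0) * f / f.mean()
            rot = Rotation.random(rng=rng).as_matrix()
            cand_nm = np.array([rng.uniform(c - a, c + a) for c, a in
                                zip(center_nm, config.cell_axes_nm)])
            cand_vox = cand_nm / pitch
            cidx = tuple(int(np.clip(np.floor(v), 0, s - 1)) for v, s in zip(cand_vox, shape))
            if not cell_mask[cidx] or nucleus_mask[cidx]:
                continue
            d = nucleus_distance(cand_nm, nucleus_mask, pitch, _distance_map=ndist_map)
            if config.placement == "perinuclear_shell":
                if not (config.shell_inner_nm <= d <= config.shell_outer_nm):
                    continue
            elif d <= 0:
                continue
            sl, m = _ellipsoid_mask(shape, cand_vox, semi_nm / pitch, rot)
            if sl is None or not m.any():
                # sub-voxel cluster: mark its containing voxel
                sl = tuple(slice(c, c + 1) for c in cidx)
                m = np.ones((1, 1, 1), dtype=bool)
            if not cell_mask[sl][m].all() or nucleus_mask[sl][m].any() or label[sl][m].max() >= LABEL_FIRST_CLUSTER:
                continue
            # separation check against existing clusters: inflate by the margin
            sl2, m2 = _ellipsoid_mask(shape, cand_vox, semi_nm / pitch + sep_vox, rot)
            if sl2 is not None and occupancy[sl2][m2].any():
                continue
            lbl_id = LABEL_FIRST_CLUSTER + i
            sub = label[sl]
            sub[m] = lbl_id
            label[sl] = sub
            occupancy[sl] |= m
            vox = np.argwhere(m) + np.array([s.start for s in sl])
            axes = fit_ellipsoid(vox, pitch)
            centroid = tuple((vox.mean(axis=0) + 0.5) * pitch)
            truth.append(ClusterRecord(
                id=lbl_id, centroid_nm=centroid, axes_nm=axes,
                size_nm=cluster_size(axes),
                nucleus_distance_nm=nucleus_distance(centroid, nucleus_mask, pitch,
                                                     _distance_map=ndist_map),
                inside_cell=True, dim="3D", n_px=int(vox.shape[0]),
            ))
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"placed {len(truth)} of {config.n_clusters} clusters; cluster {i} "
                f"(size {s_nm:.0f} nm) found no admissible position in "
                f"{config.max_attempts} attempts ({config.placement})")

    mu = np.full(shape, config.mu_background, dtype=np.float32)
    mu[label == LABEL_CYTOPLASM] = config.mu_cytoplasm
    mu[label == LABEL_NUCLEUS] = config.mu_nucleus
    mu[label >= LABEL_FIRST_CLUSTER] = config.mu_cluster
    return CellPhantom(label_volume=label, attenuation_volume=mu,
                       voxel_pitch_nm=pitch, truth=truth, config=config)
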