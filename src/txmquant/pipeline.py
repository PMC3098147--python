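"""End-to-end driver: simulate -> image -> reconstruct -> quantify -> report.

One :class:`RunConfig` (YAML-serializable) describes a whole in-silico
experiment. A single global seed governs every stochastic stage; two runs
with the same config and seed produce byte-identical catalogs. Two presets
bundle the study conditions the synthetic scenes emulate:

* ``emt-like`` — large clusters (size mode ~140 nm) spread uniformly through
  the cytoplasm;
* ``hela-like`` — small clusters (size mode ~30 nm) confined to a thin
  perinuclear shell 0.5-1.5 um outside the nuclear envelope.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path

import numpy as np

from . import io as tio
from .errors import ConfigError, StageError
from .optics import ProjectionSet, _rotated_line_integrals, add_photon_noise, project
from .phantom import CellPhantom, PhantomConfig, build_phantom
from .quant import (auto_threshold, filter_inside_cell, localize_clusters,
                    measure_clusters, segment_clusters)
from .recon import ReconVolume, reconstruct_fbp, sinogramify
from .records import ClusterRecord
from .stats import compare_distributions, default_bin_edges, make_distribution, uptake_report

__all__ = ["OpticsConfig", "ReconConfig", "QuantConfig", "StatsConfig",
           "RunConfig", "PipelineResult", "run_pipeline", "quantify_external",
           "preset", "PRESETS"]

logger = logging.getLogger(__name__)


@dataclass
class OpticsConfig:
    angle_start_deg: float = 0.0
    angle_stop_deg: float = 140.0       # instrument's mechanical limit
    angle_step_deg: float = 1.0
    photon_count: float | None = None   # None = noiseless
    psf_fwhm_nm: float | None = None

    def angles(self) -> np.ndarray:
        if self.angle_step_deg <= 0:
            raise ConfigError("angle step must be positive")
        return np.arange(self.angle_start_deg, self.angle_stop_deg, self.angle_step_deg)


@dataclass
class ReconConfig:
    apodization: str = "auto"    # "auto" -> hann iff noisy; or "hann" / "none"

    def resolve(self, noisy: bool) -> str | None:
        if self.apodization == "auto":
            return "hann" if noisy else None
        if self.apodization in ("none", "", None):
            return None
        return self.apodization


@dataclass
class QuantConfig:
    threshold_override: float | None = None
    min_size_px: int = 2
    inside_fraction: float = 0.9
    # Auto-threshold sanity check: gold clusters stand far above the tissue
    # grey values, so the two Otsu classes must be separated by many times
    # the background-class spread. An Otsu split of an unimodal (cluster-free)
    # distribution reaches a separation of only ~2-4. Below this ratio no
    # cluster class is present and zero clusters are reported. Manual
    # threshold overrides bypass the guard.
    min_class_separation: float = 6.0


@dataclass
class StatsConfig:
    bin_width_nm: float = 20.0
    bin_max_nm: float = 800.0

    def edges(self) -> np.ndarray:
        return default_bin_edges(self.bin_width_nm, self.bin_max_nm)


@dataclass
class RunConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    recon: ReconConfig = field(default_factory=ReconConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    cell_id: str = "cell_01"
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        return cls(
            phantom=PhantomConfig.from_dict(d.get("phantom", {})) if d.get("phantom") else PhantomConfig(),
            optics=OpticsConfig(**d.get("optics", {})),
            recon=ReconConfig(**d.get("recon", {})),
            quant=QuantConfig(**d.get("quant", {})),
            stats=StatsConfig(**d.get("stats", {})),
            cell_id=d.get("cell_id", "cell_01"),
            seed=int(d.get("seed", 0)),
        )

    def spawn_seeds(self) -> dict[str, int]:
        """Derive one child seed per stochastic stage from the global seed."""
        ss = np.random.SeedSequence(self.seed)
        phantom_s, noise_s = ss.spawn(2)
        return {"phantom": int(phantom_s.generate_state(1)[0] % (2**31)),
                "noise": int(noise_s.generate_state(1)[0] % (2**31))}


def preset(name: str, **overrides) -> RunConfig:
    """Named study-condition presets (``emt-like`` / ``hela-like``)."""
    if name not in PRESETS:
        raise ConfigError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    cfg = PRESETS[name]()
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


def _mode_to_median(mode_nm: float, log_sigma: float) -> float:
    # log-normal mode = exp(mu - sigma^2); the presets are specified by their
    # distribution peak, the statistic the experiments report
    return mode_nm * float(np.exp(log_sigma**2))


def _emt_like() -> RunConfig:
    sigma = 0.35
    return RunConfig(
        phantom=PhantomConfig(
            shape=(192, 192, 192), voxel_pitch_nm=15.0,
            cell_axes_nm=(1350.0, 1350.0, 1250.0),
            nucleus_axes_nm=(450.0, 450.0, 420.0),
            n_clusters=120, size_median_nm=_mode_to_median(140.0, sigma),
            size_log_sigma=sigma, min_size_nm=60.0,
            placement="uniform_cytoplasm",
        ),
        cell_id="emt_like",
    )


def _hela_like() -> RunConfig:
    sigma = 0.35
    return RunConfig(
        phantom=PhantomConfig(
            shape=(224, 224, 224), voxel_pitch_nm=15.0,
            cell_axes_nm=(1580.0, 1580.0, 1500.0),
            nucleus_axes_nm=(350.0, 350.0, 330.0),
            n_clusters=80, size_median_nm=_mode_to_median(30.0, sigma),
            size_log_sigma=sigma, min_size_nm=30.0,
            placement="perinuclear_shell",
            shell_inner_nm=500.0, shell_outer_nm=1500.0,
        ),
        cell_id="hela_like",
    )


PRESETS = {"emt-like": _emt_like, "hela-like": _hela_like}


@dataclass
class PipelineResult:
    out_dir: Path
    phantom: CellPhantom
    projections: ProjectionSet
    recon: ReconVolume
    records_3d: list[ClusterRecord]
    records_2d: list[ClusterRecord]
    qc: dict
    report_path: Path
    records_path: Path


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:         # noqa: BLE001 - re-raised with stage name
                raise StageError(name, str(exc)) from exc
        return wrapped
    return deco


def project_mask(mask: np.ndarray, angle_deg: float) -> np.ndarray:
    """2D silhouette of a 3D mask at a projection angle (same geometry as
    the transmission projector)."""
    line = _rotated_line_integrals(np.asarray(mask, dtype=np.float64), angle_deg)
    return line > 0.5


def quantify_volume(volume: np.ndarray, pixel_pitch_nm: float,
                    cell_mask: np.ndarray | None = None,
                    nucleus_mask: np.ndarray | None = None,
                    polarity: str = "bright",
                    qcfg: QuantConfig | None = None,
                    cell_id: str = "") -> tuple[list[ClusterRecord], dict]:
    """Segment + measure + (optionally) containment-filter and localize.

    Works on a 2D projection image (``polarity='dark'``) or a 3D attenuation
    volume (``polarity='bright'``). Returns the records and a QC dict with the
    threshold used, connectivity, and rejection counts.
    """
    qcfg = qcfg or QuantConfig()
    thr = qcfg.threshold_override
    degenerate = False
    if thr is None:
        # threshold on the within-cell grey values when a mask is available:
        # the cluster/tissue contrast is what the threshold must separate,
        # not the cell/background silhouette
        arr = np.asarray(volume, dtype=float)
        if cell_mask is not None and np.asarray(cell_mask).any():
            vals = arr[np.asarray(cell_mask, dtype=bool)]
        else:
            vals = arr.ravel()
        thr = auto_threshold(vals)
        fg = vals < thr if polarity == "dark" else vals > thr
        separation = float("inf")
        if fg.any() and (~fg).any():
            sd_bg = float(vals[~fg].std())
            separation = (abs(float(vals[fg].mean()) - float(vals[~fg].mean()))
                          / max(sd_bg, 1e-30))
        degenerate = separation < qcfg.min_class_separation
    if degenerate:
        warnings.warn("auto threshold class separation is too small: no "
                      "cluster grey-value class present; reporting zero clusters")
        qc = {"threshold": float(thr), "threshold_source": "otsu",
              "threshold_degenerate": True, "class_separation": separation,
              "polarity": polarity, "connectivity": 8 if np.ndim(volume) == 2 else 26,
              "n_components": 0, "n_discarded_sub_resolution": 0}
        return [], qc
    seg = segment_clusters(volume, thr, polarity, min_size_px=qcfg.min_size_px)
    qc = {"threshold": float(thr),
          "threshold_source": "override" if qcfg.threshold_override is not None else "otsu",
          "polarity": polarity, "connectivity": seg.connectivity,
          "n_components": seg.n_clusters,
          "n_discarded_sub_resolution": seg.n_discarded_small}
    if cell_mask is not None:
        records, n_rej = filter_inside_cell(seg, cell_mask, pixel_pitch_nm,
                                            min_fraction=qcfg.inside_fraction,
                                            cell_id=cell_id)
        qc["n_rejected_outside_cell"] = n_rej
    else:
        records = measure_clusters(seg, pixel_pitch_nm, cell_id=cell_id)
        qc["inside_cell_filter"] = "skipped: no cell mask supplied"
        warnings.warn("no cell mask supplied: inside-cell filter skipped")
    if nucleus_mask is not None and np.asarray(nucleus_mask).any():
        records, loc = localize_clusters(records, nucleus_mask, pixel_pitch_nm)
        qc["nucleus_localization"] = loc
    return records, qc


def run_pipeline(config: RunConfig, out_dir) -> PipelineResult:
    """Run all stages and write every artifact under ``out_dir``.

    Artifacts: phantom stacks + truth CSV, projection stack + sidecar,
    reconstructed volume + sidecar, measured-cluster CSV (2D and 3D records),
    per-cell report CSV, QC YAML, and a manifest recording every parameter.
    A stage failure aborts with the stage name; earlier artifacts remain.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.spawn_seeds()
    qc: dict = {"stages": {}}

    @_stage("phantom")
    def s_phantom() -> CellPhantom:
        ph = build_phantom(replace(config.phantom, seed=seeds["phantom"]))
        tio.write_phantom(ph, out)
        logger.info("phantom: %d clusters rendered", len(ph.truth))
        return ph

    @_stage("optics")
    def s_optics(ph: CellPhantom) -> ProjectionSet:
        angles = config.optics.angles()
        pset = project(ph.attenuation_volume, angles, ph.voxel_pitch_nm,
                       psf_fwhm_nm=config.optics.psf_fwhm_nm)
        if config.optics.photon_count:
            pset = add_photon_noise(pset, config.optics.photon_count, seeds["noise"])
        tio.write_projections(pset, out)
        logger.info("optics: %d frames, %.0f-%.0f deg", pset.n_angles,
                    angles[0], angles[-1])
        return pset

    @_stage("recon")
    def s_recon(pset: ProjectionSet) -> ReconVolume:
        sino = sinogramify(pset)
        apod = config.recon.resolve(noisy=pset.photon_count is not None)
        rv = reconstruct_fbp(sino, pset.angles_deg, pset.pixel_pitch_nm,
                             apodization=apod)
        tio.write_recon(rv, out)
        logger.info("recon: %s, coverage %s", rv.method, rv.angular_coverage)
        return rv

    phantom = s_phantom()
    projections = s_optics(phantom)
    recon = s_recon(projections)

    @_stage("quant")
    def s_quant():
        rec3, qc3 = quantify_volume(
            recon.volume, recon.voxel_pitch_nm,
            cell_mask=phantom.cell_mask, nucleus_mask=phantom.nucleus_mask,
            polarity="bright", qcfg=config.quant, cell_id=config.cell_id)
        frame0 = projections.images[0]
        a0 = float(projections.angles_deg[0])
        cell2d = project_mask(phantom.cell_mask, a0)
        nuc2d = project_mask(phantom.nucleus_mask, a0)
        rec2, qc2 = quantify_volume(
            frame0, projections.pixel_pitch_nm,
            cell_mask=cell2d, nucleus_mask=nuc2d,
            polarity="dark", qcfg=config.quant, cell_id=config.cell_id)
        return rec3, rec2, {"quant_3d": qc3, "quant_2d": {**qc2, "angle_deg": a0}}

    records_3d, records_2d, qstage = s_quant()
    qc["stages"].update(qstage)

    @_stage("stats")
    def s_stats():
        edges = config.stats.edges()
        report = uptake_report(records_3d, edges)
        report_path = out / "uptake_report.csv"
        report.to_csv(report_path, index=False)
        records_path = out / "clusters.csv"
        tio.write_records_csv(records_path, records_3d + records_2d)
        dist3 = make_distribution([r.size_nm for r in records_3d], edges,
                                  cell_id=config.cell_id, dim="3D")
        dist2 = make_distribution([r.size_nm for r in records_2d], edges,
                                  cell_id=config.cell_id, dim="2D")
        comp = {}
        if dist2.n_clusters >= 5 and dist3.n_clusters >= 5:
            stat, p, method = compare_distributions(
                [r.size_nm for r in records_2d], [r.size_nm for r in records_3d])
            comp = {"ks_statistic": stat, "p_value": p, "method": method}
        return report_path, records_path, {
            "n_clusters_3d": dist3.n_clusters, "n_clusters_2d": dist2.n_clusters,
            "mode_3d_nm": dist3.mode_nm, "mode_2d_nm": dist2.mode_nm,
            "ks_2d_vs_3d": comp,
        }

    report_path, records_path, sstage = s_stats()
    qc["stages"]["stats"] = sstage

    manifest = {
        "created_utc": datetime.now(timezone.utc).isoformat(),
        "config": config.to_dict(),
        "seeds": seeds,
        "qc": qc,
    }
    tio.write_yaml(out / "qc.yaml", qc)
    tio.write_yaml(out / "manifest.yaml", manifest)
    return PipelineResult(out_dir=out, phantom=phantom, projections=projections,
                          recon=recon, records_3d=records_3d, records_2d=records_2d,
                          qc=qc, report_path=report_path, records_path=records_path)


def quantify_external(image_path, cell_mask_path=None, nucleus_mask_path=None,
                      pixel_pitch_nm: float = 15.0, dim: str | None = None,
                      polarity: str | None = None, qcfg: QuantConfig | None = None,
                      out_dir=None, cell_id: str = "external"):
    """Quantify a user-supplied grayscale TIFF (single image or stack).

    Dimensionality is inferred from the stack depth (multi-page -> 3D) and can
    be overridden: ``dim='2D'`` on a stack quantifies each page independently
    and returns one (records, qc) pair per page. Default polarity is ``dark``
    for 2D transmission images and ``bright`` for 3D volumes.
    """
    img = tio.read_stack(image_path)
    if img.ndim not in (2, 3):
        raise ConfigError(f"{image_path}: expected 2D image or 3D stack, got ndim={img.ndim}")
    img = img.astype(np.float64)
    cell_mask = tio.read_stack(cell_mask_path).astype(bool) if cell_mask_path else None
    nucleus_mask = tio.read_stack(nucleus_mask_path).astype(bool) if nucleus_mask_path else None
    inferred = "3D" if img.ndim == 3 else "2D"
    dim = dim or inferred
    if dim not in ("2D", "3D"):
        raise ConfigError("dim must be '2D' or '3D'")

    def _one(arr, cmask, nmask, tag):
        pol = polarity or ("dark" if arr.ndim == 2 else "bright")
        recs, qc = quantify_volume(arr, pixel_pitch_nm, cell_mask=cmask,
                                   nucleus_mask=nmask, polarity=pol, qcfg=qcfg,
                                   cell_id=tag)
        if out_dir is not None:
            outp = Path(out_dir)
            outp.mkdir(parents=True, exist_ok=True)
            tio.write_records_csv(outp / f"clusters_{tag}.csv", recs)
            tio.write_yaml(outp / f"qc_{tag}.yaml", qc)
        return recs, qc

    if img.ndim == 3 and dim == "2D":
        results = []
        for i, page in enumerate(img):
            cm = cell_mask[i] if cell_mask is not None and cell_mask.ndim == 3 else cell_mask
            nm = nucleus_mask[i] if nucleus_mask is not None and nucleus_mask.ndim == 3 else nucleus_mask
            results.append(_one(page, cm, nm, f"{cell_id}_page{i:03d}"))
        return results
    return _one(img, cell_mask, nucleus_mask, cell_id)
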