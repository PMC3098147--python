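"""File I/O: multi-page TIFF stacks, YAML sidecars, CSV catalogs.

All physical lengths in files are nm. Volumes and projection stacks are
multi-page TIFFs (one page per z-slice / per angle), attenuation as 32-bit
float and label stacks as 16-bit unsigned; metadata travels in YAML sidecars
so every stage's artifacts can be re-read independently.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigError
from .optics import ProjectionSet
from .phantom import CellPhantom, PhantomConfig
from .recon import ReconVolume
from .records import ClusterRecord, frame_to_records, records_to_frame

__all__ = [
    "write_stack", "read_stack", "write_yaml", "read_yaml",
    "write_phantom", "read_phantom_volumes", "write_truth_csv", "read_truth_csv",
    "write_projections", "read_projections", "write_recon", "read_recon",
    "write_records_csv", "read_records_csv",
]

TRUTH_COLUMNS = ["id", "cz", "cy", "cx", "ax1", "ax2", "ax3", "size", "nucleus_distance"]


def write_stack(path, array: np.ndarray, dtype=np.float32) -> Path:
    path = Path(path)
    tifffile.imwrite(path, np.asarray(array, dtype=dtype), photometric="minisblack")
    return path


def read_stack(path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.dtype == np.uint8:
        raise ConfigError(f"{path}: RGB(A) images are not supported; supply grayscale TIFF")
    return arr


def write_yaml(path, data: dict) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
    return path


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_phantom(phantom: CellPhantom, out_dir) -> dict[str, Path]:
    """Write attenuation + label stacks, truth CSV, and config YAML."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "attenuation": write_stack(out / "phantom_attenuation.tif",
                                   phantom.attenuation_volume, np.float32),
        "labels": write_stack(out / "phantom_labels.tif",
                              phantom.label_volume, np.uint16),
        "truth": write_truth_csv(out / "phantom_truth.csv", phantom.truth),
        "config": write_yaml(out / "phantom_config.yaml", phantom.config.to_dict()),
    }
    return paths


def read_phantom_volumes(out_dir) -> CellPhantom:
    out = Path(out_dir)
    cfg = PhantomConfig.from_dict(read_yaml(out / "phantom_config.yaml"))
    return CellPhantom(
        label_volume=read_stack(out / "phantom_labels.tif").astype(np.int32),
        attenuation_volume=read_stack(out / "phantom_attenuation.tif").astype(np.float32),
        voxel_pitch_nm=cfg.voxel_pitch_nm,
        truth=read_truth_csv(out / "phantom_truth.csv"),
        config=cfg,
    )


def write_truth_csv(path, truth: list[ClusterRecord]) -> Path:
    rows = []
    for r in truth:
        rows.append({"id": r.id, "cz": r.centroid_nm[0], "cy": r.centroid_nm[1],
                     "cx": r.centroid_nm[2], "ax1": r.axes_nm[0], "ax2": r.axes_nm[1],
                     "ax3": r.axes_nm[2], "size": r.size_nm,
                     "nucleus_distance": r.nucleus_distance_nm})
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, index=False)
    return Path(path)


def read_truth_csv(path) -> list[ClusterRecord]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        axes = (float(row["ax1"]), float(row["ax2"]), float(row["ax3"]))
        out.append(ClusterRecord(
            id=int(row["id"]),
            centroid_nm=(float(row["cz"]), float(row["cy"]), float(row["cx"])),
            axes_nm=axes, size_nm=float(row["size"]),
            nucleus_distance_nm=float(row["nucleus_distance"]),
            inside_cell=True, dim="3D",
        ))
    return out


def write_projections(pset: ProjectionSet, out_dir, stem: str = "projections") -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tif = write_stack(out / f"{stem}.tif", pset.images, np.float32)
    meta = write_yaml(out / f"{stem}.yaml", {
        "angles_deg": [float(a) for a in pset.angles_deg],
        "pixel_pitch_nm": float(pset.pixel_pitch_nm),
        "photon_count": None if pset.photon_count is None else float(pset.photon_count),
        "geometry": pset.geometry,
    })
    return {"images": tif, "meta": meta}


def read_projections(out_dir, stem: str = "projections") -> ProjectionSet:
    out = Path(out_dir)
    meta = read_yaml(out / f"{stem}.yaml")
    return ProjectionSet(
        images=read_stack(out / f"{stem}.tif").astype(np.float64),
        angles_deg=np.asarray(meta["angles_deg"], dtype=float),
        pixel_pitch_nm=float(meta["pixel_pitch_nm"]),
        photon_count=meta.get("photon_count"),
        geometry=meta.get("geometry", "parallel"),
    )


def write_recon(recon: ReconVolume, out_dir, stem: str = "recon") -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tif = write_stack(out / f"{stem}.tif", recon.volume, np.float32)
    meta = write_yaml(out / f"{stem}.yaml", {
        "voxel_pitch_nm": float(recon.voxel_pitch_nm),
        "angular_coverage": recon.angular_coverage,
        "method": recon.method,
    })
    return {"volume": tif, "meta": meta}


def read_recon(out_dir, stem: str = "recon") -> ReconVolume:
    out = Path(out_dir)
    meta = read_yaml(out / f"{stem}.yaml")
    return ReconVolume(
        volume=read_stack(out / f"{stem}.tif").astype(np.float32),
        voxel_pitch_nm=float(meta["voxel_pitch_nm"]),
        angular_coverage=meta.get("angular_coverage", {}),
        method=meta.get("method", "fbp_ramp"),
    )


def write_records_csv(path, records: list[ClusterRecord]) -> Path:
    records_to_frame(records).to_csv(path, index=False)
    return Path(path)


def read_records_csv(path) -> list[ClusterRecord]:
    return frame_to_records(pd.read_csv(path))
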