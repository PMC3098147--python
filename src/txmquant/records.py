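"""Per-cluster records and their tabular (CSV) representation.

A :class:`ClusterRecord` describes one nanoparticle cluster, either from the
phantom ground truth or measured by the quantification stage. All lengths are
in nm; ``axes`` are full axis lengths (descending) of the moment-equivalent
ellipse (2D) or ellipsoid (3D), and ``size`` is their arithmetic mean — the
axis-averaged cluster size used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ClusterRecord", "records_to_frame", "frame_to_records"]

#: column order of the measured-cluster CSV
CSV_COLUMNS = [
    "id", "dim", "cz", "cy", "cx", "ax1", "ax2", "ax3",
    "size_nm", "nucleus_distance_nm", "inside_cell", "area_or_volume_px",
]


@dataclass(frozen=True)
class ClusterRecord:
    id: int
    centroid_nm: tuple[float, ...]          # (z, y, x) for 3D, (y, x) for 2D
    axes_nm: tuple[float, ...]              # 2 or 3 full axis lengths, descending
    size_nm: float                          # arithmetic mean of axes_nm
    nucleus_distance_nm: float = float("nan")
    inside_cell: bool | None = None
    dim: str = "3D"                         # "2D" | "3D"
    n_px: int = 0                           # pixel/voxel count of the component
    cell_id: str = ""
    flags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        axes = tuple(float(a) for a in self.axes_nm)
        if len(axes) not in (2, 3):
            raise ValueError("axes_nm must have 2 or 3 entries")
        if any(a <= 0 for a in axes):
            raise ValueError("axes must be positive")
        if list(axes) != sorted(axes, reverse=True):
            raise ValueError("axes must be sorted descending")
        object.__setattr__(self, "axes_nm", axes)
        object.__setattr__(self, "centroid_nm", tuple(float(c) for c in self.centroid_nm))

    def with_distance(self, d_nm: float, *extra_flags: str) -> "ClusterRecord":
        flags = self.flags + tuple(extra_flags)
        return replace(self, nucleus_distance_nm=float(d_nm), flags=flags)


def records_to_frame(records: Sequence[ClusterRecord]) -> pd.DataFrame:
    """Tabulate records in the package's CSV column order."""
    rows = []
    for r in records:
        cent = (float("nan"),) * (3 - len(r.centroid_nm)) + r.centroid_nm
        axes = r.axes_nm + (float("nan"),) * (3 - len(r.axes_nm))
        rows.append({
            "id": r.id, "dim": r.dim,
            "cz": cent[0], "cy": cent[1], "cx": cent[2],
            "ax1": axes[0], "ax2": axes[1], "ax3": axes[2],
            "size_nm": r.size_nm,
            "nucleus_distance_nm": r.nucleus_distance_nm,
            "inside_cell": r.inside_cell,
            "area_or_volume_px": r.n_px,
            "cell_id": r.cell_id,
            "flags": ";".join(r.flags),
        })
    return pd.DataFrame(rows, columns=CSV_COLUMNS + ["cell_id", "flags"])


def frame_to_records(df: pd.DataFrame) -> list[ClusterRecord]:
    """Inverse of :func:`records_to_frame` (round-trips the CSV)."""
    out = []
    for _, row in df.iterrows():
        dim = str(row["dim"])
        if dim == "2D":
            centroid = (row["cy"], row["cx"])
            axes = (row["ax1"], row["ax2"])
        else:
            centroid = (row["cz"], row["cy"], row["cx"])
            axes = (row["ax1"], row["ax2"], row["ax3"])
        inside = row.get("inside_cell")
        if pd.isna(inside):
            inside = None
        elif isinstance(inside, str):
            inside = inside.strip().lower() == "true"
        else:
            inside = bool(inside)
        flags = row.get("flags", "")
        flags = tuple(f for f in str(flags).split(";") if f) if not pd.isna(flags) else ()
        out.append(ClusterRecord(
            id=int(row["id"]), centroid_nm=tuple(float(c) for c in centroid),
            axes_nm=tuple(float(a) for a in axes), size_nm=float(row["size_nm"]),
            nucleus_distance_nm=float(row["nucleus_distance_nm"]),
            inside_cell=inside, dim=dim, n_px=int(row["area_or_volume_px"]),
            cell_id="" if pd.isna(row.get("cell_id", "")) else str(row.get("cell_id", "")),
            flags=flags,
        ))
    return out


def sizes(records: Sequence[ClusterRecord]) -> np.ndarray:
    return np.array([r.size_nm for r in records], dtype=float)
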