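"""CSV / TIFF / JSON readers and writers for the toolkit's conventions.

Conventions:

* trajectories: CSV with columns ``time_min, l_anterior_um, l_posterior_um,
  l_free_um``;
* position series: CSV with columns ``subject_id, neighborhood, time_min,
  position_um``;
* adjacency matrices: CSV with neuron names as first row and column;
* label stacks: multi-page TIFF of integer labels plus a JSON sidecar
  ``{pixel_size_nm, z_spacing_nm, label_names}``;
* neurite traces: CSV with columns ``subject_id, neurite_label,
  point_index, x_um, y_um[, z_um]``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import tifffile

from .connectome import AdjacencyMatrix
from .contacts import ContactPatch, LabelStack, PairContactSummary
from .kinematics import PositionSeries
from .model import NeuriteState, Trajectory, ZipperParams
from .morphometrics import NeuriteTrace

__all__ = [
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_position_series_csv",
    "read_position_series_csv",
    "write_adjacency_csv",
    "read_adjacency_csv",
    "write_label_stack",
    "read_label_stack",
    "write_patches_csv",
    "write_pair_summaries_csv",
    "read_traces_csv",
    "write_traces_csv",
]


def write_trajectory_csv(traj: Trajectory, path) -> Path:
    frame = pd.DataFrame(
        {
            "time_min": traj.times,
            "l_anterior_um": traj.l_anterior,
            "l_posterior_um": traj.l_posterior,
            "l_free_um": traj.l_free,
        }
    )
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_trajectory_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"time_min", "l_anterior_um", "l_posterior_um"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    if "l_free_um" not in frame.columns:
        frame["l_free_um"] = 0.0
    return frame


def trajectory_frame_to_series(frame: pd.DataFrame, subject_id: str = "") -> tuple[PositionSeries, PositionSeries]:
    """Split a trajectory table into (anterior, posterior) position series."""
    t = frame["time_min"].to_numpy(dtype=float)
    return (
        PositionSeries(t, frame["l_anterior_um"].to_numpy(dtype=float), "anterior", subject_id),
        PositionSeries(t, frame["l_posterior_um"].to_numpy(dtype=float), "posterior", subject_id),
    )


def write_position_series_csv(series: Iterable[PositionSeries], path) -> Path:
    rows = []
    for s in series:
        for t, p in zip(s.times, s.positions):
            rows.append(
                {
                    "subject_id": s.subject_id,
                    "neighborhood": s.neighborhood,
                    "time_min": t,
                    "position_um": p,
                }
            )
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_position_series_csv(path) -> "list[PositionSeries]":
    frame = pd.read_csv(path)
    required = {"subject_id", "neighborhood", "time_min", "position_um"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"position series CSV missing columns: {sorted(missing)}")
    out = []
    for (subject, hood), grp in frame.groupby(["subject_id", "neighborhood"], sort=True):
        grp = grp.sort_values("time_min")
        out.append(
            PositionSeries(
                grp["time_min"].to_numpy(dtype=float),
                grp["position_um"].to_numpy(dtype=float),
                str(hood),
                str(subject),
            )
        )
    return out


def write_adjacency_csv(adj: AdjacencyMatrix, path) -> Path:
    path = Path(path)
    adj.to_frame().to_csv(path)
    return path


def read_adjacency_csv(path, dataset_id: str = "", directed: bool = False) -> AdjacencyMatrix:
    frame = pd.read_csv(path, index_col=0)
    frame.index = frame.index.astype(str)
    frame.columns = frame.columns.astype(str)
    if not dataset_id:
        dataset_id = Path(path).stem
    return AdjacencyMatrix.from_frame(frame, dataset_id=dataset_id, directed=directed)


def write_label_stack(stack: LabelStack, tiff_path, meta_path) -> tuple[Path, Path]:
    tiff_path, meta_path = Path(tiff_path), Path(meta_path)
    tifffile.imwrite(tiff_path, stack.slices, photometric="minisblack")
    meta = {
        "pixel_size_nm": stack.pixel_size_nm,
        "z_spacing_nm": stack.z_spacing_nm,
        "label_names": {str(k): v for k, v in stack.label_names.items()},
    }
    meta_path.write_text(json.dumps(meta, indent=2))
    return tiff_path, meta_path


def read_label_stack(tiff_path, meta_path) -> LabelStack:
    arr = tifffile.imread(tiff_path)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    meta = json.loads(Path(meta_path).read_text())
    return LabelStack(
        np.asarray(arr),
        pixel_size_nm=float(meta["pixel_size_nm"]),
        z_spacing_nm=float(meta["z_spacing_nm"]),
        label_names={int(k): v for k, v in meta.get("label_names", {}).items()},
    )


def write_patches_csv(patches: Iterable[ContactPatch], path, pixel_size_nm: float) -> Path:
    rows = [
        {
            "slice": p.slice_index,
            "cell_a": p.pair[0],
            "cell_b": p.pair[1],
            "pixels": p.pixel_count,
            "area_nm2": p.pixel_count * pixel_size_nm**2,
            "source_direction": p.source_direction,
        }
        for p in patches
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_pair_summaries_csv(summaries: Iterable[PairContactSummary], path) -> Path:
    rows = [
        {
            "cell_a": s.pair[0],
            "cell_b": s.pair[1],
            "patch_count": s.patch_count,
            "total_pixels": s.total_pixels,
            "in_plane_area_nm2": s.in_plane_area_nm2,
            "slab_area_nm2": s.slab_area_nm2,
        }
        for s in summaries
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_traces_csv(traces: Iterable[NeuriteTrace], path) -> Path:
    rows = []
    for tr in traces:
        for i, pt in enumerate(tr.points):
            row = {
                "subject_id": tr.subject_id,
                "neurite_label": tr.neurite_label,
                "point_index": i,
                "x_um": pt[0],
                "y_um": pt[1],
            }
            if pt.size == 3:
                row["z_um"] = pt[2]
            rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def read_traces_csv(path) -> "list[NeuriteTrace]":
    frame = pd.read_csv(path)
    required = {"subject_id", "neurite_label", "point_index", "x_um", "y_um"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    cols = ["x_um", "y_um"] + (["z_um"] if "z_um" in frame.columns else [])
    out = []
    for (subject, label), grp in frame.groupby(["subject_id", "neurite_label"], sort=True):
        grp = grp.sort_values("point_index")
        out.append(NeuriteTrace(grp[cols].to_numpy(dtype=float), str(subject), str(label)))
    return out
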