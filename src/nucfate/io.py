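"""File I/O: TIFF stacks, trajectory/label CSVs and run manifests."""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError
from .metrics import NucleusTrajectory
from .simulate import TimeLapseStack

__all__ = [
    "write_timelapse",
    "read_timelapse",
    "write_trajectories",
    "read_trajectories",
    "trajectories_from_table",
    "write_manifest",
    "sha256_file",
]

TRAJECTORY_COLUMNS = [
    "cell_id",
    "frame",
    "time_min",
    "area",
    "edge_count",
    "ccp",
    "nucview_mean",
    "h2b_mean",
    "valid",
]


def write_timelapse(stack: TimeLapseStack, directory, basename: str) -> dict[str, Path]:
    """Write one stack as two single-channel multi-page TIFFs plus truth CSV.

    The channels go to ``<basename>_h2b.tif`` and ``<basename>_nucview.tif``
    (float32, frames as pages); the ground-truth table, when present, to
    ``<basename>_truth.csv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "h2b": directory / f"{basename}_h2b.tif",
        "nucview": directory / f"{basename}_nucview.tif",
    }
    tifffile.imwrite(paths["h2b"], stack.h2b.astype(np.float32), photometric="minisblack")
    tifffile.imwrite(paths["nucview"], stack.nucview.astype(np.float32), photometric="minisblack")
    if stack.truth is not None:
        paths["truth"] = directory / f"{basename}_truth.csv"
        stack.truth.to_csv(paths["truth"], index=False)
    return paths


def read_timelapse(
    h2b_path,
    nucview_path,
    pixel_size_nm: float = 111.0,
    frame_interval_min: float = 10.0,
) -> TimeLapseStack:
    """Read a two-file time-lapse written by :func:`write_timelapse`."""
    try:
        h2b = tifffile.imread(h2b_path).astype(float)
        nucview = tifffile.imread(nucview_path).astype(float)
    except (FileNotFoundError, ValueError, tifffile.TiffFileError) as err:
        raise FormatError(f"cannot read TIFF: {err}") from err
    return TimeLapseStack(
        h2b=h2b,
        nucview=nucview,
        pixel_size_nm=pixel_size_nm,
        frame_interval_min=frame_interval_min,
        truth=None,
    )


def write_trajectories(trajs: dict | list, path) -> pd.DataFrame:
    """Write trajectories as one CSV row per cell x frame; returns the table."""
    if isinstance(trajs, list):
        trajs = dict(enumerate(trajs))
    frames = [t.to_frame(cell_id) for cell_id, t in trajs.items()]
    table = pd.concat(frames, ignore_index=True)[TRAJECTORY_COLUMNS]
    table.to_csv(path, index=False)
    return table


def read_trajectories(path) -> pd.DataFrame:
    """Read a trajectory CSV, checking the documented column contract."""
    df = pd.read_csv(path)
    missing = [c for c in TRAJECTORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trajectory CSV missing columns {missing}")
    return df


def trajectories_from_table(
    table: pd.DataFrame, n_baseline: int = 3
) -> dict[object, NucleusTrajectory]:
    """Rebuild per-cell :class:`NucleusTrajectory` objects from a CSV table."""
    out = {}
    for cell_id, grp in table.groupby("cell_id", sort=True):
        grp = grp.sort_values("frame")
        out[cell_id] = NucleusTrajectory(
            time_min=grp["time_min"].to_numpy(dtype=float),
            area=grp["area"].to_numpy(dtype=float),
            edge_count=grp["edge_count"].to_numpy(dtype=float),
            ccp=grp["ccp"].to_numpy(dtype=float),
            nucview_mean=grp["nucview_mean"].to_numpy(dtype=float),
            h2b_mean=grp["h2b_mean"].to_numpy(dtype=float),
            valid=grp["valid"].to_numpy(dtype=bool),
            n_baseline=n_baseline,
        )
    return out


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, manifest: dict) -> None:
    """Write the run manifest (config snapshot, counts, warnings) as YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
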