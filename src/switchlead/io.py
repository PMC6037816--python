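"""Readers/writers for trajectory tables and observable derivation.

One canonical wide-CSV dialect is supported: one row per time step, a ``t``
column, then per-individual column groups named ``id{i}_{field}`` with
0-based ids.  Simulator output uses fields ``x, y, theta, obs``; kinematics
tables (e.g. converted field recordings) use ``x, y, z, vx, vy, vz, ax, ay,
az``.  A sidecar YAML file (``<prefix>.config.yaml``) records simulation
parameters and the leadership schedule.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulators import wrap_angle
from .types import TimeSeriesSet

__all__ = [
    "KinematicsTable",
    "write_trajectories",
    "read_trajectories",
    "derive_observable",
]

logger = logging.getLogger(__name__)

_KIN_FIELDS = ("x", "y", "z", "vx", "vy", "vz", "ax", "ay", "az")


@dataclass
class KinematicsTable:
    """Per-frame 3D kinematics (position, velocity, acceleration) per individual."""

    frame: pd.DataFrame  # columns id{i}_{x..az}
    frame_rate: float  # Hz

    @property
    def n_individuals(self) -> int:
        return len({c.split("_")[0] for c in self.frame.columns})

    def array(self, field: str) -> np.ndarray:
        """(N, T) array of one kinematic field across individuals."""
        n = self.n_individuals
        return np.stack([self.frame[f"id{i}_{field}"].to_numpy() for i in range(n)])


def write_trajectories(
    series: TimeSeriesSet,
    prefix: str | Path,
    config: dict | None = None,
) -> Path:
    """Write a series set (and optional sidecar config) as wide CSV.

    Produces ``<prefix>.csv`` with columns ``t, id0_x, id0_y, id0_theta,
    id0_obs, id1_x, ...`` (position/heading columns only when available) and,
    when ``config`` is given, ``<prefix>.config.yaml``.
    """
    prefix = Path(prefix)
    cols: dict[str, np.ndarray] = {"t": np.arange(series.n_samples) * series.dt}
    for i in range(series.n_individuals):
        if series.positions is not None:
            cols[f"id{i}_x"] = series.positions[i, :, 0]
            cols[f"id{i}_y"] = series.positions[i, :, 1]
        if series.headings is not None:
            cols[f"id{i}_theta"] = series.headings[i]
        cols[f"id{i}_obs"] = series.values[i]
    path = prefix.with_suffix(".csv")
    pd.DataFrame(cols).to_csv(path, index=False)
    if config is not None:
        meta = dict(config)
        meta.setdefault("dt", series.dt)
        meta.setdefault("observable_name", series.observable_name)
        prefix.with_suffix(".config.yaml").write_text(yaml.safe_dump(meta))
    return path


def read_trajectories(path: str | Path, format: str = "wide_csv") -> TimeSeriesSet | KinematicsTable:
    """Load a wide-CSV trajectory table.

    Returns a :class:`KinematicsTable` when the header carries full 3D
    kinematics columns, otherwise a :class:`TimeSeriesSet` built from the
    ``id{i}_obs`` columns.  Rows with missing values are dropped with a
    logged count; a non-monotone time column or ragged/unschematic header is
    rejected with the offending row.
    """
    if format != "wide_csv":
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)
    df = pd.read_csv(path)
    if "t" not in df.columns:
        raise ValueError(f"{path}: missing header or 't' column")
    n_before = len(df)
    df = df.dropna().reset_index(drop=True)
    if len(df) < n_before:
        logger.warning("%s: dropped %d row(s) with missing values", path, n_before - len(df))
    t = df["t"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: need at least two rows")
    dts = np.diff(t)
    if np.any(dts <= 0):
        row = int(np.argmax(dts <= 0)) + 1
        raise ValueError(f"{path}: non-monotone time at row {row}")
    dt = float(np.median(dts))

    ids = sorted(
        {int(m.group(1)) for c in df.columns if (m := re.match(r"id(\d+)_", c))}
    )
    if not ids or ids != list(range(len(ids))):
        raise ValueError(f"{path}: individual columns must be contiguous id0_, id1_, ...")

    if all(f"id{i}_{f}" in df.columns for i in ids for f in _KIN_FIELDS):
        frame = df[[f"id{i}_{f}" for i in ids for f in _KIN_FIELDS]]
        return KinematicsTable(frame=frame, frame_rate=1.0 / dt)

    if not all(f"id{i}_obs" in df.columns for i in ids):
        raise ValueError(f"{path}: expected id{{i}}_obs columns")
    values = np.stack([df[f"id{i}_obs"].to_numpy(dtype=float) for i in ids])
    positions = headings = None
    if all(f"id{i}_x" in df.columns and f"id{i}_y" in df.columns for i in ids):
        positions = np.stack(
            [np.column_stack([df[f"id{i}_x"], df[f"id{i}_y"]]) for i in ids]
        )
    if all(f"id{i}_theta" in df.columns for i in ids):
        headings = np.stack([df[f"id{i}_theta"].to_numpy(dtype=float) for i in ids])
    return TimeSeriesSet(values=values, dt=dt, positions=positions, headings=headings)


def read_sidecar(prefix: str | Path) -> dict:
    """Load the ``<prefix>.config.yaml`` sidecar written next to a CSV."""
    return yaml.safe_load(Path(prefix).with_suffix(".config.yaml").read_text())


def derive_observable(k: KinematicsTable, kind: str = "accel_magnitude") -> TimeSeriesSet:
    """Scalar observable series from a 3D kinematics table.

    ``accel_magnitude`` is the per-frame Euclidean norm of the acceleration
    vector (the observable of choice for fully 3D flight); ``turn_rate`` is
    the wrapped first difference of the planar heading times the frame rate
    (appropriate for near-planar, constant-speed motion).
    """
    dt = 1.0 / k.frame_rate
    if kind == "accel_magnitude":
        acc = np.stack([k.array(f) for f in ("ax", "ay", "az")], axis=-1)
        return TimeSeriesSet(
            values=np.linalg.norm(acc, axis=-1), dt=dt, observable_name="acceleration_magnitude"
        )
    if kind == "turn_rate":
        heading = np.arctan2(k.array("vy"), k.array("vx"))
        turn = wrap_angle(np.diff(heading, axis=1)) * k.frame_rate
        return TimeSeriesSet(values=turn, dt=dt, observable_name="turn_rate")
    raise ValueError(f"unknown observable kind {kind!r}")
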