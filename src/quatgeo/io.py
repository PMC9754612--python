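"""Plain-text trajectory files and their metadata sidecars.

One CSV file per trial, self-describing through its header:

* quaternion dialect — columns ``t,qw,qx,qy,qz`` (scalar-first unit
  quaternions), the default for writing;
* matrix dialect — columns ``t,r11,...,r33`` (row-major 3x3 rotation
  matrices), matching how robotic recordings are typically logged;
  converted to quaternions on load.

Floats are written with 17 significant digits so parse -> serialize ->
parse is lossless.  Trial metadata (trial index, session, group, initial
and target orientations, seeds, ...) travels in a JSON sidecar named
``<file>.meta.json`` next to the trajectory file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import quatcore as qc
from .preprocess import OrientationTrajectory, TrajectoryError

__all__ = [
    "FormatError",
    "read_trajectory",
    "write_trajectory",
    "metadata_path",
    "read_trial_dir",
    "LoadedTrial",
]

QUAT_COLUMNS = ["t", "qw", "qx", "qy", "qz"]
MATRIX_COLUMNS = ["t"] + [f"r{i}{j}" for i in range(1, 4) for j in range(1, 4)]


class FormatError(ValueError):
    """Unknown header or malformed rows in a trajectory file."""


def metadata_path(path) -> Path:
    return Path(path).with_suffix(Path(path).suffix + ".meta.json")


def _jsonable(value: Any) -> Any:
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value


def write_trajectory(traj: OrientationTrajectory, path, metadata: dict | None = None,
                     dialect: str = "quaternion") -> None:
    """Write a trajectory as CSV (plus a JSON metadata sidecar if given).

    The quaternion dialect is the default; ``dialect="matrix"`` writes
    row-major rotation matrices instead.  Output bytes are deterministic
    for identical inputs (fixed field order, 17-digit floats).
    """
    path = Path(path)
    if dialect == "quaternion":
        data = np.column_stack([traj.t, traj.q])
        header = QUAT_COLUMNS
    elif dialect == "matrix":
        mats = qc.to_rotation_matrix(traj.q).reshape(len(traj), 9)
        data = np.column_stack([traj.t, mats])
        header = MATRIX_COLUMNS
    else:
        raise ValueError("dialect must be 'quaternion' or 'matrix'")
    lines = [",".join(header)]
    for row in data:
        lines.append(",".join(f"{x:.17g}" for x in row))
    path.write_text("\n".join(lines) + "\n")
    if metadata is not None:
        meta = dict(_jsonable(metadata))
        if traj.rate is not None:
            meta.setdefault("rate", traj.rate)
        metadata_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def read_trajectory(path) -> tuple[OrientationTrajectory, dict | None]:
    """Read a trajectory file (either dialect) and its metadata sidecar.

    The dialect is auto-detected from the header.  Malformed rows and
    non-monotonic timestamps are reported with their line numbers
    (1-based, header = line 1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: cannot parse CSV ({exc})") from exc
    cols = list(frame.columns)
    if cols == QUAT_COLUMNS:
        dialect = "quaternion"
    elif cols == MATRIX_COLUMNS:
        dialect = "matrix"
    else:
        raise FormatError(f"{path}: unknown header {cols}; expected {QUAT_COLUMNS} or {MATRIX_COLUMNS}")
    values = frame.to_numpy(dtype=float)
    bad = np.nonzero(~np.isfinite(values).all(axis=1))[0]
    if len(bad):
        lines = ", ".join(str(i + 2) for i in bad[:5])
        raise FormatError(f"{path}: malformed rows at lines {lines}")
    t = values[:, 0]
    nonmono = np.nonzero(np.diff(t) <= 0)[0]
    if len(nonmono):
        raise TrajectoryError(f"{path}: non-monotonic timestamp at line {int(nonmono[0]) + 3}")
    if dialect == "quaternion":
        q = values[:, 1:5]
        norms = np.linalg.norm(q, axis=1)
        off = np.nonzero(np.abs(norms - 1.0) > 1e-6)[0]
        if len(off):
            raise FormatError(f"{path}: non-unit quaternion at line {int(off[0]) + 2}")
    else:
        q = qc.from_rotation_matrix(values[:, 1:10].reshape(-1, 3, 3))

    meta = None
    mpath = metadata_path(path)
    if mpath.exists():
        meta = json.loads(mpath.read_text())
    rate = meta.get("rate") if meta else None
    if rate is None:
        dt = np.diff(t)
        if dt.max() - dt.min() <= 1e-6 * dt.mean():
            rate = 1.0 / dt.mean()
    traj = OrientationTrajectory(t, q, rate=rate)
    return traj, meta


@dataclass
class LoadedTrial:
    """A trial read back from disk, mirroring the simulator's Trial surface."""

    index: int
    session: str
    group: str | None
    trajectory: OrientationTrajectory
    metadata: dict


def read_trial_dir(directory) -> list[LoadedTrial]:
    """Load every ``trial_*.csv`` in a participant directory, sorted by index.

    Each trial file must carry a metadata sidecar with at least ``index``
    and ``session`` fields (written by the simulator / CLI).
    """
    directory = Path(directory)
    files = sorted(directory.glob("trial_*.csv"))
    if not files:
        raise FileNotFoundError(f"no trial_*.csv files in {directory}")
    out = []
    for f in files:
        traj, meta = read_trajectory(f)
        if not meta or "index" not in meta or "session" not in meta:
            raise FormatError(f"{f}: missing metadata sidecar with 'index' and 'session'")
        out.append(
            LoadedTrial(
                index=int(meta["index"]),
                session=str(meta["session"]),
                group=meta.get("group"),
                trajectory=traj,
                metadata=meta,
            )
        )
    out.sort(key=lambda tr: tr.index)
    return out
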