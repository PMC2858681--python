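"""Trial-table CSV I/O and run-configuration parsing.

Trial files are plain CSV (UTF-8, comma separator, ``.`` decimal, mandatory
header): a ``trial`` column, an optional ``day`` column, then one column per
execution variable named after the frame's axes.  Floats are written with 12
significant digits so that a write/read round trip is lossless at that
precision.

Run configurations are YAML with a ``task`` block (reaching | skittles), a
``frames`` block, and per-analysis blocks; :func:`build_task` materializes
the model objects.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ExecutionSet
from .frames import (
    ABSOLUTE_ANGLES,
    CARTESIAN_RELEASE,
    HAND_SPACE,
    POLAR_RELEASE,
    RELATIVE_ANGLES,
    CoordinateFrame,
    LeverGeometry,
)
from .reaching import ReachingTask, TargetLine, TwoJointArm, forward_kinematics
from .skittles import SkittlesModel

__all__ = [
    "KNOWN_FRAMES",
    "read_trials",
    "write_trials",
    "read_config",
    "build_task",
    "write_report",
]

KNOWN_FRAMES: dict[str, CoordinateFrame] = {
    f.name: f
    for f in (ABSOLUTE_ANGLES, RELATIVE_ANGLES, HAND_SPACE, POLAR_RELEASE,
              CARTESIAN_RELEASE)
}


def resolve_frame(name: str) -> CoordinateFrame:
    try:
        return KNOWN_FRAMES[name]
    except KeyError:
        raise ValueError(
            f"unknown frame {name!r}; known: {sorted(KNOWN_FRAMES)}"
        ) from None


def read_trials(path, frame: CoordinateFrame | str) -> ExecutionSet:
    """Read a trial CSV into an ExecutionSet, with specific error messages."""
    if isinstance(frame, str):
        frame = resolve_frame(frame)
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if df.shape[0] < 2:
        raise ValueError(f"{path.name}: fewer than 2 trials")
    missing = [c for c in frame.axis_names if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing execution columns {missing}")
    for col in frame.axis_names:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path.name}: non-numeric cell at row {row}, column {col!r}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ValueError(f"{path.name}: empty cell at row {row}, column {col!r}")
        df[col] = coerced
    return ExecutionSet.from_dataframe(df, frame)


def write_trials(data: ExecutionSet, path, header_comment: str | None = None) -> None:
    """Write an ExecutionSet as CSV with 12 significant digits."""
    path = Path(path)
    df = data.to_frame()
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False, float_format="%.12g")


def read_config(path) -> dict:
    """Load and minimally validate a YAML run configuration."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    task = cfg.get("task", {})
    if task and task.get("kind") not in ("reaching", "skittles"):
        raise ValueError("config error at task.kind: must be 'reaching' or 'skittles'")
    for key in ("seed",):
        for block in ("ucm", "tnc", "simulate"):
            if key in cfg.get(block, {}) and not isinstance(cfg[block][key], int):
                raise ValueError(f"config error at {block}.{key}: must be an integer")
    return cfg


def build_task(cfg: dict):
    """Materialize the task object named by the config's ``task`` block."""
    task = cfg.get("task", {})
    kind = task.get("kind", "reaching")
    if kind == "reaching":
        arm = TwoJointArm(
            l1=float(task.get("l1", 0.4)),
            l2=float(task.get("l2", 0.4)),
            shoulder=tuple(task.get("shoulder", (0.0, 0.0))),
        )
        if "line_angle_deg" in task or "line_anchor" in task:
            anchor = task.get("line_anchor")
            if anchor is None:
                anchor = forward_kinematics(np.deg2rad([135.0, 45.0]), arm)
            line = TargetLine.through_point_at_angle(
                np.asarray(anchor, dtype=float),
                np.deg2rad(float(task.get("line_angle_deg", 45.0))),
            )
        else:
            line = ReachingTask.default().line
        frame = resolve_frame(task.get("frame", "absolute"))
        return ReachingTask(arm=arm, line=line, frame=frame)
    if kind == "skittles":
        lever = task.get("lever", {})
        return SkittlesModel(
            omega=float(task.get("omega", 3.16)),
            tau=float(task["tau"]) if "tau" in task else np.inf,
            post_center=tuple(task.get("post_center", (0.0, 0.0))),
            post_radius=float(task.get("post_radius", 0.25)),
            target=tuple(task.get("target", (0.0, 1.0))),
            lever=LeverGeometry(
                pivot=tuple(lever.get("pivot", (0.0, -1.5))),
                length=float(lever.get("length", 0.4)),
                counterclockwise=bool(lever.get("counterclockwise", True)),
            ),
            horizon=task.get("horizon"),
        )
    raise ValueError(f"unknown task kind {kind!r}")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        return super().default(o)


def write_report(report: dict, path=None) -> str:
    """Serialize an analysis report to JSON (stdout-ready string)."""
    text = json.dumps(report, indent=2, cls=_NumpyEncoder, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text
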