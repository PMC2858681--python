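"""Core containers shared by every analysis.

An :class:`ExecutionSet` is the trial table every analysis consumes: N trials
by n execution variables, tagged with the coordinate frame the numbers live
in.  A :class:`ResultFunction` maps an execution point to a scalar
non-negative task error (the "result"); a :class:`SolutionManifold` is the
polyline of zero-error execution points at the bottom of the error valley.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .frames import CoordinateFrame, CoordinateTransform

__all__ = ["ExecutionSet", "ResultFunction", "SolutionManifold"]


@dataclass
class ExecutionSet:
    """N trials of n execution variables in a declared coordinate frame.

    Parameters
    ----------
    data : (N, n) array
        One row per trial, one column per execution variable.
    frame : CoordinateFrame
        The coordinate frame of the columns; ``n == frame.dim``.
    trial_ids : sequence, optional
        Per-trial identifiers (defaults to 0..N-1).
    labels : sequence, optional
        Optional block/day labels, one per trial.
    """

    data: np.ndarray
    frame: CoordinateFrame
    trial_ids: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] < 2:
            raise ValueError("an ExecutionSet needs at least 2 trials")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("execution data contains non-finite entries")
        if self.data.shape[1] != self.frame.dim:
            raise ValueError(
                f"data has {self.data.shape[1]} columns but frame "
                f"{self.frame.name!r} has dimension {self.frame.dim}"
            )
        if self.trial_ids is None:
            self.trial_ids = np.arange(self.data.shape[0])
        else:
            self.trial_ids = np.asarray(self.trial_ids)
            if self.trial_ids.shape[0] != self.data.shape[0]:
                raise ValueError("trial_ids length mismatch")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape[0] != self.data.shape[0]:
                raise ValueError("labels length mismatch")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def dim(self) -> int:
        return self.data.shape[1]

    @property
    def mean(self) -> np.ndarray:
        return self.data.mean(axis=0)

    def subset(self, index: Sequence[int]) -> "ExecutionSet":
        index = np.asarray(index)
        return ExecutionSet(
            self.data[index],
            self.frame,
            trial_ids=self.trial_ids[index],
            labels=None if self.labels is None else self.labels[index],
        )

    def transformed(self, t: CoordinateTransform) -> "ExecutionSet":
        """The same trials re-expressed through ``t`` (source frame must match)."""
        if t.source.name != self.frame.name:
            raise ValueError(
                f"transform expects frame {t.source.name!r}, data is in "
                f"{self.frame.name!r}"
            )
        return ExecutionSet(
            t.apply_rows(self.data), t.target, trial_ids=self.trial_ids,
            labels=self.labels,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data, columns=list(self.frame.axis_names))
        df.insert(0, "trial", self.trial_ids)
        if self.labels is not None:
            df.insert(1, "day", self.labels)
        return df

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, frame: CoordinateFrame
    ) -> "ExecutionSet":
        cols = [c for c in frame.axis_names if c in df.columns]
        if len(cols) != frame.dim:
            missing = set(frame.axis_names) - set(df.columns)
            raise ValueError(f"missing execution columns: {sorted(missing)}")
        return cls(
            df[cols].to_numpy(dtype=float),
            frame,
            trial_ids=df["trial"].to_numpy() if "trial" in df.columns else None,
            labels=df["day"].to_numpy() if "day" in df.columns else None,
        )


@dataclass
class ResultFunction:
    """Many-to-one map from execution space to a scalar, non-negative error.

    ``evaluate`` returns the task error of one execution point in result
    units.  ``signed`` (optional) is a smooth signed version whose zero set is
    the solution manifold — used for root finding and curvature.  ``gradient``
    (optional) is the analytic gradient of the signed form.
    """

    frame: CoordinateFrame
    evaluate: Callable[[np.ndarray], float]
    units: str = ""
    gradient: Callable[[np.ndarray], np.ndarray] | None = None
    signed: Callable[[np.ndarray], float] | None = None
    evaluate_batch: Callable[[np.ndarray], np.ndarray] | None = None

    def __call__(self, p: Sequence[float]) -> float:
        return float(self.evaluate(np.asarray(p, dtype=float)))

    def batch(self, rows: np.ndarray) -> np.ndarray:
        """Vectorized evaluation over the rows of an (M, n) array."""
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        if self.evaluate_batch is not None:
            return np.asarray(self.evaluate_batch(rows), dtype=float)
        return np.array([self.evaluate(r) for r in rows], dtype=float)

    def mean_result(self, data: ExecutionSet | np.ndarray) -> float:
        """Arithmetic mean of the result over all trials."""
        rows = data.data if isinstance(data, ExecutionSet) else np.atleast_2d(data)
        vals = self.batch(rows)
        bad = np.flatnonzero(~np.isfinite(vals))
        if bad.size:
            raise ValueError(f"non-finite result at trial row {bad[0]}")
        return float(vals.mean())

    def reparametrized(self, t: CoordinateTransform) -> "ResultFunction":
        """The same physical result expressed in ``t.target`` coordinates.

        If ``t`` maps this function's frame into a new frame, the new function
        is ``f(t.inverse(q))`` — the error of the physically identical point.
        """
        if t.source.name != self.frame.name:
            raise ValueError(
                f"transform expects frame {t.source.name!r}, function is in "
                f"{self.frame.name!r}"
            )
        inv = t.inverse
        sgn = None
        if self.signed is not None:
            sgn = lambda q: self.signed(inv(np.asarray(q, dtype=float)))  # noqa: E731
        batch = None
        if t.is_linear:
            # rows of the new frame mapped back in one matrix operation
            inv_m = np.linalg.inv(t.matrix)
            off = t.offset

            def batch(rows, _inv_m=inv_m, _off=off):  # noqa: F811
                back = (np.atleast_2d(rows) - _off) @ _inv_m.T
                return self.batch(back)

        return ResultFunction(
            frame=t.target,
            evaluate=lambda q: self.evaluate(inv(np.asarray(q, dtype=float))),
            units=self.units,
            gradient=None,
            signed=sgn,
            evaluate_batch=batch,
        )


@dataclass
class SolutionManifold:
    """Polyline of zero-error execution points ("the bottom of the valley")."""

    vertices: np.ndarray
    frame: CoordinateFrame
    branch: np.ndarray | None = None  # optional per-vertex branch label

    def __post_init__(self) -> None:
        self.vertices = np.atleast_2d(np.asarray(self.vertices, dtype=float))
        if self.branch is not None:
            self.branch = np.asarray(self.branch)

    @property
    def n_vertices(self) -> int:
        return 0 if self.vertices.size == 0 else self.vertices.shape[0]

    def transformed(self, t: CoordinateTransform) -> "SolutionManifold":
        if self.n_vertices == 0:
            return SolutionManifold(np.empty((0, t.target.dim)), t.target)
        return SolutionManifold(
            t.apply_rows(self.vertices), t.target, branch=self.branch
        )
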