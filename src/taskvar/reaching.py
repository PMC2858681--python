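"""Two-joint planar arm pointing to a target line.

The model task: a planar arm with two segments (shoulder fixed) points to a
straight target line in hand space.  Every hand position on the line is a
perfect solution, so the task is redundant — the set of joint-angle pairs
whose hand point lies on the line forms a one-dimensional solution manifold
in the two-dimensional joint space.

Joint angles come in two common conventions, linearly related:

* absolute: both segment orientations measured against a fixed external line,
  (phi1, phi2); forward kinematics x = l1 cos phi1 + l2 cos phi2,
  y = l1 sin phi1 + l2 sin phi2.
* relative: the elbow angle measured against the upper arm,
  (theta1, theta2) = (phi1, phi2 - phi1).

The result (task error) of a posture is the distance of its hand point from
the target line, in metres.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
from scipy.optimize import brentq

from .core import ResultFunction, SolutionManifold
from .frames import (
    ABSOLUTE_ANGLES,
    RELATIVE_ANGLES,
    CoordinateFrame,
    absolute_from_relative,
    relative_from_absolute,
)

__all__ = [
    "TwoJointArm",
    "TargetLine",
    "ReachingTask",
    "OutOfWorkspaceError",
    "forward_kinematics",
    "inverse_kinematics",
    "kinematic_jacobian",
]


class OutOfWorkspaceError(ValueError):
    """Hand point not reachable by the arm."""


@dataclass(frozen=True)
class TwoJointArm:
    """Segment lengths in metres; the shoulder sits at ``shoulder``."""

    l1: float = 0.4
    l2: float = 0.4
    shoulder: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.l1 <= 0 or self.l2 <= 0:
            raise ValueError("segment lengths must be positive")


@dataclass(frozen=True)
class TargetLine:
    """Line {p : normal . p = offset} in hand space; |normal| = 1."""

    normal: tuple[float, float]
    offset: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("line normal must be a unit vector")

    @classmethod
    def through_point_at_angle(cls, point, angle_rad: float) -> "TargetLine":
        """Line through ``point`` whose direction makes ``angle_rad`` with x."""
        d = np.array([np.cos(angle_rad), np.sin(angle_rad)])
        n = np.array([-d[1], d[0]])
        return cls(tuple(n), float(n @ np.asarray(point, dtype=float)))

    def signed_distance(self, p) -> float:
        return float(np.asarray(self.normal) @ np.asarray(p, dtype=float) - self.offset)


def forward_kinematics(angles, arm: TwoJointArm, frame: str = "absolute") -> np.ndarray:
    """Hand position for a joint configuration.

    ``frame`` selects the angle convention of the input ("absolute" or
    "relative"); relative input is first mapped to absolute angles.
    """
    angles = np.asarray(angles, dtype=float)
    if frame == "relative":
        angles = absolute_from_relative(angles)
    elif frame != "absolute":
        raise ValueError(f"unknown angle frame {frame!r}")
    p1, p2 = angles
    return np.asarray(arm.shoulder, dtype=float) + np.array(
        [
            arm.l1 * np.cos(p1) + arm.l2 * np.cos(p2),
            arm.l1 * np.sin(p1) + arm.l2 * np.sin(p2),
        ]
    )


def kinematic_jacobian(angles_abs, arm: TwoJointArm) -> np.ndarray:
    """d(hand)/d(absolute angles): columns are l_i (-sin phi_i, cos phi_i)."""
    p1, p2 = np.asarray(angles_abs, dtype=float)
    return np.array(
        [
            [-arm.l1 * np.sin(p1), -arm.l2 * np.sin(p2)],
            [arm.l1 * np.cos(p1), arm.l2 * np.cos(p2)],
        ]
    )


def inverse_kinematics(
    hand, arm: TwoJointArm, elbow_branch: str = "down"
) -> np.ndarray:
    """Absolute joint angles reaching ``hand``; one of the two mirror solutions.

    ``elbow_branch`` selects the sign of the relative elbow angle:
    "down" gives theta2 <= 0, "up" gives theta2 >= 0.

    Raises
    ------
    OutOfWorkspaceError
        If ``hand`` lies outside the annulus |l1-l2| <= r <= l1+l2.
    """
    p = np.asarray(hand, dtype=float) - np.asarray(arm.shoulder, dtype=float)
    r2 = float(p @ p)
    r = np.sqrt(r2)
    if r > arm.l1 + arm.l2 + 1e-12 or r < abs(arm.l1 - arm.l2) - 1e-12:
        raise OutOfWorkspaceError(
            f"hand at radius {r:.4f} m outside workspace "
            f"[{abs(arm.l1 - arm.l2):.4f}, {arm.l1 + arm.l2:.4f}]"
        )
    c2 = (r2 - arm.l1**2 - arm.l2**2) / (2.0 * arm.l1 * arm.l2)
    c2 = float(np.clip(c2, -1.0, 1.0))
    t2 = np.arccos(c2)
    if elbow_branch == "down":
        t2 = -t2
    elif elbow_branch != "up":
        raise ValueError("elbow_branch must be 'up' or 'down'")
    t1 = np.arctan2(p[1], p[0]) - np.arctan2(
        arm.l2 * np.sin(t2), arm.l1 + arm.l2 * np.cos(t2)
    )
    return absolute_from_relative((t1, t2))


@dataclass
class ReachingTask:
    """Line-pointing task: arm, target line, and the analysis angle frame.

    The default geometry places the mean posture at absolute angles
    (135 deg, 45 deg) — segment orientations 90 deg apart, so the kinematic
    Jacobian there is a scaled rotation and isotropic hand noise stays
    isotropic in absolute angles — with the target line running at 45 deg
    through the mean hand point.
    """

    arm: TwoJointArm
    line: TargetLine
    frame: CoordinateFrame = ABSOLUTE_ANGLES

    @classmethod
    def default(cls, frame: CoordinateFrame = ABSOLUTE_ANGLES) -> "ReachingTask":
        arm = TwoJointArm()
        mean_posture = np.deg2rad([135.0, 45.0])
        hand = forward_kinematics(mean_posture, arm)
        line = TargetLine.through_point_at_angle(hand, np.deg2rad(45.0))
        return cls(arm=arm, line=line, frame=frame)

    # -- result function ---------------------------------------------------

    def _absolute(self, angles) -> np.ndarray:
        angles = np.asarray(angles, dtype=float)
        if self.frame.name == "relative":
            return absolute_from_relative(angles)
        return angles

    def signed_result(self, angles) -> float:
        """Signed line distance of the hand point (smooth across the manifold)."""
        return self.line.signed_distance(
            forward_kinematics(self._absolute(angles), self.arm)
        )

    def result(self, angles) -> float:
        """Task error: |distance of hand from the target line| in metres."""
        return abs(self.signed_result(angles))

    def result_gradient(self, angles) -> np.ndarray:
        """Gradient of the *unsigned* error w.r.t. the task's angle frame.

        Computed from the signed form by the chain rule; at points exactly on
        the line the signed-form gradient is returned (the |.| kink).
        """
        g = self.signed_result_gradient(angles)
        s = self.signed_result(angles)
        return g if s >= 0 else -g

    def signed_result_gradient(self, angles) -> np.ndarray:
        """Gradient of the signed line distance w.r.t. the task's angle frame."""
        abs_angles = self._absolute(angles)
        g_abs = np.asarray(self.line.normal) @ kinematic_jacobian(abs_angles, self.arm)
        if self.frame.name == "relative":
            # chain rule through (phi1, phi2) = (theta1, theta1 + theta2)
            return g_abs @ np.array([[1.0, 0.0], [1.0, 1.0]])
        return g_abs

    def result_batch(self, rows: np.ndarray) -> np.ndarray:
        """Vectorized |line distance| over the rows of an (M, 2) angle array."""
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        if self.frame.name == "relative":
            rows = rows @ np.array([[1.0, 0.0], [1.0, 1.0]]).T  # to absolute
        sx, sy = self.arm.shoulder
        x = sx + self.arm.l1 * np.cos(rows[:, 0]) + self.arm.l2 * np.cos(rows[:, 1])
        y = sy + self.arm.l1 * np.sin(rows[:, 0]) + self.arm.l2 * np.sin(rows[:, 1])
        nx, ny = self.line.normal
        return np.abs(nx * x + ny * y - self.line.offset)

    def result_function(self) -> ResultFunction:
        return ResultFunction(
            frame=self.frame,
            evaluate=self.result,
            units="m",
            gradient=self.signed_result_gradient,
            signed=self.signed_result,
            evaluate_batch=self.result_batch,
        )

    def in_frame(self, frame: CoordinateFrame) -> "ReachingTask":
        return ReachingTask(arm=self.arm, line=self.line, frame=frame)

    # -- solution manifold -------------------------------------------------

    def solution_manifold(
        self,
        phi1_range: tuple[float, float] = (np.deg2rad(90.0), np.deg2rad(180.0)),
        n_samples: int = 100,
    ) -> SolutionManifold:
        """Zero-error polyline: for each sampled phi1, solve for phi2 on the line.

        The signed error along phi2 (at fixed phi1) is bracketed by a scan and
        refined by bisection; each elbow branch of the scan is reported in the
        vertex list with a branch label.  All vertices satisfy
        ``result < 1e-8``.
        """
        phi1s = np.linspace(phi1_range[0], phi1_range[1], n_samples)
        verts: list[np.ndarray] = []
        labels: list[str] = []

        def signed_abs(p1: float, p2: float) -> float:
            return self.line.signed_distance(
                forward_kinematics((p1, p2), self.arm)
            )

        phi2_grid = np.linspace(-np.pi, np.pi, 721)
        for p1 in phi1s:
            vals = np.array([signed_abs(p1, p2) for p2 in phi2_grid])
            sign_change = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
            for k, idx in enumerate(sign_change[:2]):
                root = brentq(
                    lambda p2: signed_abs(p1, p2),
                    phi2_grid[idx],
                    phi2_grid[idx + 1],
                    xtol=1e-12,
                )
                verts.append(np.array([p1, root]))
                labels.append(f"branch{k}")

        if not verts:
            warn("no zero-error crossing in the requested phi1 range")
            return SolutionManifold(np.empty((0, 2)), ABSOLUTE_ANGLES)

        vertices = np.asarray(verts)
        manifold = SolutionManifold(
            vertices, ABSOLUTE_ANGLES, branch=np.asarray(labels)
        )
        if self.frame.name == "relative":
            rel = np.apply_along_axis(relative_from_absolute, 1, vertices)
            manifold = SolutionManifold(rel, RELATIVE_ANGLES, branch=np.asarray(labels))
        return manifold
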