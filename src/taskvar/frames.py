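"""Execution-space coordinate frames and the invertible maps between them.

Analyses of movement variability are carried out in a *coordinate frame* of
execution variables chosen by the experimenter (absolute vs. relative joint
angles, polar vs. Cartesian release variables, ...).  This module defines the
frame/transform vocabulary used throughout the package: a
:class:`CoordinateFrame` names the axes and units of an execution space, and a
:class:`CoordinateTransform` is an invertible, differentiable map between two
frames that carries its Jacobian (analytic for the named transforms, central
differences otherwise).

Angles are radians everywhere inside the library; degrees appear only at the
CLI boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "CoordinateFrame",
    "CoordinateTransform",
    "DegenerateInputError",
    "absolute_from_relative",
    "relative_from_absolute",
    "absolute_relative_transform",
    "LeverGeometry",
    "release_cartesian_from_polar",
    "release_polar_from_cartesian",
    "release_transform",
    "linear_transform",
    "identity_transform",
    "compose",
    "transform_jacobian",
    "angle_under_transform",
]


class DegenerateInputError(ValueError):
    """Raised when a transform is evaluated where it is not defined
    (e.g. inverting a zero release velocity, whose direction is indeterminate)."""


@dataclass(frozen=True)
class CoordinateFrame:
    """A named execution-space coordinate frame.

    Parameters
    ----------
    name : str
        Short label, unique within a registry ("absolute", "polar", ...).
    axis_names : sequence of str
        One label per execution variable.
    axis_units : sequence of str
        One unit per execution variable (e.g. "rad", "rad/s", "m/s").
    """

    name: str
    axis_names: tuple[str, ...]
    axis_units: tuple[str, ...]

    def __init__(self, name: str, axis_names: Sequence[str], axis_units: Sequence[str]):
        object.__setattr__(self, "name", str(name))
        object.__setattr__(self, "axis_names", tuple(axis_names))
        object.__setattr__(self, "axis_units", tuple(axis_units))
        if len(self.axis_names) != len(self.axis_units):
            raise ValueError("axis_names and axis_units must have equal length")
        if len(self.axis_names) == 0:
            raise ValueError("frame must have positive dimension")

    @property
    def dim(self) -> int:
        return len(self.axis_names)


@dataclass
class CoordinateTransform:
    """Invertible point map between two frames, with Jacobian.

    ``forward`` maps a point of ``source`` into ``target``; ``inverse`` undoes
    it.  Linear (affine) transforms carry an explicit ``matrix`` and ``offset``
    so that ``forward(p) = matrix @ p + offset``.
    """

    source: CoordinateFrame
    target: CoordinateFrame
    forward: Callable[[np.ndarray], np.ndarray]
    inverse: Callable[[np.ndarray], np.ndarray]
    is_linear: bool = False
    matrix: np.ndarray | None = None
    offset: np.ndarray | None = None
    jacobian: Callable[[np.ndarray], np.ndarray] | None = field(default=None)
    fd_step: float = 1e-6

    def __post_init__(self) -> None:
        if self.is_linear:
            if self.matrix is None:
                raise ValueError("linear transform requires an explicit matrix")
            self.matrix = np.asarray(self.matrix, dtype=float)
            if self.offset is None:
                self.offset = np.zeros(self.matrix.shape[0])
            self.offset = np.asarray(self.offset, dtype=float)
            if not np.isfinite(np.linalg.cond(self.matrix)):
                raise ValueError("linear transform matrix is singular")

    def __call__(self, p: np.ndarray) -> np.ndarray:
        return self.forward(np.asarray(p, dtype=float))

    def apply_rows(self, data: np.ndarray) -> np.ndarray:
        """Apply the forward map to every row of an (N, dim) array."""
        data = np.asarray(data, dtype=float)
        return np.apply_along_axis(self.forward, 1, data)

    def inverted(self) -> "CoordinateTransform":
        """The reverse transform (target -> source)."""
        if self.is_linear:
            inv = np.linalg.inv(self.matrix)
            return linear_transform(self.target, self.source, inv, -inv @ self.offset)
        return CoordinateTransform(
            source=self.target,
            target=self.source,
            forward=self.inverse,
            inverse=self.forward,
            fd_step=self.fd_step,
        )


# ---------------------------------------------------------------------------
# Named frames

ABSOLUTE_ANGLES = CoordinateFrame("absolute", ("phi1", "phi2"), ("rad", "rad"))
RELATIVE_ANGLES = CoordinateFrame("relative", ("theta1", "theta2"), ("rad", "rad"))
HAND_SPACE = CoordinateFrame("hand", ("x", "y"), ("m", "m"))
POLAR_RELEASE = CoordinateFrame("polar", ("theta", "theta_dot"), ("rad", "rad/s"))
CARTESIAN_RELEASE = CoordinateFrame("cartesian", ("vx", "vy"), ("m/s", "m/s"))


# ---------------------------------------------------------------------------
# Absolute <-> relative joint angles

#: phi1 = theta1, phi2 = theta1 + theta2
_ABS_FROM_REL = np.array([[1.0, 0.0], [1.0, 1.0]])


def absolute_from_relative(angles: Sequence[float]) -> np.ndarray:
    """Map relative joint angles (theta1, theta2) to absolute (phi1, phi2).

    The upper-arm angle is shared; the forearm's absolute orientation is the
    sum of the upper-arm orientation and the relative elbow angle:
    ``(phi1, phi2) = (theta1, theta1 + theta2)``.
    """
    t1, t2 = np.asarray(angles, dtype=float)
    return np.array([t1, t1 + t2])


def relative_from_absolute(angles: Sequence[float]) -> np.ndarray:
    """Inverse of :func:`absolute_from_relative`."""
    p1, p2 = np.asarray(angles, dtype=float)
    return np.array([p1, p2 - p1])


def absolute_relative_transform() -> CoordinateTransform:
    """The linear transform object relative -> absolute joint angles."""
    return linear_transform(RELATIVE_ANGLES, ABSOLUTE_ANGLES, _ABS_FROM_REL)


# ---------------------------------------------------------------------------
# Polar <-> Cartesian release variables (skittles manipulandum)


@dataclass(frozen=True)
class LeverGeometry:
    """Manipulandum geometry: a lever of given length rotating about a pivot.

    ``counterclockwise`` fixes the rotation sense used to invert the
    polar -> Cartesian velocity map (the sense is a modelling convention; the
    map is bijective away from zero velocity once it is fixed).
    """

    pivot: tuple[float, float] = (0.0, 0.0)
    length: float = 0.4
    counterclockwise: bool = True

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("lever length must be positive")


def release_cartesian_from_polar(
    theta: float, theta_dot: float, lever: LeverGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Hand position and velocity at release from lever angle and angular velocity.

    position = pivot + L (cos theta, sin theta);
    velocity = theta_dot * L * (-sin theta, cos theta)  (tangential).
    """
    L = lever.length
    pos = np.asarray(lever.pivot, dtype=float) + L * np.array(
        [np.cos(theta), np.sin(theta)]
    )
    vel = theta_dot * L * np.array([-np.sin(theta), np.cos(theta)])
    return pos, vel


def release_polar_from_cartesian(
    vx: float, vy: float, lever: LeverGeometry
) -> tuple[float, float]:
    """Recover (theta, theta_dot) from the release velocity via tangency.

    The velocity is tangential to the lever arc, so its direction fixes theta
    up to the rotation sense and its magnitude fixes |theta_dot| = |v| / L.

    Raises
    ------
    DegenerateInputError
        At zero velocity, whose direction is indeterminate.
    """
    speed = float(np.hypot(vx, vy))
    if speed == 0.0:
        raise DegenerateInputError(
            "zero release velocity: lever angle is indeterminate"
        )
    if lever.counterclockwise:
        theta = np.arctan2(vy, vx) - np.pi / 2.0
        theta_dot = speed / lever.length
    else:
        theta = np.arctan2(vy, vx) + np.pi / 2.0
        theta_dot = -speed / lever.length
    return float(theta), float(theta_dot)


def release_transform(lever: LeverGeometry) -> CoordinateTransform:
    """Nonlinear transform (theta, theta_dot) -> (vx, vy) with analytic Jacobian."""

    def fwd(p: np.ndarray) -> np.ndarray:
        _, vel = release_cartesian_from_polar(p[0], p[1], lever)
        return vel

    def inv(v: np.ndarray) -> np.ndarray:
        theta, theta_dot = release_polar_from_cartesian(v[0], v[1], lever)
        return np.array([theta, theta_dot])

    def jac(p: np.ndarray) -> np.ndarray:
        theta, theta_dot = p
        L = lever.length
        # d(vx, vy)/d(theta, theta_dot)
        return np.array(
            [
                [-theta_dot * L * np.cos(theta), -L * np.sin(theta)],
                [-theta_dot * L * np.sin(theta), L * np.cos(theta)],
            ]
        )

    return CoordinateTransform(
        source=POLAR_RELEASE,
        target=CARTESIAN_RELEASE,
        forward=fwd,
        inverse=inv,
        jacobian=jac,
    )


# ---------------------------------------------------------------------------
# Generic constructors


def linear_transform(
    source: CoordinateFrame,
    target: CoordinateFrame,
    matrix: np.ndarray,
    offset: np.ndarray | None = None,
) -> CoordinateTransform:
    """Affine transform p -> matrix @ p + offset with exact Jacobian."""
    matrix = np.asarray(matrix, dtype=float)
    if offset is None:
        offset = np.zeros(matrix.shape[0])
    offset = np.asarray(offset, dtype=float)
    inv_m = np.linalg.inv(matrix)

    return CoordinateTransform(
        source=source,
        target=target,
        forward=lambda p: matrix @ np.asarray(p, dtype=float) + offset,
        inverse=lambda q: inv_m @ (np.asarray(q, dtype=float) - offset),
        is_linear=True,
        matrix=matrix,
        offset=offset,
        jacobian=lambda p: matrix,
    )


def identity_transform(frame: CoordinateFrame) -> CoordinateTransform:
    return linear_transform(frame, frame, np.eye(frame.dim))


def compose(second: CoordinateTransform, first: CoordinateTransform) -> CoordinateTransform:
    """The transform ``second(first(.))``; linear if both factors are linear."""
    if first.target.name != second.source.name:
        raise ValueError(
            f"cannot compose: {first.target.name!r} != {second.source.name!r}"
        )
    if first.is_linear and second.is_linear:
        return linear_transform(
            first.source,
            second.target,
            second.matrix @ first.matrix,
            second.matrix @ first.offset + second.offset,
        )
    jac = None
    if first.jacobian is not None and second.jacobian is not None:
        jac = lambda p: second.jacobian(first.forward(p)) @ first.jacobian(p)  # noqa: E731
    return CoordinateTransform(
        source=first.source,
        target=second.target,
        forward=lambda p: second.forward(first.forward(p)),
        inverse=lambda q: first.inverse(second.inverse(q)),
        jacobian=jac,
    )


# ---------------------------------------------------------------------------
# Jacobians and angles


def transform_jacobian(t: CoordinateTransform, at: Sequence[float]) -> np.ndarray:
    """Jacobian matrix of ``t`` at a point.

    Exact for linear transforms and transforms carrying an analytic Jacobian;
    otherwise central differences with step ``t.fd_step * (1 + |coordinate|)``
    per axis.
    """
    at = np.asarray(at, dtype=float)
    if t.is_linear:
        return np.array(t.matrix, copy=True)
    if t.jacobian is not None:
        return np.asarray(t.jacobian(at), dtype=float)
    n = at.size
    f0 = np.asarray(t.forward(at), dtype=float)
    J = np.empty((f0.size, n))
    for j in range(n):
        h = t.fd_step * (1.0 + abs(at[j]))
        e = np.zeros(n)
        e[j] = h
        J[:, j] = (np.asarray(t.forward(at + e)) - np.asarray(t.forward(at - e))) / (
            2.0 * h
        )
    return J


def angle_under_transform(
    u: Sequence[float],
    v: Sequence[float],
    t: CoordinateTransform,
    at: Sequence[float],
) -> float:
    """Angle in degrees between the images of directions u and v under ``t``.

    Directions are pushed forward through the Jacobian of ``t`` at ``at``;
    orthogonal maps preserve the 90 degrees of an orthonormal pair, while a
    mere axis rescaling already distorts it.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if not (np.linalg.norm(u) > 0 and np.linalg.norm(v) > 0):
        raise ValueError("direction vectors must be nonzero")
    J = transform_jacobian(t, at)
    if np.linalg.matrix_rank(J) < min(J.shape):
        raise ValueError("singular Jacobian: directions collapse")
    ju, jv = J @ u, J @ v
    c = float(np.dot(ju, jv) / (np.linalg.norm(ju) * np.linalg.norm(jv)))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
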