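"""Virtual skittles: throwing a tethered ball around a post to hit a target.

The player rotates a lever (manipulandum) and releases a ball that is tied by
an elastic tether to a central post.  After release the ball moves in the
horizontal plane under an isotropic linear restoring force toward the post
(optionally damped), so its trajectory has the closed form, per component
relative to the post center,

    x(t) = [x0 cos(w t) + (vx0 / w) sin(w t)] exp(-t / tau)

with natural frequency ``w`` and damping time constant ``tau`` (``tau = inf``
gives the undamped elliptical orbit).  The throw's result is the closest
approach of the ball to the target within one flight horizon — zero when the
ball passes through the target.

Execution variables come in two frames: "polar" (lever angle and angular
velocity at release) and "cartesian" (the two components of release
velocity).  The two frames describe the same physics, so the result of a
throw is frame independent; the error *landscape*, however, is a distorted
copy of one frame in the other.
"""

from __future__ import annotations

from dataclasses import dataclass
from warnings import warn

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .core import ResultFunction, SolutionManifold
from .frames import (
    CARTESIAN_RELEASE,
    POLAR_RELEASE,
    LeverGeometry,
    release_cartesian_from_polar,
    release_polar_from_cartesian,
    release_transform,
)

__all__ = ["SkittlesModel", "BallTrajectory", "landscape_grid"]


@dataclass
class BallTrajectory:
    """Closed-form ball flight after release."""

    release_pos: np.ndarray
    release_vel: np.ndarray
    omega: float
    tau: float
    post_center: np.ndarray

    def position(self, t) -> np.ndarray:
        """Ball position at time(s) t; shape (..., 2)."""
        t = np.asarray(t, dtype=float)
        r0 = self.release_pos - self.post_center
        w = self.omega
        osc = (
            np.multiply.outer(np.cos(w * t), r0)
            + np.multiply.outer(np.sin(w * t), self.release_vel / w)
        )
        damp = np.exp(-t / self.tau) if np.isfinite(self.tau) else np.ones_like(t)
        return self.post_center + osc * damp[..., None]

    def velocity(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        r0 = self.release_pos - self.post_center
        w = self.omega
        osc = (
            np.multiply.outer(np.cos(w * t), r0)
            + np.multiply.outer(np.sin(w * t), self.release_vel / w)
        )
        dosc = (
            np.multiply.outer(-w * np.sin(w * t), r0)
            + np.multiply.outer(np.cos(w * t), self.release_vel)
        )
        if np.isfinite(self.tau):
            damp = np.exp(-t / self.tau)
            return (dosc - osc / self.tau) * damp[..., None]
        return dosc

    def acceleration(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        r0 = self.release_pos - self.post_center
        w = self.omega
        osc = (
            np.multiply.outer(np.cos(w * t), r0)
            + np.multiply.outer(np.sin(w * t), self.release_vel / w)
        )
        dosc = (
            np.multiply.outer(-w * np.sin(w * t), r0)
            + np.multiply.outer(np.cos(w * t), self.release_vel)
        )
        if np.isfinite(self.tau):
            damp = np.exp(-t / self.tau)
            return (
                -(w**2) * osc - 2.0 * dosc / self.tau + osc / self.tau**2
            ) * damp[..., None]
        return -(w**2) * osc


@dataclass
class SkittlesModel:
    """Task physics and geometry.

    Parameters
    ----------
    omega : float
        Natural frequency sqrt(k/m) of the tether restoring force, rad/s.
    tau : float
        Damping time constant in seconds; ``inf`` means undamped.
    post_center, post_radius : post obstacle (the tether anchor).
    target : target point to hit, metres.
    lever : manipulandum geometry (pivot, length, rotation sense).
    horizon : flight time over which the closest approach is evaluated;
        at least one period 2 pi / omega when undamped.
    """

    omega: float = 3.16
    tau: float = np.inf
    post_center: tuple[float, float] = (0.0, 0.0)
    post_radius: float = 0.25
    target: tuple[float, float] = (0.0, 1.0)
    lever: LeverGeometry = LeverGeometry(pivot=(0.0, -1.5), length=0.4)
    horizon: float | None = None

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.post_radius < 0:
            raise ValueError("post radius must be non-negative")
        if self.horizon is None:
            self.horizon = self.period
        if not np.isfinite(self.tau) and self.horizon < self.period - 1e-12:
            raise ValueError("horizon must cover one period when undamped")

    @property
    def period(self) -> float:
        return 2.0 * np.pi / self.omega

    # -- physics -----------------------------------------------------------

    def trajectory_from_polar(self, theta: float, theta_dot: float) -> BallTrajectory:
        pos, vel = release_cartesian_from_polar(theta, theta_dot, self.lever)
        return BallTrajectory(
            release_pos=pos,
            release_vel=vel,
            omega=self.omega,
            tau=self.tau,
            post_center=np.asarray(self.post_center, dtype=float),
        )

    def trajectory_from_cartesian(self, vx: float, vy: float) -> BallTrajectory:
        theta, theta_dot = release_polar_from_cartesian(vx, vy, self.lever)
        return self.trajectory_from_polar(theta, theta_dot)

    def _trajectory(self, execution, frame_name: str) -> BallTrajectory:
        a, b = np.asarray(execution, dtype=float)
        if frame_name == "polar":
            return self.trajectory_from_polar(a, b)
        if frame_name == "cartesian":
            return self.trajectory_from_cartesian(a, b)
        raise ValueError(f"unknown skittles frame {frame_name!r}")

    def _contact_time(self, traj: BallTrajectory, ts: np.ndarray) -> float | None:
        """First time the ball enters the post circle, or None."""
        if self.post_radius == 0.0:
            return None
        d = np.linalg.norm(traj.position(ts) - np.asarray(self.post_center), axis=-1)
        inside = np.flatnonzero(d < self.post_radius)
        if inside.size == 0:
            return None
        i = inside[0]
        if i == 0:
            return float(ts[0])
        f = lambda t: (  # noqa: E731
            np.linalg.norm(traj.position(t) - np.asarray(self.post_center))
            - self.post_radius
        )
        return float(brentq(f, ts[i - 1], ts[i], xtol=1e-12))

    def closest_approach(
        self, execution, frame_name: str = "polar", n_time: int = 1000
    ) -> tuple[float, float, bool]:
        """(error, time of closest approach, post-collision flag).

        The distance to the target is scanned on a dense time grid
        (``n_time`` points per period) up to the horizon or the first post
        contact, then refined by bounded local minimization of the smooth
        closed-form squared distance.
        """
        traj = self._trajectory(execution, frame_name)
        t_stop = float(self.horizon)
        n = max(2, int(n_time * t_stop / self.period))
        ts = np.linspace(0.0, t_stop, n)
        collided = False
        tc = self._contact_time(traj, ts)
        if tc is not None:
            collided = True
            t_stop = tc
            ts = np.linspace(0.0, t_stop, max(2, int(n * tc / self.horizon) + 2))

        target = np.asarray(self.target, dtype=float)

        def dist2(t: float) -> float:
            d = traj.position(t) - target
            return float(d @ d)

        d2 = np.einsum("ij,ij->i", traj.position(ts) - target, traj.position(ts) - target)
        d2[0] = np.inf  # closest approach over t > 0 (release instant excluded)
        # refine every competitive local minimum: a near-circular orbit can
        # approach the target nearly equally twice per period
        interior = np.flatnonzero(
            (d2[1:-1] <= d2[:-2]) & (d2[1:-1] <= d2[2:])
        ) + 1
        cand = list(interior) + [len(ts) - 1]
        floor = d2[cand].min()
        t_best, best = float(ts[int(np.argmin(d2))]), float(d2.min())
        for i in sorted(cand, key=lambda k: d2[k])[:5]:
            if d2[i] > max(4.0 * floor, floor + 1e-6):
                continue
            lo = ts[max(i - 1, 0)]
            hi = ts[min(i + 1, len(ts) - 1)]
            if lo == hi:
                continue
            res = minimize_scalar(
                dist2, bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-13},
            )
            t_ref, f_ref = float(res.x), float(res.fun)
            # Newton polish on the analytic derivative of the squared
            # distance pins the minimum to machine precision
            for _ in range(4):
                d = traj.position(t_ref) - target
                v = traj.velocity(t_ref)
                acc = traj.acceleration(t_ref)
                g1 = 2.0 * float(d @ v)
                g2 = 2.0 * float(v @ v + d @ acc)
                if g2 <= 0:
                    break
                t_new = t_ref - g1 / g2
                if not lo <= t_new <= hi:
                    break
                t_ref = t_new
            f_new = dist2(t_ref)
            if f_new < f_ref:
                f_ref = f_new
            else:
                t_ref = float(res.x)
            if f_ref < best:
                t_best, best = t_ref, f_ref
        return float(np.sqrt(best)), t_best, collided

    # -- result function ---------------------------------------------------

    def result(self, execution, frame_name: str = "polar") -> float:
        """Task error: closest approach of the ball to the target, metres."""
        return self.closest_approach(execution, frame_name)[0]

    def signed_result(self, execution, frame_name: str = "polar") -> float:
        """Signed miss distance: the error with the sign of the cross product
        of the ball velocity at closest approach with the vector to the
        target.  Changes sign across the solution manifold, enabling
        bracketing/bisection for manifold extraction."""
        traj = self._trajectory(execution, frame_name)
        err, t_best, _ = self.closest_approach(execution, frame_name)
        v = traj.velocity(t_best)
        d = np.asarray(self.target, dtype=float) - traj.position(t_best)
        s = np.sign(v[0] * d[1] - v[1] * d[0])
        return float(err if s >= 0 else -err)

    def result_batch(
        self, rows: np.ndarray, frame_name: str = "polar", n_time: int = 1000,
        chunk: int = 2048,
    ) -> np.ndarray:
        """Vectorized closest approach over many executions.

        Uses a dense time grid (``n_time`` points per period) with one
        parabolic refinement of the interior minimum; post collisions truncate
        the scanned flight.  Precision is far below the solver tolerances used
        elsewhere (~1e-9 m), but slightly coarser than the scalar
        :meth:`result` path, so cost analyses should use one path throughout
        (they use this one).
        """
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        out = np.empty(rows.shape[0])
        for s in range(0, rows.shape[0], chunk):
            out[s : s + chunk] = self._result_batch_chunk(
                rows[s : s + chunk], frame_name, n_time
            )
        return out

    def _result_batch_chunk(
        self, rows: np.ndarray, frame_name: str, n_time: int
    ) -> np.ndarray:
        L = self.lever.length
        pivot = np.asarray(self.lever.pivot, dtype=float)
        if frame_name == "polar":
            theta, theta_dot = rows[:, 0], rows[:, 1]
        elif frame_name == "cartesian":
            speed = np.hypot(rows[:, 0], rows[:, 1])
            if np.any(speed == 0.0):
                raise ValueError("zero release velocity in batch input")
            if self.lever.counterclockwise:
                theta = np.arctan2(rows[:, 1], rows[:, 0]) - np.pi / 2.0
                theta_dot = speed / L
            else:
                theta = np.arctan2(rows[:, 1], rows[:, 0]) + np.pi / 2.0
                theta_dot = -speed / L
        else:
            raise ValueError(f"unknown skittles frame {frame_name!r}")

        r0 = pivot + L * np.stack([np.cos(theta), np.sin(theta)], axis=1)
        v0 = (theta_dot * L)[:, None] * np.stack(
            [-np.sin(theta), np.cos(theta)], axis=1
        )
        post = np.asarray(self.post_center, dtype=float)
        target = np.asarray(self.target, dtype=float)
        w = self.omega
        n = max(3, int(n_time * self.horizon / self.period))
        ts = np.linspace(0.0, float(self.horizon), n)

        def pos_grid(t):  # common time grid (K,) -> (M, K, 2)
            c, s = np.cos(w * t), np.sin(w * t)
            p = (
                (r0 - post)[:, None, :] * c[None, :, None]
                + (v0 / w)[:, None, :] * s[None, :, None]
            )
            if np.isfinite(self.tau):
                p *= np.exp(-t / self.tau)[None, :, None]
            return p + post

        def pos_per_trial(t):  # per-trial times (M,) -> (M, 2)
            c, s = np.cos(w * t), np.sin(w * t)
            p = (r0 - post) * c[:, None] + (v0 / w) * s[:, None]
            if np.isfinite(self.tau):
                p *= np.exp(-t / self.tau)[:, None]
            return p + post

        p = pos_grid(ts)  # (M, K, 2)
        d2_target = np.einsum("mkd,mkd->mk", p - target, p - target)
        colliders = np.zeros(rows.shape[0], dtype=bool)
        if self.post_radius > 0.0:
            d2_post = np.einsum("mkd,mkd->mk", p - post, p - post)
            colliders = (d2_post < self.post_radius**2).any(axis=1)
        d2_target[:, 0] = np.inf  # closest approach over t > 0
        k = np.argmin(d2_target, axis=1)
        best = d2_target[np.arange(rows.shape[0]), k]
        # one parabolic refinement where the minimum is interior
        interior = (k > 0) & (k < n - 1)
        km, kp = np.clip(k - 1, 0, n - 1), np.clip(k + 1, 0, n - 1)
        fm = d2_target[np.arange(rows.shape[0]), km]
        fp = d2_target[np.arange(rows.shape[0]), kp]
        denom = fp - 2.0 * best + fm
        ok = interior & np.isfinite(fm) & np.isfinite(fp) & (np.abs(denom) > 0)
        dt = ts[1] - ts[0]
        t_star = ts[k].copy()
        t_star[ok] -= 0.5 * dt * (fp[ok] - fm[ok]) / denom[ok]
        p_star = pos_per_trial(t_star)
        d2_star = np.einsum("md,md->m", p_star - target, p_star - target)
        best = np.where(ok, np.minimum(best, d2_star), best)
        out = np.sqrt(best)
        # post-contact truncation needs the refined contact time: take the
        # exact scalar path for the (typically few) colliding trials
        if colliders.any():
            for i in np.flatnonzero(colliders):
                out[i] = self.closest_approach(
                    (theta[i], theta_dot[i]), "polar", n_time=n_time
                )[0]
        return out

    def result_function(self, frame_name: str = "polar") -> ResultFunction:
        frame = POLAR_RELEASE if frame_name == "polar" else CARTESIAN_RELEASE
        return ResultFunction(
            frame=frame,
            evaluate=lambda p: self.result(p, frame_name),
            units="m",
            signed=lambda p: self.signed_result(p, frame_name),
            evaluate_batch=lambda rows: self.result_batch(rows, frame_name),
        )

    # -- solution manifold -------------------------------------------------

    def solution_manifold(
        self,
        frame_name: str = "polar",
        ranges: tuple[tuple[float, float], tuple[float, float]] | None = None,
        n: int = 50,
        scan: int = 200,
    ) -> SolutionManifold:
        """Zero-error polyline extracted column-by-column.

        For each of ``n`` values of the first execution variable, the signed
        miss distance is scanned over ``scan`` values of the second; each sign
        change is refined by bisection.  All vertices have error < 1e-6 m.
        """
        if ranges is None:
            ranges = self.default_ranges(frame_name)
        (a_lo, a_hi), (b_lo, b_hi) = ranges
        a_vals = np.linspace(a_lo, a_hi, n)
        b_grid = np.linspace(b_lo, b_hi, scan)
        verts: list[np.ndarray] = []
        for a in a_vals:
            vals = np.array(
                [self.signed_result((a, b), frame_name) for b in b_grid]
            )
            cross = np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)
            for idx in cross:
                f = lambda b: self.signed_result((a, b), frame_name)  # noqa: E731
                root = brentq(f, b_grid[idx], b_grid[idx + 1], xtol=1e-12)
                if self.result((a, root), frame_name) < 1e-6:
                    verts.append(self._polish_vertex((a, root), frame_name))
        if not verts:
            warn("no zero-error contour found in the requested ranges")
            frame = POLAR_RELEASE if frame_name == "polar" else CARTESIAN_RELEASE
            return SolutionManifold(np.empty((0, 2)), frame)
        frame = POLAR_RELEASE if frame_name == "polar" else CARTESIAN_RELEASE
        return SolutionManifold(np.asarray(verts), frame)

    def _polish_vertex(self, vertex, frame_name: str) -> np.ndarray:
        """Local 2-D minimization of the squared error around a bisection
        root.  The sign convention of the signed miss distance can flip at a
        closest-approach branch switch slightly off the true zero set; this
        polish removes the resulting ~1e-8 vertex offset."""
        from scipy.optimize import minimize

        v0 = np.asarray(vertex, dtype=float)
        h = lambda p: self.result(p, frame_name) ** 2  # noqa: E731
        if h(v0) < 1e-24:
            return v0
        res = minimize(
            h, v0, method="Nelder-Mead",
            options={
                "xatol": 1e-11, "fatol": 1e-26, "maxiter": 200,
                "initial_simplex": v0 + np.array(
                    [[0.0, 0.0], [1e-6, 0.0], [0.0, 1e-6]]
                ),
            },
        )
        return np.asarray(res.x) if res.fun < h(v0) else v0

    def default_ranges(self, frame_name: str):
        """Execution ranges that bracket the default task's solution manifold."""
        if frame_name == "polar":
            return ((np.deg2rad(50.0), np.deg2rad(75.0)), (1.0, 15.0))
        return ((-5.0, -0.5), (0.1, 3.5))

    def release_transform(self):
        """Polar -> Cartesian execution transform for this model's lever."""
        return release_transform(self.lever)


def landscape_grid(
    model: SkittlesModel,
    frame_name: str = "polar",
    ranges=None,
    resolution: int = 50,
):
    """Error sampled on a regular execution-space grid.

    Returns ``(axis1, axis2, errors)`` with ``errors[i, j]`` the result at
    ``(axis1[i], axis2[j])``.
    """
    if ranges is None:
        ranges = model.default_ranges(frame_name)
    (a_lo, a_hi), (b_lo, b_hi) = ranges
    if resolution < 2:
        raise ValueError("resolution must be at least 2 per axis")
    if a_lo >= a_hi or b_lo >= b_hi:
        raise ValueError("empty landscape range")
    a = np.linspace(a_lo, a_hi, resolution)
    b = np.linspace(b_lo, b_hi, resolution)
    errs = np.empty((resolution, resolution))
    for i, ai in enumerate(a):
        for j, bj in enumerate(b):
            errs[i, j] = model.result((ai, bj), frame_name)
    return a, b, errs
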