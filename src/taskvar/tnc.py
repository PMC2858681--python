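"""Tolerance-Noise-Covariation (TNC) decomposition of performance variability.

TNC analysis evaluates execution variability *in result space*: every cost is
"observed mean error minus the mean error after an idealized improvement of
the data cloud", so all three are non-negative and expressed in result units.

* **Tolerance cost** — rigidly translate the whole cloud over a grid of
  execution-space locations and keep the best; measures whether performance
  sits in an error-tolerant region.
* **Noise cost** — shrink the cloud uniformly toward its mean by a scale
  factor s in [0, 1]; measures how much random dispersion costs.
* **Covariation cost** — re-pair coordinate values across trials (preserving
  every marginal distribution); measures how much better the existing
  marginals could have been combined.  The exact optimum is a linear
  assignment problem; a seeded swap heuristic covers large N.
* **Revised covariation cost** — covariation re-evaluated after rotating
  execution coordinates so that a straight-line fit to the solution manifold
  (within the central mass of the data) runs diagonally; removes the plain
  C cost's blindness to axis-parallel manifolds.

Build a :class:`TNC` model from an :class:`~taskvar.core.ExecutionSet` and a
:class:`~taskvar.core.ResultFunction` and call :meth:`TNC.fit`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from warnings import warn

import numpy as np
from scipy.optimize import linear_sum_assignment, minimize

from .core import ExecutionSet, ResultFunction, SolutionManifold
from .frames import CoordinateFrame, linear_transform

__all__ = [
    "TNC",
    "TNCResults",
    "tolerance_cost",
    "noise_cost",
    "covariation_cost",
    "revised_covariation_cost",
]


# ---------------------------------------------------------------------------
# individual costs


def _translated_objective(dev: np.ndarray, f: ResultFunction):
    """Mean result of the cloud translated so its mean sits at g."""

    def obj(g: np.ndarray) -> float:
        return float(f.batch(dev + np.asarray(g, dtype=float)).mean())

    return obj


def default_tolerance_grid(data: np.ndarray, resolution: int = 101, inflate: float = 3.0):
    """Bounding box of the data inflated about its center, per axis."""
    lo, hi = data.min(axis=0), data.max(axis=0)
    center, half = (lo + hi) / 2.0, (hi - lo) / 2.0
    half = np.where(half > 0, half, 1e-6) * inflate
    return [
        np.linspace(c - h, c + h, resolution) for c, h in zip(center, half)
    ]


def tolerance_cost(
    data: ExecutionSet,
    f: ResultFunction,
    grid: list[np.ndarray] | None = None,
    resolution: int = 101,
    polish: bool = True,
) -> tuple[float, np.ndarray]:
    """(T cost, optimal shift of the cloud mean).

    The cloud is rigidly translated so its mean visits every node of a
    rectangular grid (default: the data's bounding box inflated x3, 101 nodes
    per axis); the original mean location is always included as a candidate,
    so the cost is never negative.  With ``polish`` the best node is refined
    by a derivative-free local minimization, which makes the reported minimum
    independent of the grid placement (and hence invariant under linear
    re-coordinatizations applied jointly to data and result function).
    Ties between nodes are broken by the smallest shift norm.
    """
    rows = data.data
    mean = rows.mean(axis=0)
    dev = rows - mean
    obj = _translated_objective(dev, f)
    original = obj(mean)

    if grid is None:
        grid = default_tolerance_grid(rows, resolution=resolution)
    axes = [np.asarray(a, dtype=float) for a in grid]
    covered = all(a.min() <= m <= a.max() for a, m in zip(axes, mean))
    if not covered:
        warn("tolerance grid does not cover the original mean; "
             "T cost may be biased")
    mesh = np.meshgrid(*axes, indexing="ij")
    nodes = np.stack([m.ravel() for m in mesh], axis=1)  # (G, n)

    # mean result per node, vectorized: evaluate f on every translated point
    n_nodes, n_trials = nodes.shape[0], rows.shape[0]
    pts = nodes[:, None, :] + dev[None, :, :]
    vals = f.batch(pts.reshape(n_nodes * n_trials, -1)).reshape(n_nodes, n_trials)
    node_means = vals.mean(axis=1)

    best_val = float(node_means.min())
    winners = np.flatnonzero(node_means <= best_val + 1e-15)
    shifts = nodes[winners] - mean
    best_g = nodes[winners[np.argmin(np.linalg.norm(shifts, axis=1))]]

    if polish:
        res = minimize(
            obj, best_g, method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 4000,
                     "maxfev": 8000},
        )
        if res.fun < best_val:
            best_val, best_g = float(res.fun), np.asarray(res.x)

    if original < best_val:  # identity translation always admissible
        best_val, best_g = original, mean
    return original - best_val, best_g - mean


def noise_cost(
    data: ExecutionSet,
    f: ResultFunction,
    steps: np.ndarray | None = None,
) -> tuple[float, float]:
    """(N cost, optimal shrink scale).

    The cloud is contracted toward its mean, z_i(s) = mean + s (z_i - mean),
    for s on a grid from 1 down to 0 (default step 0.01).  s = 1 is the
    identity, so the cost is non-negative.  Ties prefer the largest s (the
    mildest shrink).
    """
    if steps is None:
        steps = np.linspace(1.0, 0.0, 101)
    steps = np.asarray(steps, dtype=float)
    rows = data.data
    mean = rows.mean(axis=0)
    dev = rows - mean
    pts = mean + steps[:, None, None] * dev[None, :, :]
    vals = f.batch(pts.reshape(-1, rows.shape[1])).reshape(len(steps), -1)
    means = vals.mean(axis=1)
    i0 = int(np.argmin(np.abs(steps - 1.0)))
    original = float(means[i0])
    best = int(np.argmin(means))
    if means[best] >= original:
        return 0.0, 1.0
    return original - float(means[best]), float(steps[best])


def _assignment_cost_matrix(
    rows: np.ndarray, f: ResultFunction, column: int
) -> np.ndarray:
    """C[i, j] = f(row_i with ``column`` replaced by row_j's value)."""
    n = rows.shape[0]
    rep = np.repeat(rows, n, axis=0)
    rep[:, column] = np.tile(rows[:, column], n)
    return f.batch(rep).reshape(n, n)


def covariation_cost(
    data: ExecutionSet,
    f: ResultFunction,
    method: str = "exact",
    seed: int | None = None,
    exact_cap: int = 500,
    heuristic_iters: int = 20000,
) -> tuple[float, np.ndarray]:
    """(C cost, optimal pairing of column 2 against column 1).

    Re-pairings permute one column's values against the others, leaving every
    marginal distribution untouched.  For 2-D execution spaces the exact
    optimum is the linear assignment problem on C[i, j] = f(x_i, y_j)
    (identity permutation included, so the cost is non-negative).  ``method=
    'swap'`` runs a seeded random-swap hill-climb instead (for N beyond
    ``exact_cap``).  For more than two execution dimensions the exact method
    cycles column-wise assignments to convergence and is approximate.
    """
    rows = data.data
    n, dim = rows.shape
    original = float(f.batch(rows).mean())

    if method == "exact" and n > exact_cap:
        raise ValueError(
            f"N = {n} exceeds the exact-assignment cap ({exact_cap}); "
            "use method='swap'"
        )

    if method == "exact":
        if dim == 2:
            C = _assignment_cost_matrix(rows, f, column=1)
            r_ind, c_ind = linear_sum_assignment(C)
            best = float(C[r_ind, c_ind].mean())
            perm = c_ind
        else:
            # coordinate-wise cycling; approximate beyond 2-D
            perm_rows = rows.copy()
            perms = [np.arange(n) for _ in range(dim)]
            for _ in range(20):
                improved = False
                for col in range(1, dim):
                    C = _assignment_cost_matrix(perm_rows, f, column=col)
                    r_ind, c_ind = linear_sum_assignment(C)
                    new = float(C[r_ind, c_ind].mean())
                    cur = float(f.batch(perm_rows).mean())
                    if new < cur - 1e-15:
                        perm_rows[:, col] = perm_rows[c_ind, col]
                        perms[col] = perms[col][c_ind]
                        improved = True
                if not improved:
                    break
            best = float(f.batch(perm_rows).mean())
            perm = perms[1]
    elif method == "swap":
        rng = np.random.default_rng(seed)
        perm = np.arange(n)
        work = rows.copy()
        vals = f.batch(work)
        total = vals.sum()
        for _ in range(heuristic_iters):
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            cand = work[[i, j]].copy()
            cand[[0, 1], 1] = cand[[1, 0], 1]
            new_vals = f.batch(cand)
            delta = new_vals.sum() - vals[i] - vals[j]
            if delta < 0:
                work[[i, j], 1] = work[[j, i], 1]
                perm[[i, j]] = perm[[j, i]]
                vals[i], vals[j] = new_vals
                total += delta
        best = float(total / n)
    else:
        raise ValueError("method must be 'exact' or 'swap'")

    if best > original:
        best, perm = original, np.arange(n)
    return original - best, perm


def brute_force_covariation(
    rows: np.ndarray, f: ResultFunction
) -> tuple[float, np.ndarray]:
    """Exhaustive search over all N! pairings of column 2 (oracle; N <= ~8)."""
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[0]
    best_mean, best_perm = np.inf, None
    for perm in permutations(range(n)):
        cand = rows.copy()
        cand[:, 1] = rows[list(perm), 1]
        m = float(f.batch(cand).mean())
        if m < best_mean - 1e-15:
            best_mean, best_perm = m, np.asarray(perm)
    return best_mean, best_perm


def _tls_direction(points: np.ndarray) -> float:
    """Angle of the total-least-squares line through a point set, in
    (-pi/2, pi/2]."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d = vt[0]
    ang = float(np.arctan2(d[1], d[0]))
    if ang <= -np.pi / 2:
        ang += np.pi
    elif ang > np.pi / 2:
        ang -= np.pi
    return ang


def revised_covariation_cost(
    data: ExecutionSet,
    f: ResultFunction,
    manifold: SolutionManifold,
    coverage: float = 0.95,
    method: str = "exact",
    seed: int | None = None,
) -> tuple[float, float]:
    """(revised C cost, rotation angle applied, rad).

    Procedure: (1) bound the central ``coverage`` of each marginal by a
    rectangle; (2) fit a total-least-squares line to the manifold vertices
    inside it; (3) rotate execution coordinates so the fitted line runs at
    45 degrees; (4) recompute the covariation cost in the rotated frame.
    The extra step stops an axis-parallel manifold from hiding covariation
    structure, and makes the measure insensitive to the initial rotation of
    the coordinates whenever the manifold is close to straight.
    """
    if not 0.0 < coverage <= 1.0:
        raise ValueError("coverage must be in (0, 1]")
    rows = data.data
    qlo, qhi = (1.0 - coverage) / 2.0, 1.0 - (1.0 - coverage) / 2.0
    lo = np.quantile(rows, qlo, axis=0)
    hi = np.quantile(rows, qhi, axis=0)
    v = manifold.vertices
    inside = np.all((v >= lo) & (v <= hi), axis=1)
    if inside.sum() < 3:
        raise ValueError(
            "fewer than 3 solution-manifold vertices fall inside the data "
            "rectangle; the manifold is not local to the data"
        )
    alpha = _tls_direction(v[inside])
    psi = np.pi / 4.0 - alpha
    c, s = np.cos(psi), np.sin(psi)
    R = np.array([[c, -s], [s, c]])

    rot_frame = CoordinateFrame(
        data.frame.name + "_rot", ("u1", "u2"), data.frame.axis_units
    )
    t = linear_transform(data.frame, rot_frame, R)
    c_cost, _ = covariation_cost(
        data.transformed(t), f.reparametrized(t), method=method, seed=seed
    )
    return c_cost, float(psi)


# ---------------------------------------------------------------------------
# model / results


@dataclass
class TNCResults:
    """TNC costs in result units, with optima and optional bootstrap."""

    t_cost: float
    n_cost: float
    c_cost: float
    units: str
    frame_name: str
    optimal_shift: np.ndarray
    optimal_scale: float
    optimal_pairing: np.ndarray
    revised_c_cost: float | None = None
    rotation_angle: float | None = None
    mean_result: float = np.nan
    diagnostics: dict = field(default_factory=dict)
    bootstrap: dict | None = None

    def summary(self) -> str:
        u = self.units or "result units"
        lines = [
            "TNC decomposition",
            "-----------------",
            f"frame:           {self.frame_name}",
            f"mean result:     {self.mean_result:.6g} {u}",
            f"Tolerance cost:  {self.t_cost:.6g} {u}"
            f"  (optimal shift {np.array2string(self.optimal_shift, precision=4)})",
            f"Noise cost:      {self.n_cost:.6g} {u}"
            f"  (optimal scale {self.optimal_scale:.2f})",
            f"Covariation cost:{self.c_cost:.6g} {u}",
        ]
        if self.revised_c_cost is not None:
            lines.append(
                f"Revised C cost:  {self.revised_c_cost:.6g} {u}"
                f"  (rotation {np.degrees(self.rotation_angle):.1f} deg)"
            )
        if self.bootstrap is not None:
            lines.append("bootstrap (mean +/- SD over draws):")
            for k in ("t_cost", "n_cost", "c_cost"):
                b = self.bootstrap[k]
                lines.append(f"  {k}: {b['mean']:.6g} +/- {b['sd']:.6g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "frame": self.frame_name,
            "units": self.units,
            "mean_result": self.mean_result,
            "t_cost": self.t_cost,
            "n_cost": self.n_cost,
            "c_cost": self.c_cost,
            "optimal_shift": list(map(float, self.optimal_shift)),
            "optimal_scale": self.optimal_scale,
        }
        if self.revised_c_cost is not None:
            out["revised_c_cost"] = self.revised_c_cost
            out["rotation_angle_rad"] = self.rotation_angle
        if self.bootstrap is not None:
            out["bootstrap"] = {
                k: {kk: vv for kk, vv in v.items() if kk != "draws"}
                for k, v in self.bootstrap.items()
            }
        return out


class TNC:
    """TNC cost model for one execution dataset and its result function.

    Parameters
    ----------
    data : ExecutionSet
    result_function : ResultFunction in the same frame.
    manifold : SolutionManifold, optional
        Needed only for the revised covariation cost.
    """

    def __init__(
        self,
        data: ExecutionSet,
        result_function: ResultFunction,
        manifold: SolutionManifold | None = None,
    ):
        if result_function.frame.name != data.frame.name:
            raise ValueError(
                f"result function frame {result_function.frame.name!r} does "
                f"not match data frame {data.frame.name!r}"
            )
        self.data = data
        self.result_function = result_function
        self.manifold = manifold

    def fit(
        self,
        grid=None,
        grid_resolution: int = 101,
        noise_steps=None,
        c_method: str = "exact",
        revised: bool = False,
        coverage: float = 0.95,
        bootstrap: bool = False,
        k_draws: int = 100,
        n_per_draw: int = 100,
        seed: int | None = None,
        polish_tolerance: bool = True,
    ) -> TNCResults:
        f = self.result_function
        t, shift = tolerance_cost(
            self.data, f, grid=grid, resolution=grid_resolution,
            polish=polish_tolerance,
        )
        n_c, scale = noise_cost(self.data, f, steps=noise_steps)
        c, pairing = covariation_cost(self.data, f, method=c_method, seed=seed)
        res = TNCResults(
            t_cost=t,
            n_cost=n_c,
            c_cost=c,
            units=f.units,
            frame_name=self.data.frame.name,
            optimal_shift=shift,
            optimal_scale=scale,
            optimal_pairing=pairing,
            mean_result=f.mean_result(self.data),
        )
        if revised:
            if self.manifold is None:
                raise ValueError("revised covariation cost needs a solution manifold")
            rc, angle = revised_covariation_cost(
                self.data, f, self.manifold, coverage=coverage,
                method=c_method, seed=seed,
            )
            res.revised_c_cost, res.rotation_angle = rc, angle
        if bootstrap:
            res.bootstrap = self.bootstrap(
                k_draws=k_draws, n_per_draw=n_per_draw, seed=seed,
                grid=grid, grid_resolution=grid_resolution,
                noise_steps=noise_steps, c_method=c_method,
                polish_tolerance=polish_tolerance,
            )
        return res

    def bootstrap(
        self,
        k_draws: int = 100,
        n_per_draw: int = 100,
        seed: int | None = None,
        grid=None,
        grid_resolution: int = 41,
        noise_steps=None,
        c_method: str = "exact",
        polish_tolerance: bool = False,
    ) -> dict:
        """Resample trials with replacement and recompute all three costs.

        Returns per-cost draw arrays plus mean and SD, deterministic for a
        given seed.  Per-draw failures propagate with the draw index.
        """
        rng = np.random.default_rng(seed)
        draws: dict[str, list[float]] = {"t_cost": [], "n_cost": [], "c_cost": []}
        for d in range(k_draws):
            idx = rng.integers(0, self.data.n_trials, size=n_per_draw)
            sub = self.data.subset(idx)
            try:
                t, _ = tolerance_cost(
                    sub, self.result_function, grid=grid,
                    resolution=grid_resolution, polish=polish_tolerance,
                )
                n_c, _ = noise_cost(sub, self.result_function, steps=noise_steps)
                c, _ = covariation_cost(sub, self.result_function, method=c_method)
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(f"bootstrap draw {d} failed: {exc}") from exc
            draws["t_cost"].append(t)
            draws["n_cost"].append(n_c)
            draws["c_cost"].append(c)
        out = {}
        for k, v in draws.items():
            arr = np.asarray(v)
            out[k] = {
                "mean": float(arr.mean()),
                "sd": float(arr.std(ddof=1)),
                "se": float(arr.std(ddof=1) / np.sqrt(len(arr))),
                "draws": arr,
            }
        return out
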