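"""Uncontrolled-manifold (UCM) variance partition and covariance whitening.

The UCM method asks whether trial-to-trial variability of execution variables
is preferentially channelled along "do-not-matter" directions.  The result
function's Jacobian is evaluated at the mean execution point; deviations from
the mean are projected onto the Jacobian's nullspace (directions that leave
the result unchanged, to first order) and its orthogonal complement.  The
reported statistic is the ratio of per-degree-of-freedom variance parallel to
the nullspace over the variance orthogonal to it, in percent:

    ratio = 100 * (sum ||proj_null d_i||^2 / (d_null N))
                / (sum ||proj_orth d_i||^2 / (d_orth N))

A ratio well above 100% is conventionally read as evidence of skill.  The
ratio is, however, not invariant under linear re-coordinatizations of
execution space — quantifying that sensitivity is what this package is for.

The module follows the model/results idiom: build :class:`UCM` from an
:class:`~taskvar.core.ExecutionSet` and a result function (or an explicit
Jacobian callable), call :meth:`UCM.fit`, and read the partition, the
bootstrap distribution and :meth:`UCMResults.summary`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .core import ExecutionSet, ResultFunction

__all__ = ["UCM", "UCMResults", "WhiteningPipeline", "result_nullspace", "whiten"]


def result_nullspace(jacobian: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal bases of the nullspace and its orthogonal complement.

    Parameters
    ----------
    jacobian : (m, n) array with m < n, full row rank.

    Returns
    -------
    null_basis : (n, n-m) array, columns orthonormal, J @ v = 0.
    orth_basis : (n, m) array, columns orthonormal, spanning the row space.
    """
    J = np.atleast_2d(np.asarray(jacobian, dtype=float))
    m, n = J.shape
    if m >= n:
        raise ValueError("Jacobian must have fewer rows than columns (m < n)")
    rank = np.linalg.matrix_rank(J)
    if rank < m:
        raise ValueError(f"rank-deficient Jacobian: rank {rank} < {m} rows")
    # SVD: right singular vectors split row space / nullspace
    _, _, vt = np.linalg.svd(J)
    orth = vt[:m].T
    null = vt[m:].T
    return null, orth


@dataclass
class UCMResults:
    """Variance partition plus (optionally) its bootstrap distribution."""

    v_parallel: float
    v_orthogonal: float
    d_null: int
    d_orth: int
    mean_point: np.ndarray
    nullspace_basis: np.ndarray
    orth_basis: np.ndarray
    infinite: bool = False
    frame_name: str = ""
    boot_ratios: np.ndarray | None = None
    boot_excluded: int = 0

    @property
    def ratio_percent(self) -> float:
        """100 * Vpar / Vorth per degree of freedom; inf when Vorth = 0."""
        if self.v_orthogonal == 0.0:
            return np.inf
        return 100.0 * self.v_parallel / self.v_orthogonal

    @property
    def boot_mean(self) -> float | None:
        if self.boot_ratios is None:
            return None
        return float(np.mean(self.boot_ratios))

    @property
    def boot_se(self) -> float | None:
        """Standard error of the bootstrap ratios: SD / sqrt(k)."""
        if self.boot_ratios is None:
            return None
        k = len(self.boot_ratios)
        return float(np.std(self.boot_ratios, ddof=1) / np.sqrt(k))

    def summary(self) -> str:
        lines = [
            "UCM variance partition",
            "----------------------",
            f"frame:            {self.frame_name}",
            f"trials mean:      {np.array2string(self.mean_point, precision=6)}",
            f"V_parallel/DOF:   {self.v_parallel:.6g}  (d_null = {self.d_null})",
            f"V_orthogonal/DOF: {self.v_orthogonal:.6g}  (d_orth = {self.d_orth})",
            f"ratio:            {self.ratio_percent:.1f} %"
            + ("  [orthogonal variance is zero]" if self.infinite else ""),
        ]
        if self.boot_ratios is not None:
            lines += [
                f"bootstrap:        {self.boot_mean:.1f} +/- {self.boot_se:.1f} % "
                f"(k = {len(self.boot_ratios)} draws"
                + (f", {self.boot_excluded} excluded" if self.boot_excluded else "")
                + ")",
            ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        out = {
            "frame": self.frame_name,
            "v_parallel": self.v_parallel,
            "v_orthogonal": self.v_orthogonal,
            "ratio_percent": self.ratio_percent,
            "d_null": self.d_null,
            "d_orth": self.d_orth,
            "infinite": self.infinite,
        }
        if self.boot_ratios is not None:
            out["bootstrap"] = {
                "mean": self.boot_mean,
                "se": self.boot_se,
                "draws": list(map(float, self.boot_ratios)),
                "excluded": self.boot_excluded,
            }
        return out


class UCM:
    """UCM variance-partition model for one execution dataset.

    Parameters
    ----------
    data : ExecutionSet
        Trials in some execution frame.
    result_function : ResultFunction, optional
        Task result function in the same frame; its gradient (analytic if
        available, else central differences) is evaluated at the sample mean.
    jacobian : callable, optional
        Alternative to ``result_function``: point -> (m, n) Jacobian.
    """

    def __init__(
        self,
        data: ExecutionSet,
        result_function: ResultFunction | None = None,
        jacobian: Callable[[np.ndarray], np.ndarray] | None = None,
    ):
        if (result_function is None) == (jacobian is None):
            raise ValueError("provide exactly one of result_function or jacobian")
        if result_function is not None and result_function.frame.name != data.frame.name:
            raise ValueError(
                f"result function frame {result_function.frame.name!r} does not "
                f"match data frame {data.frame.name!r}"
            )
        self.data = data
        self.result_function = result_function
        self._jacobian = jacobian

    def jacobian_at(self, point: np.ndarray) -> np.ndarray:
        if self._jacobian is not None:
            return np.atleast_2d(np.asarray(self._jacobian(point), dtype=float))
        f = self.result_function
        if f.gradient is not None:
            return np.atleast_2d(np.asarray(f.gradient(point), dtype=float))
        # central differences on the signed form when available, else on |f|
        g = f.signed if f.signed is not None else f.evaluate
        point = np.asarray(point, dtype=float)
        out = np.empty(point.size)
        for j in range(point.size):
            h = 1e-6 * (1.0 + abs(point[j]))
            e = np.zeros(point.size)
            e[j] = h
            out[j] = (g(point + e) - g(point - e)) / (2.0 * h)
        return np.atleast_2d(out)

    def _partition(self, rows: np.ndarray) -> UCMResults:
        mean = rows.mean(axis=0)
        J = self.jacobian_at(mean)
        null, orth = result_nullspace(J)
        dev = rows - mean
        n_trials = rows.shape[0]
        # per-DOF variance of projections; N (not N-1) normalization
        v_par = float(np.sum((dev @ null) ** 2) / (null.shape[1] * n_trials))
        v_orth = float(np.sum((dev @ orth) ** 2) / (orth.shape[1] * n_trials))
        return UCMResults(
            v_parallel=v_par,
            v_orthogonal=v_orth,
            d_null=null.shape[1],
            d_orth=orth.shape[1],
            mean_point=mean,
            nullspace_basis=null,
            orth_basis=orth,
            infinite=(v_orth == 0.0),
            frame_name=self.data.frame.name,
        )

    def fit(
        self,
        bootstrap: bool = False,
        k_draws: int = 10,
        n_per_draw: int = 100,
        seed: int | None = None,
    ) -> UCMResults:
        """Partition the variance; optionally bootstrap the ratio.

        The bootstrap draws ``k_draws`` samples of ``n_per_draw`` trials with
        replacement and recomputes the full partition (Jacobian at each
        draw's own mean) per draw.  Draws with zero orthogonal variance are
        flagged and excluded from the bootstrap mean.
        """
        res = self._partition(self.data.data)
        if bootstrap:
            if k_draws < 2:
                raise ValueError("k_draws must be at least 2")
            if np.allclose(self.data.data, self.data.data[0]):
                raise ValueError("degenerate data: zero variance, cannot bootstrap")
            rng = np.random.default_rng(seed)
            ratios = []
            excluded = 0
            for _ in range(k_draws):
                idx = rng.integers(0, self.data.n_trials, size=n_per_draw)
                r = self._partition(self.data.data[idx])
                if r.infinite:
                    excluded += 1
                    continue
                ratios.append(r.ratio_percent)
            res.boot_ratios = np.asarray(ratios)
            res.boot_excluded = excluded
        return res


@dataclass
class WhiteningPipeline:
    """Shift -> rotate -> rescale factors that isotropize a dataset.

    ``apply`` maps source-frame points p to scaling @ rotation @ (p - shift);
    after it, the sample covariance is the identity.
    """

    shift: np.ndarray
    rotation: np.ndarray
    scaling: np.ndarray  # diagonal matrix

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return (points - self.shift) @ self.rotation.T @ self.scaling.T

    def matrix(self) -> np.ndarray:
        """The combined linear part (scaling @ rotation)."""
        return self.scaling @ self.rotation


def whiten(data: ExecutionSet) -> tuple[ExecutionSet, WhiteningPipeline]:
    """Center, rotate to principal axes, and rescale to unit variance.

    The covariance eigendecomposition is sorted by descending eigenvalue and
    each eigenvector's first nonzero component is made positive (a
    deterministic sign convention).  Output sample covariance is the identity
    to 1e-8.

    Raises
    ------
    ValueError
        If the sample covariance is singular (advice: reduce dimensions).
    """
    rows = data.data
    shift = rows.mean(axis=0)
    cov = np.cov(rows, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if np.min(evals) <= np.max(evals) * 1e-12 or np.min(evals) <= 0:
        raise ValueError(
            "singular sample covariance; reduce the dimensionality before whitening"
        )
    for j in range(evecs.shape[1]):
        nz = np.flatnonzero(np.abs(evecs[:, j]) > 1e-12)
        if nz.size and evecs[nz[0], j] < 0:
            evecs[:, j] = -evecs[:, j]
    rotation = evecs.T
    scaling = np.diag(1.0 / np.sqrt(evals))
    pipe = WhiteningPipeline(shift=shift, rotation=rotation, scaling=scaling)
    from .frames import CoordinateFrame

    out_frame = CoordinateFrame(
        data.frame.name + "_whitened",
        tuple(f"w{i + 1}" for i in range(data.dim)),
        ("1",) * data.dim,
    )
    out = ExecutionSet(pipe.apply(rows), out_frame, trial_ids=data.trial_ids,
                       labels=data.labels)
    return out, pipe
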