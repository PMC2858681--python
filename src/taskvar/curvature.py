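"""Curvature of the result function along the solution manifold.

The result landscape is a surface over execution space whose valley bottom is
the solution manifold.  Its local shape is captured by the Hessian of the
result function; the eigenvalues of the Hessian, corrected by the surface
normalization factor involving the gradient, are the principal curvatures.
Because the error is zero exactly on the manifold and positive elsewhere, on
the manifold the smallest principal curvature vanishes and the largest is
non-negative — so the Gaussian curvature (their product) is identically zero
along the manifold, in *any* execution coordinates.  What varies along the
manifold is only the largest curvature: the "width of the valley", i.e. the
local error tolerance.

Curvature is evaluated on the squared-error form of the result function.
The raw closest-approach error behaves like |.| across the manifold and is
not twice differentiable at the bottom; squaring preserves the zero set and
restores smoothness.  Reported curvatures are therefore those of the squared
surface (1/result-units scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable
from warnings import warn

import numpy as np

from .core import ResultFunction, SolutionManifold

__all__ = [
    "numerical_hessian",
    "principal_curvatures",
    "gaussian_curvature_profile",
    "CurvatureReport",
]


def _squared_form(f: ResultFunction) -> Callable[[np.ndarray], float]:
    base = f.signed if f.signed is not None else f.evaluate
    return lambda p: float(base(np.asarray(p, dtype=float))) ** 2


def numerical_hessian(
    func: Callable[[np.ndarray], float], at, step: float = 1e-3
) -> np.ndarray:
    """Symmetric central-difference Hessian of a scalar function.

    Mixed partials are averaged over both difference orders; the result is
    exactly symmetric.  Raises if any stencil sample is non-finite.
    """
    at = np.asarray(at, dtype=float)
    n = at.size
    H = np.empty((n, n))
    f0 = func(at)

    def ev(p: np.ndarray) -> float:
        v = func(p)
        if not np.isfinite(v):
            raise ValueError("non-finite sample in Hessian stencil")
        return v

    for i in range(n):
        ei = np.zeros(n)
        ei[i] = step
        H[i, i] = (ev(at + ei) - 2.0 * f0 + ev(at - ei)) / step**2
        for j in range(i + 1, n):
            ej = np.zeros(n)
            ej[j] = step
            mixed = (
                ev(at + ei + ej)
                - ev(at + ei - ej)
                - ev(at - ei + ej)
                + ev(at - ei - ej)
            ) / (4.0 * step**2)
            H[i, j] = H[j, i] = mixed
    return 0.5 * (H + H.T)


def _numerical_gradient(
    func: Callable[[np.ndarray], float], at: np.ndarray, step: float
) -> np.ndarray:
    n = at.size
    g = np.empty(n)
    for i in range(n):
        e = np.zeros(n)
        e[i] = step
        g[i] = (func(at + e) - func(at - e)) / (2.0 * step)
    return g


def principal_curvatures(
    hessian: np.ndarray, gradient: np.ndarray | None = None
) -> tuple[float, float]:
    """(kappa_min, kappa_max) of the surface z = f(x) from Hessian and gradient.

    The Hessian eigenvalues are normalized by (1 + |grad f|^2)^(3/2), the
    surface correction that reduces to the plane-curve curvature formula in
    one dimension.  On the solution manifold the gradient of the squared
    error vanishes, so the factor is 1 and the raw eigenvalues are returned.
    """
    H = np.asarray(hessian, dtype=float)
    if not np.allclose(H, H.T, atol=1e-8):
        raise ValueError("Hessian must be symmetric")
    evals = np.linalg.eigvalsh(H)
    if gradient is not None:
        g2 = float(np.asarray(gradient) @ np.asarray(gradient))
        evals = evals / (1.0 + g2) ** 1.5
    return float(evals[0]), float(evals[-1])


@dataclass
class CurvatureReport:
    """Per-vertex principal and Gaussian curvatures along a manifold."""

    points: np.ndarray
    kappa_min: np.ndarray
    kappa_max: np.ndarray
    step: float
    skipped: int = 0

    @property
    def gaussian(self) -> np.ndarray:
        return self.kappa_min * self.kappa_max

    @property
    def max_abs_gaussian(self) -> float:
        return float(np.max(np.abs(self.gaussian)))

    def summary(self) -> str:
        return "\n".join(
            [
                "Curvature along the solution manifold (squared-error surface)",
                f"vertices:          {len(self.kappa_min)}"
                + (f"  ({self.skipped} skipped)" if self.skipped else ""),
                f"fd step:           {self.step:g}",
                f"max |gaussian|:    {self.max_abs_gaussian:.3e}",
                f"max |kappa_min|:   {float(np.max(np.abs(self.kappa_min))):.3e}",
                f"kappa_max range:   [{float(self.kappa_max.min()):.4g}, "
                f"{float(self.kappa_max.max()):.4g}]",
            ]
        )


def gaussian_curvature_profile(
    f: ResultFunction,
    manifold: SolutionManifold,
    step: float = 1e-3,
    on_manifold_tol: float = 1e-6,
) -> CurvatureReport:
    """Principal/Gaussian curvature of the squared-error surface per vertex.

    Vertices whose error exceeds ``on_manifold_tol`` are skipped with a
    warning.  The kappa_max profile is the local "valley width" along the
    manifold; max |kappa_min * kappa_max| quantifies how close the Gaussian
    curvature is to its theoretical value of zero.
    """
    sq = _squared_form(f)
    pts, kmin, kmax = [], [], []
    skipped = 0
    for v in np.atleast_2d(manifold.vertices):
        if f(v) > on_manifold_tol:
            skipped += 1
            continue
        H = numerical_hessian(sq, v, step=step)
        g = _numerical_gradient(sq, v, step)
        lo, hi = principal_curvatures(H, g)
        pts.append(v)
        kmin.append(lo)
        kmax.append(hi)
    if skipped:
        warn(f"{skipped} vertices failed the on-manifold check and were skipped")
    return CurvatureReport(
        points=np.asarray(pts),
        kappa_min=np.asarray(kmin),
        kappa_max=np.asarray(kmax),
        step=step,
        skipped=skipped,
    )
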