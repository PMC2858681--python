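"""Seeded synthetic datasets for every analysis in the package.

No public dataset exists for the tasks studied here, so the generators below
emulate the study conditions directly:

* :func:`generate_reaching_dataset` — an isotropic bivariate Gaussian hand
  scatter centered on the target line (500 trials by default), expressed
  simultaneously in hand coordinates, absolute joint angles and relative
  joint angles.  This is the dataset on which the UCM ratio flips between
  ~100% and a much larger value purely through the angle convention.
* :func:`generate_alignment_case` — schematic clouds plus a linear result
  function |a x + b y - c| with an axis-parallel or diagonal solution
  manifold and a data distribution misaligned / unaligned / aligned with it;
  the cases that expose the covariation cost's rotation sensitivity.
* :func:`generate_skittles_sessions` — multi-day practice data for the
  skittles task with shrinking dispersion, mean drift toward the solution
  manifold, and growing alignment with the local manifold tangent, in polar
  coordinates with exact Cartesian twins.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ExecutionSet, ResultFunction
from .frames import (
    ABSOLUTE_ANGLES,
    CARTESIAN_RELEASE,
    HAND_SPACE,
    POLAR_RELEASE,
    RELATIVE_ANGLES,
    CoordinateFrame,
    relative_from_absolute,
)
from .reaching import (
    OutOfWorkspaceError,
    ReachingTask,
    forward_kinematics,
    inverse_kinematics,
)
from .skittles import SkittlesModel

__all__ = [
    "ReachingScenario",
    "generate_reaching_dataset",
    "generate_alignment_case",
    "PracticeSchedule",
    "generate_skittles_sessions",
]


@dataclass
class ReachingScenario:
    """The line-pointing simulation scenario.

    The hand scatter is an isotropic bivariate Gaussian of SD ``sigma``
    (metres) whose mean — the hand point of ``mean_posture`` — lies on the
    target line.  The magnitude of sigma is not critical: the UCM ratio and
    the relative sizes of the TNC costs across frames do not depend on it.
    """

    task: ReachingTask = field(default_factory=ReachingTask.default)
    mean_posture: tuple[float, float] = (
        np.deg2rad(135.0),
        np.deg2rad(45.0),
    )  # absolute angles
    sigma: float = 0.01
    n: int = 500
    seed: int | None = None
    elbow_branch: str = "down"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        hand = forward_kinematics(self.mean_posture, self.task.arm)
        if abs(self.task.line.signed_distance(hand)) > 1e-9:
            raise ValueError("mean posture's hand point must lie on the target line")


def generate_reaching_dataset(
    scenario: ReachingScenario | None = None,
) -> dict[str, ExecutionSet]:
    """Linked trial sets in hand space, absolute angles, and relative angles.

    Hand samples falling outside the arm's reachable annulus (or inside a
    thin guard band at its edge, where the inverse kinematics is
    ill-conditioned) are re-drawn so that n stays fixed; the count of
    re-draws is attached as ``.resampled`` on the returned dict.
    """
    sc = scenario or ReachingScenario()
    arm = sc.task.arm
    rng = np.random.default_rng(sc.seed)
    center = forward_kinematics(sc.mean_posture, arm)

    r_max = arm.l1 + arm.l2
    r_min = abs(arm.l1 - arm.l2)
    guard = 1e-6 * r_max

    hands = np.empty((sc.n, 2))
    angles = np.empty((sc.n, 2))
    resampled = 0
    filled = 0
    while filled < sc.n:
        p = center + sc.sigma * rng.standard_normal(2)
        r = np.linalg.norm(p - np.asarray(arm.shoulder))
        if not (r_min + guard < r < r_max - guard):
            resampled += 1
            continue
        try:
            a = inverse_kinematics(p, arm, elbow_branch=sc.elbow_branch)
        except OutOfWorkspaceError:
            resampled += 1
            continue
        hands[filled] = p
        angles[filled] = a
        filled += 1

    rel = np.apply_along_axis(relative_from_absolute, 1, angles)
    out = {
        "hand": ExecutionSet(hands, HAND_SPACE),
        "absolute": ExecutionSet(angles, ABSOLUTE_ANGLES),
        "relative": ExecutionSet(rel, RELATIVE_ANGLES),
    }
    out["resampled"] = resampled
    return out


def generate_alignment_case(
    manifold_orientation: str = "diagonal",
    data_alignment: str = "misaligned",
    n: int = 100,
    seed: int | None = None,
    anisotropy: float = 3.0,
    sigma: float = 1.0,
    center: tuple[float, float] = (0.0, 0.0),
) -> tuple[ExecutionSet, ResultFunction]:
    """A schematic cloud plus the linear valley |a x + b y - c|.

    ``manifold_orientation`` is "axis-parallel" (valley along the x-axis,
    result |y - c|) or "diagonal" (valley along the (1, 1) direction).
    ``data_alignment`` orients the cloud's principal axis relative to the
    valley: "aligned", "none" (isotropic) or "misaligned" (perpendicular).
    """
    if manifold_orientation == "axis-parallel":
        a_vec = np.array([0.0, 1.0])  # manifold along x
        m_dir = np.array([1.0, 0.0])
    elif manifold_orientation == "diagonal":
        a_vec = np.array([1.0, -1.0]) / np.sqrt(2.0)  # manifold along (1,1)
        m_dir = np.array([1.0, 1.0]) / np.sqrt(2.0)
    else:
        raise ValueError("manifold_orientation must be 'axis-parallel' or 'diagonal'")
    if n < 10:
        raise ValueError("n must be at least 10")
    c_val = float(a_vec @ np.asarray(center, dtype=float))

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    if data_alignment == "none":
        cloud = sigma * z
    else:
        if data_alignment == "aligned":
            major = m_dir
        elif data_alignment == "misaligned":
            major = a_vec  # perpendicular to the manifold
        else:
            raise ValueError(
                "data_alignment must be 'aligned', 'none' or 'misaligned'"
            )
        minor = np.array([-major[1], major[0]])
        cloud = sigma * (
            np.outer(z[:, 0] * anisotropy, major) + np.outer(z[:, 1], minor)
        )
    cloud = cloud + np.asarray(center, dtype=float)

    frame = CoordinateFrame("plane", ("x", "y"), ("1", "1"))
    f = ResultFunction(
        frame=frame,
        evaluate=lambda p: abs(float(a_vec @ p) - c_val),
        units="1",
        signed=lambda p: float(a_vec @ p) - c_val,
        evaluate_batch=lambda rows: np.abs(np.atleast_2d(rows) @ a_vec - c_val),
    )
    return ExecutionSet(cloud, frame), f


@dataclass
class PracticeSchedule:
    """Qualitative trends of multi-day practice.

    Dispersions are per-day cloud SDs in polar execution units (the angle and
    angular-velocity axes are scaled by ``axis_scales`` before the
    tangent/normal decomposition so that one scalar dispersion is
    meaningful).  The mean drifts from an offset start toward an anchor on
    the solution manifold; the cloud's principal axis aligns progressively
    with the local manifold tangent.
    """

    days: int = 16
    trials_per_day: int = 180
    initial_dispersion: float = 0.12
    final_dispersion: float = 0.03
    start_frac: float = 0.2  # arc-length position on the manifold on day 1
    end_frac: float = 0.5  # position drifted to by the last day
    initial_normal_offset: float = 0.02  # initial mean offset off the manifold
    alignment_gain: float = 2.0  # tangent/normal SD ratio reached on the last day
    axis_scales: tuple[float, float] = (1.0, 5.0)  # rad per unit, rad/s per unit
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.days < 1 or self.trials_per_day < 2:
            raise ValueError("need at least 1 day and 2 trials per day")
        if not (0 < self.final_dispersion <= self.initial_dispersion):
            raise ValueError("dispersions must be positive and non-increasing")
        if self.alignment_gain < 1.0:
            raise ValueError("alignment_gain must be >= 1")


def generate_skittles_sessions(
    schedule: PracticeSchedule | None = None,
    model: SkittlesModel | None = None,
    ranges=None,
    manifold=None,
) -> tuple[list[ExecutionSet], list[ExecutionSet]]:
    """Daily execution sets in polar coordinates plus exact Cartesian twins.

    Day-by-day, the cloud SD decays geometrically from the initial to the
    final dispersion, the mean drifts along the solution manifold from the
    ``start_frac`` to the ``end_frac`` arc-length position (with an initial
    off-manifold offset that decays to zero), and the tangent-to-normal SD
    ratio grows linearly to ``alignment_gain``.  The Cartesian twin of each
    day is the per-trial release transform of the polar data, so both frames
    describe identical throws.

    ``manifold`` may be a precomputed polar-frame solution manifold of the
    model (to avoid re-extracting it).
    """
    schedule = schedule or PracticeSchedule()
    model = model or SkittlesModel()
    if manifold is None:
        manifold = model.solution_manifold("polar", ranges=ranges, n=41)
    if manifold.n_vertices < 3:
        raise ValueError("no solution manifold found for this model")
    scales = np.asarray(schedule.axis_scales, dtype=float)
    # order vertices into a polyline along the first execution axis
    verts = manifold.vertices[np.argsort(manifold.vertices[:, 0])] / scales
    seg = np.linalg.norm(np.diff(verts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])

    def along(frac_pos: float) -> tuple[np.ndarray, np.ndarray]:
        """Point and unit tangent at an arc-length fraction of the polyline."""
        s = frac_pos * arc[-1]
        i = int(np.clip(np.searchsorted(arc, s) - 1, 0, len(seg) - 1))
        w = (s - arc[i]) / seg[i] if seg[i] > 0 else 0.0
        point = (1.0 - w) * verts[i] + w * verts[i + 1]
        tan = (verts[i + 1] - verts[i]) / (seg[i] if seg[i] > 0 else 1.0)
        return point, tan

    if ranges is None:
        ranges = model.default_ranges("polar")
    (a_lo, a_hi), (b_lo, b_hi) = ranges

    rng = np.random.default_rng(schedule.seed)
    polar_days: list[ExecutionSet] = []
    cart_days: list[ExecutionSet] = []
    t = model.release_transform()
    for d in range(schedule.days):
        frac = d / max(schedule.days - 1, 1)
        pos_frac = (1.0 - frac) * schedule.start_frac + frac * schedule.end_frac
        point, tangent = along(pos_frac)
        normal = np.array([-tangent[1], tangent[0]])
        mean = point + (1.0 - frac) * schedule.initial_normal_offset * normal
        mean_raw = mean * scales
        if not (a_lo <= mean_raw[0] <= a_hi and b_lo <= mean_raw[1] <= b_hi):
            raise ValueError(
                f"day {d + 1} mean path leaves the configured execution range"
            )
        disp = schedule.initial_dispersion * (
            schedule.final_dispersion / schedule.initial_dispersion
        ) ** frac
        ratio = 1.0 + (schedule.alignment_gain - 1.0) * frac
        sd_t = disp * np.sqrt(ratio)
        sd_n = disp / np.sqrt(ratio)
        z = rng.standard_normal((schedule.trials_per_day, 2))
        cloud = mean + np.outer(z[:, 0] * sd_t, tangent) + np.outer(
            z[:, 1] * sd_n, normal
        )
        cloud_raw = cloud * scales
        day = np.full(schedule.trials_per_day, d + 1)
        polar = ExecutionSet(cloud_raw, POLAR_RELEASE, labels=day)
        polar_days.append(polar)
        cart_days.append(
            ExecutionSet(t.apply_rows(cloud_raw), CARTESIAN_RELEASE, labels=day)
        )
    return polar_days, cart_days
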