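"""Skittles physics, result function, landscape, and manifold equivariance."""

import numpy as np
import pytest

from taskvar import SkittlesModel, landscape_grid


class TestTrajectory:
    def test_initial_conditions(self, skittles_model, rng):
        for _ in range(10):
            theta = rng.uniform(0, np.pi)
            theta_dot = rng.uniform(0.5, 10.0)
            traj = skittles_model.trajectory_from_polar(theta, theta_dot)
            assert np.allclose(traj.position(0.0), traj.release_pos, atol=1e-12)
            assert np.allclose(traj.velocity(0.0), traj.release_vel, atol=1e-9)

    def test_undamped_orbit_is_periodic(self, skittles_model):
        traj = skittles_model.trajectory_from_polar(1.0, 4.0)
        T = skittles_model.period
        ts = np.linspace(0.0, T, 7)
        assert np.allclose(traj.position(ts), traj.position(ts + T), atol=1e-9)

    def test_release_at_rest_oscillates_on_a_line(self, skittles_model):
        traj = skittles_model.trajectory_from_polar(0.9, 0.0)
        r0 = traj.release_pos - np.asarray(skittles_model.post_center)
        ts = np.linspace(0.0, skittles_model.period, 40)
        rel = traj.position(ts) - np.asarray(skittles_model.post_center)
        cross = rel[:, 0] * r0[1] - rel[:, 1] * r0[0]
        assert np.max(np.abs(cross)) < 1e-12

    def test_energy_conservation(self, skittles_model, rng):
        w = skittles_model.omega
        post = np.asarray(skittles_model.post_center)
        for _ in range(10):
            traj = skittles_model.trajectory_from_polar(
                rng.uniform(0, np.pi), rng.uniform(0.5, 10)
            )
            ts = np.linspace(0, skittles_model.period, 50)
            E = (
                np.linalg.norm(traj.velocity(ts), axis=1) ** 2
                + w**2 * np.linalg.norm(traj.position(ts) - post, axis=1) ** 2
            )
            assert (E.max() - E.min()) / E.mean() < 1e-9

    def test_damped_orbit_decays(self):
        m = SkittlesModel(tau=2.0, horizon=1.0)
        traj = m.trajectory_from_polar(1.0, 4.0)
        post = np.asarray(m.post_center)
        r0 = np.linalg.norm(traj.position(0.0) - post)
        rT = np.linalg.norm(traj.position(5 * m.period) - post)
        assert rT < 0.1 * r0


class TestResult:
    def test_target_on_trajectory_gives_zero(self, skittles_model):
        base = skittles_model.trajectory_from_polar(np.deg2rad(60.0), 4.0)
        pt = base.position(0.4 * skittles_model.period)
        m = SkittlesModel(target=tuple(pt), post_radius=0.0)
        err = m.result((np.deg2rad(60.0), 4.0))
        assert err < 1e-8

    def test_frame_consistency_random_releases(self, skittles_model, rng):
        t = skittles_model.release_transform()
        worst = 0.0
        for _ in range(200):
            p = np.array(
                [rng.uniform(np.deg2rad(30), np.deg2rad(150)), rng.uniform(0.5, 12)]
            )
            v = t(p)
            worst = max(
                worst,
                abs(
                    skittles_model.result(p, "polar")
                    - skittles_model.result(v, "cartesian")
                ),
            )
        assert worst < 1e-9

    def test_collision_flagged_and_truncated(self, skittles_model):
        # a slow, nearly radial release toward the post must make contact
        found = False
        for theta_dot in np.linspace(0.5, 3.0, 10):
            err, t_best, collided = skittles_model.closest_approach(
                (np.deg2rad(66.0), theta_dot)
            )
            if collided:
                found = True
                traj = skittles_model.trajectory_from_polar(
                    np.deg2rad(66.0), theta_dot
                )
                post = np.asarray(skittles_model.post_center)
                d_at_best = np.linalg.norm(traj.position(t_best) - post)
                assert d_at_best >= skittles_model.post_radius - 1e-6
        assert found

    def test_batch_matches_scalar(self, skittles_model, rng):
        rows = np.column_stack(
            [
                rng.uniform(np.deg2rad(40), np.deg2rad(110), 60),
                rng.uniform(1.0, 12.0, 60),
            ]
        )
        b = skittles_model.result_batch(rows)
        s = np.array([skittles_model.result(r) for r in rows])
        assert np.max(np.abs(b - s)) < 1e-6


class TestLandscape:
    def test_grid_nonnegative_and_contains_valley(self, skittles_model):
        a, b, errs = landscape_grid(skittles_model, "polar", resolution=25)
        assert np.all(errs >= 0)
        assert errs.min() < 1e-2

    def test_frame_matched_points_equal_error(self, skittles_model, rng):
        t = skittles_model.release_transform()
        a, b, errs = landscape_grid(
            skittles_model, "polar",
            ranges=((np.deg2rad(55), np.deg2rad(70)), (2.0, 6.0)),
            resolution=5,
        )
        for i in range(5):
            for j in range(5):
                v = t(np.array([a[i], b[j]]))
                assert skittles_model.result(v, "cartesian") == pytest.approx(
                    errs[i, j], abs=1e-9
                )

    def test_empty_range_raises(self, skittles_model):
        with pytest.raises(ValueError):
            landscape_grid(skittles_model, "polar", ranges=((1.0, 1.0), (0, 1)))


class TestManifold:
    def test_vertices_are_zeros(self, polar_manifold, skittles_model):
        errs = [skittles_model.result(v, "polar") for v in polar_manifold.vertices]
        assert max(errs) < 1e-6

    def test_error_grows_off_manifold(self, polar_manifold, skittles_model):
        v = polar_manifold.vertices[len(polar_manifold.vertices) // 2]
        base = skittles_model.result(v, "polar")
        for eps in (1e-3, 3e-3, 1e-2):
            up = skittles_model.result(v + [0.0, eps], "polar")
            down = skittles_model.result(v - [0.0, eps], "polar")
            assert min(up, down) > base

    def test_cartesian_manifold_is_image_of_polar(
        self, polar_manifold, cartesian_manifold, skittles_model
    ):
        t = skittles_model.release_transform()
        mapped = polar_manifold.transformed(t).vertices
        for p in mapped:
            assert skittles_model.result(p, "cartesian") < 1e-6
        # the curves coincide on their overlapping span (symmetric Hausdorff)
        d = manifold_hausdorff(mapped, cartesian_manifold.vertices)
        assert d < 1e-3


def _chain(curve: np.ndarray) -> np.ndarray:
    """Order curve vertices into a polyline by greedy nearest-neighbor
    chaining from an extreme vertex (handles folds that interleave when
    sorted along one axis)."""
    start = int(np.argmax(curve[:, 1]))
    left = list(range(len(curve)))
    order = [start]
    left.remove(start)
    while left:
        last = curve[order[-1]]
        nxt = min(left, key=lambda i: np.linalg.norm(curve[i] - last))
        order.append(nxt)
        left.remove(nxt)
    return curve[order]


def _polyline_distances(points: np.ndarray, curve: np.ndarray) -> np.ndarray:
    """Distance from each point to the chained polyline through curve
    vertices.  Points closest to the polyline's free ends are skipped: the
    two curves cover slightly different arcs of the same zero set, so their
    ends need not correspond."""
    c = _chain(curve)
    seg = np.diff(c, axis=0)
    out = []
    for p in points:
        d_vert = np.linalg.norm(c - p, axis=1)
        best, at_end = float(d_vert.min()), d_vert.argmin() in (0, len(c) - 1)
        for i, (a, d) in enumerate(zip(c[:-1], seg)):
            t = float(np.clip(np.dot(p - a, d) / np.dot(d, d), 0.0, 1.0))
            dist = float(np.linalg.norm(a + t * d - p))
            if dist < best:
                best = dist
                at_end = (i == 0 and t == 0.0) or (i == len(seg) - 1 and t == 1.0)
        if not at_end:
            out.append(best)
    return np.asarray(out)


def manifold_hausdorff(curve_a: np.ndarray, curve_b: np.ndarray) -> float:
    """Symmetric Hausdorff distance between two sampled manifold curves,
    evaluated away from their free ends."""
    return float(
        max(
            np.max(_polyline_distances(curve_a, curve_b)),
            np.max(_polyline_distances(curve_b, curve_a)),
        )
    )
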