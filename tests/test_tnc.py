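"""Tolerance, noise, and covariation costs: hand examples, oracles,
invariances, and the bootstrap."""

import numpy as np
import pytest

from taskvar import (
    CoordinateFrame,
    ExecutionSet,
    ResultFunction,
    SolutionManifold,
    TNC,
    covariation_cost,
    generate_alignment_case,
    linear_transform,
    noise_cost,
    revised_covariation_cost,
    tolerance_cost,
)
from taskvar.tnc import brute_force_covariation

PLANE = CoordinateFrame("plane", ("x", "y"), ("1", "1"))


def linear_valley(a, b, c):
    """Result |a x + b y - c| with analytic batch evaluation."""
    v = np.array([a, b], dtype=float)
    return ResultFunction(
        frame=PLANE,
        evaluate=lambda p: abs(float(v @ p) - c),
        signed=lambda p: float(v @ p) - c,
        evaluate_batch=lambda rows: np.abs(np.atleast_2d(rows) @ v - c),
    )


class TestMeanResult:
    def test_single_trial_mean(self):
        f = linear_valley(0, 1, 0)
        assert f.mean_result(np.array([[2.0, 3.0], [2.0, 3.0]])) == 3.0

    def test_zero_on_manifold(self):
        f = linear_valley(1, -1, 0)
        data = np.array([[x, x] for x in np.linspace(-2, 2, 7)])
        assert f.mean_result(data) == 0.0

    def test_non_finite_row_named(self):
        f = ResultFunction(
            frame=PLANE,
            evaluate=lambda p: np.nan if p[0] > 0 else 1.0,
            evaluate_batch=lambda rows: np.where(rows[:, 0] > 0, np.nan, 1.0),
        )
        with pytest.raises(ValueError, match="row 1"):
            f.mean_result(np.array([[-1.0, 0.0], [1.0, 0.0]]))


class TestToleranceCost:
    def test_zero_when_already_optimal(self):
        f = linear_valley(0, 1, 0)
        data = ExecutionSet([[0.0, 1.0], [0.0, -1.0]], PLANE)
        t, _ = tolerance_cost(data, f)
        assert t == pytest.approx(0.0, abs=1e-12)

    def test_cloud_parallel_to_valley(self):
        # both trials at the same height: shifting onto the valley removes
        # the entire mean error
        f = linear_valley(0, 1, 0)
        data = ExecutionSet([[0.0, 0.7], [1.0, 0.7]], PLANE)
        t, shift = tolerance_cost(data, f)
        assert t == pytest.approx(0.7, abs=1e-9)
        assert shift[1] == pytest.approx(-0.7, abs=1e-6)

    def test_grid_not_covering_mean_warns(self):
        f = linear_valley(0, 1, 0)
        data = ExecutionSet([[0.0, 5.0], [1.0, 5.0]], PLANE)
        grid = [np.linspace(10, 11, 5), np.linspace(10, 11, 5)]
        with pytest.warns(UserWarning, match="grid"):
            tolerance_cost(data, f, grid=grid, polish=False)

    def test_matches_independent_grid_oracle(self, rng):
        """Same grid, independently looped oracle: identical cost."""
        for _ in range(10):
            pts = rng.normal(size=(2, 2)) * 2.0
            a, b = rng.normal(size=2)
            f = linear_valley(a, b, rng.normal())
            data = ExecutionSet(pts, PLANE)
            grid = [np.linspace(-6, 6, 41), np.linspace(-6, 6, 41)]
            t, _ = tolerance_cost(data, f, grid=grid, polish=False)
            # oracle: exhaustive loops, no vectorization shared with the impl
            mean = pts.mean(axis=0)
            dev = pts - mean
            orig = np.mean([f(p) for p in pts])
            best = orig
            for gx in grid[0]:
                for gy in grid[1]:
                    m = np.mean([f(d + [gx, gy]) for d in dev])
                    best = min(best, m)
            assert t == pytest.approx(orig - best, abs=1e-12)

    def test_invariant_under_linear_reparametrization(self, rng):
        data, f = generate_alignment_case("diagonal", "misaligned", n=60, seed=2)
        t0, _ = tolerance_cost(data, f)
        for k in range(5):
            M = rng.normal(size=(2, 2)) + 2 * np.eye(2)
            tgt = CoordinateFrame(f"lin{k}", ("u", "v"), ("1", "1"))
            t = linear_transform(data.frame, tgt, M, rng.normal(size=2))
            t1, _ = tolerance_cost(data.transformed(t), f.reparametrized(t))
            assert t1 == pytest.approx(t0, abs=1e-9)


class TestNoiseCost:
    def test_zero_variance_cloud(self):
        f = linear_valley(0, 1, 0)
        data = ExecutionSet([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]], PLANE)
        n, s = noise_cost(data, f)
        assert n == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_pair_full_shrink(self):
        f = linear_valley(0, 1, 0)
        data = ExecutionSet([[0.0, 1.0], [0.0, -1.0]], PLANE)
        n, s = noise_cost(data, f)
        assert n == pytest.approx(1.0, abs=1e-12)
        assert s == pytest.approx(0.0, abs=1e-12)

    def test_invariant_under_linear_reparametrization(self, rng):
        data, f = generate_alignment_case("diagonal", "none", n=60, seed=3)
        n0, _ = noise_cost(data, f)
        for k in range(5):
            M = rng.normal(size=(2, 2)) + 2 * np.eye(2)
            tgt = CoordinateFrame(f"nlin{k}", ("u", "v"), ("1", "1"))
            t = linear_transform(data.frame, tgt, M, rng.normal(size=2))
            n1, _ = noise_cost(data.transformed(t), f.reparametrized(t))
            assert n1 == pytest.approx(n0, abs=1e-9)


class TestCovariationCost:
    def test_axis_parallel_valley_zero(self, rng):
        f = linear_valley(0, 1, 0.3)
        data = ExecutionSet(rng.normal(size=(50, 2)), PLANE)
        c, _ = covariation_cost(data, f)
        assert c < 1e-12

    def test_hand_example_perfect_repairing(self):
        f = linear_valley(1, -1, 0)
        data = ExecutionSet([[0.0, 1.0], [1.0, 0.0]], PLANE)
        c, perm = covariation_cost(data, f)
        assert c == pytest.approx(1.0, abs=1e-12)
        assert sorted(perm) == [0, 1] and perm[0] != 0

    def test_equals_brute_force(self, rng):
        for _ in range(20):
            n = int(rng.integers(4, 8))
            rows = rng.normal(size=(n, 2))
            a, b, c0 = rng.normal(size=3)
            f = ResultFunction(
                frame=PLANE,
                evaluate=lambda p: abs(a * p[0] + b * np.sin(p[1]) - c0),
                evaluate_batch=lambda R: np.abs(
                    a * R[:, 0] + b * np.sin(R[:, 1]) - c0
                ),
            )
            data = ExecutionSet(rows, PLANE)
            cost, _ = covariation_cost(data, f)
            oracle_mean, _ = brute_force_covariation(rows, f)
            assert f.batch(rows).mean() - cost == pytest.approx(
                oracle_mean, abs=1e-12
            )

    def test_marginals_preserved(self, rng):
        data, f = generate_alignment_case("diagonal", "misaligned", n=40, seed=5)
        _, perm = covariation_cost(data, f)
        repaired = data.data.copy()
        repaired[:, 1] = data.data[perm, 1]
        for col in range(2):
            assert np.array_equal(
                np.sort(repaired[:, col]), np.sort(data.data[:, col])
            )

    def test_exact_cap_advises_heuristic(self, rng):
        data = ExecutionSet(rng.normal(size=(30, 2)), PLANE)
        f = linear_valley(1, 1, 0)
        with pytest.raises(ValueError, match="swap"):
            covariation_cost(data, f, exact_cap=20)

    def test_swap_heuristic_near_exact(self, rng):
        data, f = generate_alignment_case("diagonal", "misaligned", n=60, seed=6)
        c_exact, _ = covariation_cost(data, f, method="exact")
        c_swap, _ = covariation_cost(data, f, method="swap", seed=0)
        assert 0 <= c_swap <= c_exact + 1e-12
        assert c_swap >= 0.9 * c_exact

    def test_alignment_ordering(self):
        costs = {}
        for align in ("misaligned", "none", "aligned"):
            data, f = generate_alignment_case("diagonal", align, n=100, seed=4)
            costs[align], _ = covariation_cost(data, f)
        assert costs["misaligned"] > costs["none"] > costs["aligned"]
        for align in ("misaligned", "none", "aligned"):
            data, f = generate_alignment_case("axis-parallel", align, n=100, seed=4)
            c, _ = covariation_cost(data, f)
            assert c < 1e-12


class TestRevisedCovariation:
    def _diag_manifold(self, lim=12.0, n=60):
        s = np.linspace(-lim, lim, n) / np.sqrt(2)
        return SolutionManifold(np.column_stack([s, s]), PLANE)

    def test_idempotent_at_45_degrees(self):
        data, f = generate_alignment_case("diagonal", "misaligned", n=80, seed=7)
        man = self._diag_manifold()
        c_plain, _ = covariation_cost(data, f)
        c_rev, ang = revised_covariation_cost(data, f, man)
        assert abs(ang) < 1e-6
        assert c_rev == pytest.approx(c_plain, rel=1e-9)

    def test_detects_hidden_covariation(self):
        """Axis-parallel manifold hides covariation from the plain C cost;
        the rotation-aligned revision exposes it."""
        data, f = generate_alignment_case("axis-parallel", "misaligned", n=80, seed=8)
        man = SolutionManifold(
            np.column_stack([np.linspace(-12, 12, 60), np.zeros(60)]), PLANE
        )
        c_plain, _ = covariation_cost(data, f)
        c_rev, ang = revised_covariation_cost(data, f, man)
        assert c_plain < 1e-12
        assert c_rev > 0.1
        assert abs(abs(ang) - np.pi / 4) < 1e-6

    def test_insensitive_to_initial_rotation(self, rng):
        data, f = generate_alignment_case("diagonal", "misaligned", n=80, seed=9)
        man = self._diag_manifold()
        base, _ = revised_covariation_cost(data, f, man)
        for k in range(10):
            b = rng.uniform(0, np.pi)
            R = np.array(
                [[np.cos(b), -np.sin(b)], [np.sin(b), np.cos(b)]]
            )
            tgt = CoordinateFrame(f"rot{k}", ("u", "v"), ("1", "1"))
            t = linear_transform(data.frame, tgt, R)
            rc, _ = revised_covariation_cost(
                data.transformed(t), f.reparametrized(t), man.transformed(t)
            )
            assert rc == pytest.approx(base, rel=0.1)

    def test_manifold_far_from_data_raises(self):
        data, f = generate_alignment_case("diagonal", "misaligned", n=50, seed=1)
        far = SolutionManifold(
            np.column_stack([np.linspace(90, 100, 20), np.linspace(90, 100, 20)]),
            PLANE,
        )
        with pytest.raises(ValueError, match="manifold"):
            revised_covariation_cost(data, f, far)


class TestNonnegativityAndModel:
    def test_all_costs_nonnegative_random_clouds(self, rng):
        for seed in range(5):
            data, f = generate_alignment_case(
                "diagonal",
                ("misaligned", "none", "aligned")[seed % 3],
                n=40,
                seed=seed,
            )
            res = TNC(data, f).fit(grid_resolution=21)
            assert res.t_cost >= 0
            assert res.n_cost >= 0
            assert res.c_cost >= 0

    def test_summary_mentions_all_costs(self):
        data, f = generate_alignment_case("diagonal", "none", n=30, seed=0)
        res = TNC(data, f).fit(grid_resolution=11)
        s = res.summary()
        for word in ("Tolerance", "Noise", "Covariation"):
            assert word in s


class TestBootstrap:
    def test_deterministic_given_seed(self):
        data, f = generate_alignment_case("diagonal", "misaligned", n=60, seed=3)
        m = TNC(data, f)
        b1 = m.bootstrap(k_draws=8, n_per_draw=30, seed=5, grid_resolution=11)
        b2 = m.bootstrap(k_draws=8, n_per_draw=30, seed=5, grid_resolution=11)
        for k in ("t_cost", "n_cost", "c_cost"):
            assert np.array_equal(b1[k]["draws"], b2[k]["draws"])
            assert b1[k]["sd"] >= 0

    def test_sd_shrinks_with_draw_size(self):
        """Bootstrap SDs shrink roughly like 1/sqrt(n_per_draw)."""
        data, f = generate_alignment_case("diagonal", "misaligned", n=400, seed=10)
        m = TNC(data, f)
        small = m.bootstrap(k_draws=30, n_per_draw=50, seed=1, grid_resolution=11)
        large = m.bootstrap(k_draws=30, n_per_draw=200, seed=1, grid_resolution=11)
        ratio = small["c_cost"]["sd"] / large["c_cost"]["sd"]
        assert 1.0 < ratio < 4.0  # expected 2, generous factor-2 window
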