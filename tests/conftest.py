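"""Shared fixtures: model tasks and seeded synthetic datasets.

Expensive objects (solution manifolds, the 500-trial reaching dataset) are
session-scoped so the suite extracts them once.
"""

import numpy as np
import pytest

from taskvar import (
    ReachingScenario,
    ReachingTask,
    SkittlesModel,
    generate_reaching_dataset,
)


@pytest.fixture(scope="session")
def reaching_task() -> ReachingTask:
    return ReachingTask.default()


@pytest.fixture(scope="session")
def reaching_sets(reaching_task):
    """The 500-trial isotropic hand-scatter scenario in all three frames."""
    return generate_reaching_dataset(ReachingScenario(seed=1))


@pytest.fixture(scope="session")
def skittles_model() -> SkittlesModel:
    return SkittlesModel()


@pytest.fixture(scope="session")
def polar_manifold(skittles_model):
    man = skittles_model.solution_manifold("polar", n=50)
    assert man.n_vertices >= 30
    return man


@pytest.fixture(scope="session")
def cartesian_manifold(skittles_model):
    man = skittles_model.solution_manifold("cartesian", n=50)
    assert man.n_vertices >= 30
    return man


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
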