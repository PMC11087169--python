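"""Shared fixtures: calibrated functions, packaged tables, small grids."""
from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from aptqa.grids import DoseGrid, StructureMask
from aptqa.io import (
    default_scoring_functions,
    load_endpoint_fixture,
    load_scorecard_fixture,
)
from aptqa.scoring import default_goals
from aptqa.synthetic import default_phantom_spec


@pytest.fixture(scope="session")
def fns():
    return default_scoring_functions()


@pytest.fixture(scope="session")
def goals():
    return default_goals()


@pytest.fixture(scope="session")
def cohort_endpoints():
    return load_endpoint_fixture("cohort")


@pytest.fixture(scope="session")
def cohort_scores():
    return load_scorecard_fixture("cohort")


@pytest.fixture(scope="session")
def finetuned_endpoints():
    return load_endpoint_fixture("finetuned")


@pytest.fixture(scope="session")
def finetuned_scores():
    return load_scorecard_fixture("finetuned")


def coarse_spec(seed=None, spacing=4.0):
    """The default phantom coarsened for fast course simulation."""
    spec = default_phantom_spec(seed)
    shape = tuple(int(round(n * s / spacing)) for n, s in zip(spec.shape, spec.spacing))
    return replace(spec, shape=shape, spacing=(spacing,) * 3)


def random_case(seed, shape=(11, 13, 9), spacing=(2.0, 2.5, 3.0), density=0.4):
    """A seeded random dose grid with a nonempty random mask."""
    rng = np.random.default_rng(seed)
    dose = DoseGrid(rng.uniform(0.0, 80.0, size=shape), spacing)
    mask = rng.random(shape) < density
    if not mask.any():
        mask.flat[rng.integers(0, mask.size)] = True
    return dose, StructureMask("ROI", mask)
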