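"""Shared fixtures: small simulated datasets generated at test time."""

import warnings

import numpy as np
import pandas as pd
import pytest

from wavegam.experiments import SINGLE_WAVE_TRUTH, single_wave_field
from wavegam.preprocess import aggregate, assign_centroids, compute_growth
from wavegam.synth import SamplingDesign, Wave, WaveFieldSpec, generate_surveys


def simulate_growth(spec, n_per_quarter=150, seed=0, mode="uniform",
                    core=None):
    """Surveys -> growth observations for a given field, warnings silenced."""
    design = SamplingDesign(mode=mode, n_surveys_per_quarter=n_per_quarter,
                            core_region=core, seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        surveys = generate_surveys(spec, design)
    assignment = assign_centroids(surveys)
    cells = aggregate(surveys, assignment)
    return compute_growth(cells)


@pytest.fixture(scope="session")
def re_truth():
    return dict(SINGLE_WAVE_TRUTH)


@pytest.fixture(scope="session")
def re_field():
    """Canonical single radial-expanding wave field."""
    return single_wave_field()


@pytest.fixture(scope="session")
def small_growth(re_field):
    """Growth observations from a modest survey effort (fast fits)."""
    return simulate_growth(re_field, n_per_quarter=150, seed=42)


@pytest.fixture(scope="session")
def tiny_growth(re_field):
    """Very small dataset for exercising every model structure cheaply."""
    growth = simulate_growth(re_field, n_per_quarter=60, seed=7)
    return growth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
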