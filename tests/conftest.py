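"""Shared fixtures.

Small untrained observers cover mechanism tests (homogeneity, isolation,
rewiring algebra); a single full experiment record — the default study
conditions — is computed once per session and shared by the end-to-end
behavioral checks.
"""

import warnings

import numpy as np
import pytest

from gainscope import stimuli
from gainscope.observer import Observer, ObserverConfig

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_observer():
    """Untrained 64-px observer with narrow channels; mechanism tests only."""
    return Observer(ObserverConfig(input_side=64, channels=(8, 16, 16, 16),
                                   seed=7))


@pytest.fixture(scope="session")
def small_observer_nobias():
    return Observer(ObserverConfig(input_side=64, channels=(8, 16, 16, 16),
                                   use_bias=False, seed=7))


@pytest.fixture(scope="session")
def small_images(rng):
    return rng.random((12, 64, 64, 3)).astype(np.float32)


@pytest.fixture(scope="session")
def tiny_library():
    """8 categories x 45 images at the minimum image side (cheap renders)."""
    return stimuli.generate_category_library(8, 45, 16, seed=5)


@pytest.fixture(scope="session")
def experiment_record():
    """The full default experiment (full-scale stimulus geometry, narrow
    channels) run once per session."""
    from gainscope.pipeline import ExperimentConfig, run_experiment

    return run_experiment(ExperimentConfig(seed=1))
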