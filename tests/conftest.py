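import warnings

import numpy as np
import pytest

from petkin import hrrt_38_frame_schedule
from petkin.simulate import (
    DEFAULT_REGIONS,
    StudyDesign,
    simulate_study,
    simulate_tissue_tac,
    simulate_true_input,
)

try:
    from hypothesis import settings

    settings.register_profile("ci", derandomize=True, max_examples=50)
    settings.load_profile("ci")
except ImportError:
    pass

warnings.filterwarnings("ignore", message="excluding .* non-positive")


@pytest.fixture(scope="session")
def schedule():
    return hrrt_38_frame_schedule()


@pytest.fixture(scope="session")
def true_input():
    """Noise-free default input function on the fine grid."""
    return simulate_true_input()


@pytest.fixture(scope="session")
def noiseless_tacs(true_input, schedule):
    """Noise-free frame-averaged TACs for the default regions."""
    return {
        r.region_label: simulate_tissue_tac(r, true_input, schedule)
        for r in DEFAULT_REGIONS
    }


@pytest.fixture(scope="session")
def small_study():
    """A small noisy test-retest study (3 subjects, defaults otherwise)."""
    return simulate_study(StudyDesign(n_subjects=3, seed=42))
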