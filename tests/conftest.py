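"""Shared fixtures: small synthetic cohorts reused across test modules.

Everything is generated programmatically at session scope; cohort containers
use a 220-s recording (the 180-s analysis window plus margins) to keep the
suite fast while preserving the study's window length.
"""

import numpy as np
import pytest

from edsleep.pipeline import build_cohort_table
from edsleep.synth_cohort import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(n_high=8, n_low=8, duration_s=220.0, seed=1234)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    """Feature table for the small cohort, detector-based masking, PAC on."""
    return build_cohort_table(small_cohort, include_pac=True)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
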