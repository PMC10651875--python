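import logging
import warnings

import numpy as np
import pytest

from slowspec import FitSettings, ect_like_config, make_cohort
from slowspec.pipeline import analyze_arm

logging.disable(logging.WARNING)


@pytest.fixture(autouse=True)
def _quiet():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def ect_arm():
    """One fully analyzed ECT-like arm (22 patients, 16 electrodes),
    shared across tests that inspect features and test results."""
    cohort = make_cohort(ect_like_config(n_patients=22, n_channels=16, seed=7))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        arm = analyze_arm(cohort, FitSettings())
    arm["cohort"] = cohort
    return arm
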