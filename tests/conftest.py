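import numpy as np
import pandas as pd
import pytest

from aidiet import calibration_default, simulate_study


@pytest.fixture(scope="session")
def study_dataset():
    """Study-sized synthetic dataset (273 cases / 269 controls) under the
    packaged calibration."""
    return simulate_study(calibration_default(seed=20240523))


@pytest.fixture(scope="session")
def subjects(study_dataset):
    return study_dataset.data


@pytest.fixture
def rng():
    return np.random.default_rng(20240523)
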