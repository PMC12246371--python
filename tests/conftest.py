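import numpy as np
import pandas as pd
import pytest
from hypothesis import settings as hyp_settings

from sretddm.design import GroupTruth, StudyDesign

hyp_settings.register_profile("repro", derandomize=True)
hyp_settings.load_profile("repro")
from sretddm.synthetic import generate_dataset


@pytest.fixture(scope="session")
def small_trials() -> pd.DataFrame:
    """Six-participant dataset at the default generating truth."""
    return generate_dataset(GroupTruth(), StudyDesign(n_participants=6), seed=20)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
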