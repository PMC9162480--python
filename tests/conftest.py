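import numpy as np
import pytest

from pcw.survey_io import write_table
from pcw.synthetic_data import GeneratorConfig, sample_population


@pytest.fixture(scope="session")
def small_dataset():
    """A 200-record synthetic cohort with default study conditions."""
    return sample_population(GeneratorConfig(n=200, seed=11))


@pytest.fixture(scope="session")
def survey_csv(tmp_path_factory, small_dataset):
    path = tmp_path_factory.mktemp("data") / "survey.csv"
    write_table(small_dataset.frame, path)
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
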