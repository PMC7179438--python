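import pytest
from hypothesis import settings

from a2aqsar import datasets

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def training_table():
    return datasets.load_training_table()


@pytest.fixture(scope="session")
def clean_training_table(training_table):
    """The 16-compound training set after removing the five outliers."""
    return training_table.drop(datasets.training_outlier_ids())


@pytest.fixture(scope="session")
def test_table():
    return datasets.load_test_table()


@pytest.fixture(scope="session")
def screening_table():
    return datasets.load_screening_table()


@pytest.fixture(scope="session")
def printed_models():
    return datasets.load_linear_models()


@pytest.fixture(scope="session")
def pharmacophore_model():
    return datasets.load_pharmacophore_model()
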