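import pytest

from oxaqsar import LinearQSAR, load_study_dataset


@pytest.fixture(scope="session")
def dataset():
    return load_study_dataset()


@pytest.fixture(scope="session")
def training(dataset):
    return dataset.training()


@pytest.fixture(scope="session")
def mlr_refit(training):
    return LinearQSAR().fit(training, training["pIC50_obs"])
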