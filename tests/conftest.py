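import pytest
from hypothesis import settings

from mirsite import RunConfig, default_params
from mirsite.synth import SynthConfig, generate_dataset
from mirsite import pipeline

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def small_dataset():
    """A 6-transcript shifted dataset shared across the suite."""
    return generate_dataset(SynthConfig(n_transcripts=6), seed=11)


@pytest.fixture(scope="session")
def small_table(small_dataset):
    return pipeline.build_dataset_table(small_dataset)
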