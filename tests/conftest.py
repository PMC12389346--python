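import pytest

from budcast import featurize_dataset, load_packaged_dataset


@pytest.fixture(scope="session")
def dataset():
    """The packaged 53-record curated stability dataset."""
    return load_packaged_dataset()


@pytest.fixture(scope="session")
def features(dataset):
    """The 27-feature encoding of the packaged dataset (+ bud_days)."""
    return featurize_dataset(dataset)
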