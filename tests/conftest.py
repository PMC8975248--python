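import numpy as np
import pytest

from emgdx import PipelineConfig, SimConfig, build_lifting_scheme, compute_feature_table, generate_dataset


@pytest.fixture(scope="session")
def scheme():
    return build_lifting_scheme("rbio3.7")


@pytest.fixture(scope="session")
def small_dataset():
    """9 short recordings, 3 per class."""
    base = SimConfig(class_label="healthy", duration_s=0.5)
    return generate_dataset({"healthy": 3, "myopathy": 3, "neuropathy": 3}, base, seed=11)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    return compute_feature_table(small_dataset, PipelineConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
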