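import pytest

from amidebench.features import ReactionFeaturizer
from amidebench.synthetic import GeneratorConfig, build_fragment_library, generate_dataset


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(
        n_reactions=300, n_planted_cliffs=8, n_planted_uncertain=4, seed=42
    )


@pytest.fixture(scope="session")
def small_data(small_config):
    """A 300-reaction synthetic dataset with planted structure."""
    return generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_dataset(small_data):
    return small_data[0]


@pytest.fixture(scope="session")
def small_truth(small_data):
    return small_data[1]


@pytest.fixture(scope="session")
def small_featurizer(small_data):
    dataset, truth = small_data
    return ReactionFeaturizer(dataset, qm_provider=truth.qm_provider())


@pytest.fixture(scope="session")
def fragment_library():
    return build_fragment_library(GeneratorConfig())
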