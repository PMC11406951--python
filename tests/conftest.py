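import pytest

from commgem import netgen
from commgem.pipeline import ExperimentConfig


@pytest.fixture(scope="session")
def universal():
    return netgen.generate_universal_network(200, 400, 0.2, seed=1)


@pytest.fixture(scope="session")
def organism(universal):
    return netgen.sample_organism_genome(universal, 3, seed=7, organism_id="spA")


def make_small_config(seed: int, **overrides) -> ExperimentConfig:
    """A scaled-down experiment configuration that runs in well under a
    second, used for Monte-Carlo and determinism tests."""
    params = dict(
        seed=seed,
        n_compounds=120,
        n_reactions=260,
        n_accessory_modules=12,
        n_organisms=10,
        modules_min=1,
        modules_max=3,
        n_samples=4,
        n_met_samples=3,
        n_host_extras=5,
        n_replicate_ids=2,
        n_pathways=12,
    )
    params.update(overrides)
    return ExperimentConfig(**params)


@pytest.fixture
def small_config():
    return make_small_config(seed=1)
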