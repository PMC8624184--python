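import pytest

from polyals import synthdata
from polyals.mutations import default_reference


@pytest.fixture(scope="session")
def models():
    """(red hexaploid, white tetraploid) template models, seed 0."""
    return synthdata.make_species_models(0)


@pytest.fixture(scope="session")
def red(models):
    return models[0]


@pytest.fixture(scope="session")
def white(models):
    return models[1]


@pytest.fixture(scope="session")
def reference():
    return default_reference()


@pytest.fixture(scope="session")
def mixed_full_library(models):
    """Mixed-species full-length clone library used to derive anchors."""
    cfg = synthdata.GeneratorConfig(seed=11, n_clones=30, part="full",
                                    error_rate=0.002)
    return synthdata.sample_clone_library(models, cfg)
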