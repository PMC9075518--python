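import pytest

from shsp.model import build_default_model, default_threshold
from shsp.simulate import GeneratorConfig, generate_repertoire
from shsp.templates import CLUSTERS, build_template


@pytest.fixture(scope="session")
def model():
    return build_default_model()


@pytest.fixture(scope="session")
def threshold():
    return default_threshold()


@pytest.fixture(scope="session")
def templates():
    return {lab: build_template(lab) for lab in CLUSTERS + ("dimeric",)}


@pytest.fixture(scope="session")
def small_repertoire():
    """A modest mutated repertoire shared across tests (seed 7, 2% noise)."""
    cfg = GeneratorConfig(
        n_per_cluster={"A1": 4, "A2": 4, "B1": 4, "B2": 4, "B3": 4, "dimeric": 4},
        sub_rate_strand=0.02,
        sub_rate_loop=0.02,
        n_random_decoys=10,
        n_near_miss_decoys=10,
        seed=7,
    )
    return cfg, generate_repertoire(cfg)
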