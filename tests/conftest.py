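import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from swimneat.genome import (
    Genome,
    InnovationRegistry,
    minimal_genome,
    mutate_add_connection,
    mutate_add_node,
    mutate_weights,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def registry():
    return InnovationRegistry()


def make_random_genome(registry: InnovationRegistry, rng: np.random.Generator,
                       n_structural: int = 3) -> Genome:
    """A small genome grown from minimal by random structural mutations."""
    g = minimal_genome(2, 1, registry, rng)
    for _ in range(n_structural):
        if rng.random() < 0.5:
            mutate_add_node(g, registry, rng)
        else:
            mutate_add_connection(g, registry, rng)
    mutate_weights(g, 1.0, 0.5, 0.1, rng)
    return g


@pytest.fixture
def random_population(registry, rng):
    """20 small genomes sharing one innovation registry."""
    pop = [make_random_genome(registry, rng, n_structural=int(rng.integers(0, 4)))
           for _ in range(20)]
    return pop
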