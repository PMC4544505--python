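import random

import pytest
from hypothesis import HealthCheck, settings

import linemol as lm

settings.register_profile(
    "linemol",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("linemol")


@pytest.fixture(scope="session")
def toy() -> lm.MolecularGraph:
    """4-bead methylcyclopropane lumped model."""
    return lm.load_example("methylcyclopropane")


@pytest.fixture(scope="session")
def tauro() -> lm.MolecularGraph:
    """12-bead coarse-grained taurocholate bile salt model."""
    return lm.load_example("taurocholate")


def random_graph_from_seed(seed: int, p_max: int = 12) -> lm.MolecularGraph:
    """Deterministic random connected molecule: seed -> graph."""
    rng = random.Random(seed)
    p = rng.randint(2, p_max)
    max_extra = p * (p - 1) // 2 - (p - 1)
    k = rng.randint(0, min(max_extra, p))
    return lm.random_connected(p, extra_edges=k, seed=rng.randrange(2**31))
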