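import numpy as np
import pytest
from hypothesis import settings

from targetprop.knowledge import (
    ComplexSet,
    GeneUniverse,
    Interactome,
    LigandReceptorMap,
    PathwaySet,
)
from targetprop.synthetic_data import SimulationConfig, generate_world

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=40)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_world():
    """Planted synthetic world, small enough for repeated use."""
    return generate_world(SimulationConfig(n_genes=300, n_traits=6, seed=7))


@pytest.fixture
def toy_universe():
    genes = [f"g{i}" for i in range(1, 11)]
    return GeneUniverse(
        genes=tuple(genes),
        is_coding=tuple([True] * 9 + [False]),
        is_hla=tuple([False] * 10),
    )


@pytest.fixture
def path_graph():
    """a - b - c - d."""
    return Interactome.from_edges(
        [("a", "b", 1.0), ("b", "c", 1.0), ("c", "d", 1.0)], name="path"
    )
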