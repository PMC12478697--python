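import numpy as np
import pytest

from crnsubnet.core import NetworkDims, parse_reaction_string
from crnsubnet.randnet import ReactionTypeDistribution, make_random_network


@pytest.fixture
def chain_net():
    """R1: A->B; R2: B->C — the canonical two-step chain."""
    return parse_reaction_string("R1: A -> B\nR2: B -> C", name="chain")


@pytest.fixture
def single_bimolecular():
    return parse_reaction_string("J1: A + B -> C", name="bimolecular")


@pytest.fixture
def autocatalytic():
    """2A -> A + B, the worked stoichiometry example."""
    return parse_reaction_string("J1: 2 A -> A + B", name="auto")


def random_net(num_species, num_reactions, seed, dist=None):
    return make_random_network(
        NetworkDims(num_species, num_reactions),
        dist=dist,
        seed=seed,
        name=f"rand{seed}",
    )


@pytest.fixture
def small_dist():
    """Types up to 2 reactants/products: keeps tiny nets connected enough."""
    types = [(i, j) for i in range(3) for j in range(3) if (i, j) != (0, 0)]
    from crnsubnet.core import ReactionType

    rts = tuple(ReactionType(*t) for t in types)
    return ReactionTypeDistribution(rts, tuple([1 / len(rts)] * len(rts)))
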