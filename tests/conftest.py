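import numpy as np
import pytest

from metajac.network import MetabolicNetwork, Reaction, Species, build_interaction_matrix


def make_network(species_spec, reactions_spec, compartments=("cytosol",)):
    """Helper: species_spec is a list of (id, compartment); reactions_spec a
    list of (id, stoichiometry dict) or (id, stoichiometry, reversible)."""
    species = [Species(id=s, name=s, compartment=c) for s, c in species_spec]
    reactions = []
    for spec in reactions_spec:
        rid, stoich = spec[0], spec[1]
        rev = spec[2] if len(spec) > 2 else False
        reactions.append(Reaction(id=rid, reversible=rev, stoichiometry=dict(stoich)))
    return MetabolicNetwork(species=species, reactions=reactions, compartments=list(compartments))


@pytest.fixture
def chain_network():
    """A -> B -> C in one compartment."""
    return make_network(
        [("A", "cytosol"), ("B", "cytosol"), ("C", "cytosol")],
        [("r1", {"A": -1.0, "B": 1.0}), ("r2", {"B": -1.0, "C": 1.0})],
    )


@pytest.fixture
def branched_network():
    """A -> B -> C with a side branch B -> D."""
    return make_network(
        [("A", "cytosol"), ("B", "cytosol"), ("C", "cytosol"), ("D", "cytosol")],
        [
            ("r1", {"A": -1.0, "B": 1.0}),
            ("r2", {"B": -1.0, "C": 1.0}),
            ("r3", {"B": -1.0, "D": 1.0}),
        ],
    )


@pytest.fixture
def chain_matrix(chain_network):
    return build_interaction_matrix(chain_network)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
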