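"""Reduce a metabolic network to the experimentally measured pools.

Builds a small branched network, assembles its interaction matrix, and
projects it onto a measured subset: the removed intermediate B is collapsed
into superpathway columns whose provenance records every original reaction.
"""

from metajac import build_interaction_matrix, parse_sbml, project_to_measured
from metajac.network import MetabolicNetwork, Reaction, Species, write_sbml

net = MetabolicNetwork(
    species=[Species(s, s, "cytosol") for s in "ABCD"],
    reactions=[
        Reaction("r1", False, {"A": -1.0, "B": 1.0}),
        Reaction("r2", False, {"B": -1.0, "C": 1.0}),
        Reaction("r3", False, {"B": -1.0, "D": 1.0}),
    ],
    compartments=["cytosol"],
)

# round-trip through SBML, as a real reconstruction would arrive
net = parse_sbml(write_sbml(net))
matrix = build_interaction_matrix(net)
print("full matrix:")
print(matrix.to_delimited())

# only A, C and D were measured; B is collapsed into superpathways
projected = project_to_measured(matrix, ["A", "C", "D"])
print("projected onto measured pools {A, C, D}:")
print(projected.to_delimited())
print(projected.provenance_table())
# Each sp__ column carries -1 at its source and +1 at its sink; its
# provenance lists the original reactions it implicitly represents.
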