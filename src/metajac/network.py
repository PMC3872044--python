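"""Metabolic network models and the metabolic interaction matrix.

A genome-scale (or reduced) metabolic reconstruction is read from SBML into a
:class:`MetabolicNetwork`.  Its stoichiometry is assembled into an
:class:`InteractionMatrix` (species x interactions, signed coefficients) --
the structural surrogate for the stoichiometric matrix ``N`` in the Jacobian
decomposition ``J = N dr/dM``.  :func:`project_to_measured` reduces the
matrix to an experimentally measured metabolite subset: chains of reactions
running through removed intermediates are collapsed into single
"superpathway" columns that implicitly represent every intermediate step,
with full provenance back to the original reactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

import libsbml


class NetworkValidationError(ValueError):
    """A structural inconsistency in a metabolic network or matrix input."""


class SBMLParseError(ValueError):
    """The SBML document could not be read."""


@dataclass(frozen=True)
class Species:
    id: str
    name: str
    compartment: str
    is_boundary: bool = False


@dataclass(frozen=True)
class Reaction:
    id: str
    reversible: bool
    #: species id -> signed coefficient (reactants negative, products positive)
    stoichiometry: dict


@dataclass
class MetabolicNetwork:
    """A compartmented metabolic network: species, reactions, compartments."""

    species: list
    reactions: list
    compartments: list

    def __post_init__(self) -> None:
        ids = [s.id for s in self.species]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise NetworkValidationError(f"duplicate species ids: {sorted(dupes)}")
        comp_set = set(self.compartments)
        for s in self.species:
            if s.compartment not in comp_set:
                raise NetworkValidationError(
                    f"species {s.id!r} references undeclared compartment "
                    f"{s.compartment!r}"
                )
        id_set = set(ids)
        for r in self.reactions:
            if not r.stoichiometry:
                raise NetworkValidationError(f"reaction {r.id!r} has empty stoichiometry")
            missing = set(r.stoichiometry) - id_set
            if missing:
                raise NetworkValidationError(
                    f"reaction {r.id!r} references unknown species {sorted(missing)}"
                )

    @property
    def species_ids(self) -> list:
        return [s.id for s in self.species]

    def compartment_of(self) -> dict:
        return {s.id: s.compartment for s in self.species}


def parse_sbml(sbml_text: str) -> MetabolicNetwork:
    """Parse an SBML document (Level 2 or 3) into a :class:`MetabolicNetwork`.

    Reactant coefficients are recorded negative, product coefficients
    positive; a species appearing on both sides carries its net coefficient.

    Raises
    ------
    SBMLParseError
        for malformed XML (the message names the offending line).
    NetworkValidationError
        for duplicate species ids or undeclared compartments.
    """
    doc = libsbml.readSBMLFromString(sbml_text)
    errors = [
        doc.getError(i)
        for i in range(doc.getNumErrors())
        if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
    ]
    if errors:
        e = errors[0]
        raise SBMLParseError(
            f"SBML parse error at line {e.getLine()}: {e.getMessage().strip()}"
        )
    model = doc.getModel()
    if model is None:
        raise SBMLParseError("document contains no model")
    if model.getNumSpecies() == 0:
        raise NetworkValidationError("model declares no species")

    compartments = [model.getCompartment(i).getId() for i in range(model.getNumCompartments())]
    species = []
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        species.append(
            Species(
                id=sp.getId(),
                name=sp.getName() or sp.getId(),
                compartment=sp.getCompartment(),
                is_boundary=bool(sp.getBoundaryCondition()),
            )
        )
    reactions = []
    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        stoich: dict = {}
        for j in range(rx.getNumReactants()):
            ref = rx.getReactant(j)
            c = ref.getStoichiometry()
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) - (
                1.0 if np.isnan(c) else c
            )
        for j in range(rx.getNumProducts()):
            ref = rx.getProduct(j)
            c = ref.getStoichiometry()
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), 0.0) + (
                1.0 if np.isnan(c) else c
            )
        stoich = {k: v for k, v in stoich.items() if v != 0.0}
        if not stoich:
            # fully cancelling (or empty) reactions carry no structural information
            raise NetworkValidationError(f"reaction {rx.getId()!r} has empty net stoichiometry")
        reactions.append(Reaction(id=rx.getId(), reversible=bool(rx.getReversible()), stoichiometry=stoich))

    return MetabolicNetwork(species=species, reactions=reactions, compartments=compartments)


def read_sbml_file(path) -> MetabolicNetwork:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_sbml(fh.read())


def write_sbml(network: MetabolicNetwork) -> str:
    """Serialize a network as SBML Level 3 Version 1."""
    doc = libsbml.SBMLDocument(3, 1)
    model = doc.createModel()
    model.setId("model")
    for c in network.compartments:
        comp = model.createCompartment()
        comp.setId(c)
        comp.setConstant(True)
        comp.setSize(1.0)
    for s in network.species:
        sp = model.createSpecies()
        sp.setId(s.id)
        sp.setName(s.name)
        sp.setCompartment(s.compartment)
        sp.setBoundaryCondition(s.is_boundary)
        sp.setHasOnlySubstanceUnits(False)
        sp.setConstant(False)
    for r in network.reactions:
        rx = model.createReaction()
        rx.setId(r.id)
        rx.setReversible(r.reversible)
        rx.setFast(False)
        for sid, coef in sorted(r.stoichiometry.items()):
            if coef < 0:
                ref = rx.createReactant()
                ref.setSpecies(sid)
                ref.setStoichiometry(-coef)
            else:
                ref = rx.createProduct()
                ref.setSpecies(sid)
                ref.setStoichiometry(coef)
            ref.setConstant(True)
    return libsbml.writeSBMLToString(doc)


@dataclass
class InteractionMatrix:
    """Species x interaction signed coefficient matrix.

    ``provenance`` maps every interaction (column) id to the list of original
    reaction ids it summarizes; a plain reaction column maps to itself, a
    superpathway column to every reaction collapsed into it.
    """

    species_order: list
    interaction_order: list
    values: np.ndarray
    provenance: dict
    #: species id -> compartment, carried along for deterministic reordering
    species_compartment: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.species_order), len(self.interaction_order)):
            raise NetworkValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.species_order)} species x {len(self.interaction_order)} interactions"
            )
        if self.interaction_order and not np.all(np.any(self.values != 0.0, axis=0)):
            empty = [
                self.interaction_order[j]
                for j in np.flatnonzero(~np.any(self.values != 0.0, axis=0))
            ]
            raise NetworkValidationError(f"all-zero interaction columns: {empty}")
        missing = set(self.interaction_order) - set(self.provenance)
        if missing:
            raise NetworkValidationError(f"interactions without provenance: {sorted(missing)}")

    def column(self, interaction_id: str) -> np.ndarray:
        return self.values[:, self.interaction_order.index(interaction_id)]

    def to_delimited(self, sep: str = "\t") -> str:
        """Matrix as delimited text: header of interaction ids, first column species ids."""
        lines = [sep.join(["species"] + list(self.interaction_order))]
        for i, sid in enumerate(self.species_order):
            lines.append(sep.join([sid] + [f"{v:g}" for v in self.values[i]]))
        return "\n".join(lines) + "\n"

    def provenance_table(self, sep: str = "\t") -> str:
        lines = [sep.join(["interaction", "reactions"])]
        for iid in self.interaction_order:
            lines.append(sep.join([iid, ",".join(self.provenance[iid])]))
        return "\n".join(lines) + "\n"


def _species_sort_key(matrix_compartments: dict):
    return lambda sid: (matrix_compartments.get(sid, ""), sid)


def build_interaction_matrix(network: MetabolicNetwork) -> InteractionMatrix:
    """Assemble the signed stoichiometric matrix of a network.

    Rows are species, ordered by (compartment, id); columns are reactions in
    document order; entries are the signed coefficients.  Each column's
    provenance is its own reaction.
    """
    if not network.species:
        raise NetworkValidationError("network has no species")
    comp = network.compartment_of()
    species_order = sorted(network.species_ids, key=_species_sort_key(comp))
    idx = {sid: i for i, sid in enumerate(species_order)}
    values = np.zeros((len(species_order), len(network.reactions)))
    for j, r in enumerate(network.reactions):
        for sid, coef in r.stoichiometry.items():
            values[idx[sid], j] = coef
    return InteractionMatrix(
        species_order=species_order,
        interaction_order=[r.id for r in network.reactions],
        values=values,
        provenance={r.id: [r.id] for r in network.reactions},
        species_compartment=comp,
    )


def _interaction_edges(matrix: InteractionMatrix):
    """Directed (source, target, interaction-id) edges implied by each column.

    Every consumed species points to every produced species; reversible
    directionality is not represented in the signed column, so collapse
    treats the stated direction only.  Columns touching a single species
    (pure influx/efflux) contribute no edges.
    """
    edges = []
    for j, iid in enumerate(matrix.interaction_order):
        col = matrix.values[:, j]
        sources = [matrix.species_order[i] for i in np.flatnonzero(col < 0)]
        targets = [matrix.species_order[i] for i in np.flatnonzero(col > 0)]
        for u in sources:
            for v in targets:
                edges.append((u, v, iid))
    return edges


def project_to_measured(
    matrix: InteractionMatrix,
    measured,
    include_first_neighbors: bool = False,
    max_path_length: int = 6,
) -> InteractionMatrix:
    """Project an interaction matrix onto a measured metabolite subset.

    Retained species are the measured set plus, if ``include_first_neighbors``,
    every species sharing at least one interaction with a measured species.
    Interactions whose participants are all retained keep their original
    column.  Chains of interactions running through removed intermediates are
    collapsed into superpathway columns (coefficient -1 on the retained
    source, +1 on the retained sink) by bounded enumeration of simple paths
    (at most ``max_path_length`` interaction steps); a superpathway's
    provenance is the union of the original reactions along every collapsed
    path.  Parallel superpathways with the same signed pattern are merged.
    """
    measured = list(measured)
    if not measured:
        raise NetworkValidationError("measured set is empty")
    unknown = sorted(set(measured) - set(matrix.species_order))
    if unknown:
        raise NetworkValidationError(f"measured species not in matrix: {unknown}")

    retained = set(measured)
    if include_first_neighbors:
        meas_rows = [matrix.species_order.index(s) for s in measured]
        touch = np.any(matrix.values[meas_rows, :] != 0.0, axis=0)
        for j in np.flatnonzero(touch):
            for i in np.flatnonzero(matrix.values[:, j] != 0.0):
                retained.add(matrix.species_order[i])

    species_order = sorted(retained, key=_species_sort_key(matrix.species_compartment))
    idx = {sid: i for i, sid in enumerate(species_order)}

    # 1. interactions with every participant retained: kept verbatim
    kept_cols, kept_ids, kept_prov = [], [], []
    kept_reaction_ids = set()
    for j, iid in enumerate(matrix.interaction_order):
        participants = {
            matrix.species_order[i] for i in np.flatnonzero(matrix.values[:, j] != 0.0)
        }
        if participants <= retained:
            col = np.zeros(len(species_order))
            for sid in participants:
                col[idx[sid]] = matrix.values[matrix.species_order.index(sid), j]
            kept_cols.append(col)
            kept_ids.append(iid)
            kept_prov.append(set(matrix.provenance[iid]))
            kept_reaction_ids.add(iid)

    # 2. superpathways: simple paths source -> sink through removed species only
    out_edges: dict = {}
    for u, v, iid in _interaction_edges(matrix):
        out_edges.setdefault(u, []).append((v, iid))

    superpaths: dict = {}  # (source, sink) -> set of reaction ids

    def _dfs(source, node, visited, used, depth):
        if depth >= max_path_length:
            return
        for v, iid in out_edges.get(node, ()):
            if v in retained:
                if v == source:
                    continue  # cycles collapse to a zero column
                if not used and iid in kept_reaction_ids:
                    continue  # direct fully-retained step, already kept verbatim
                key = (source, v)
                prov = superpaths.setdefault(key, set())
                prov.update(used)
                prov.add(iid)
            elif v not in visited:
                _dfs(source, v, visited | {v}, used + [iid], depth + 1)

    for source in species_order:
        _dfs(source, source, {source}, [], 0)

    sp_cols, sp_ids, sp_prov = [], [], []
    for (source, sink) in sorted(superpaths):
        col = np.zeros(len(species_order))
        col[idx[source]] = -1.0
        col[idx[sink]] = 1.0
        prov = set()
        for iid in superpaths[(source, sink)]:
            prov.update(matrix.provenance[iid])
        # a superpathway duplicating a kept column merges into it
        dup = next(
            (k for k, kc in enumerate(kept_cols) if np.array_equal(kc, col)), None
        )
        if dup is not None:
            kept_prov[dup] |= prov
        else:
            sp_cols.append(col)
            sp_ids.append(f"sp__{source}__{sink}")
            sp_prov.append(prov)

    all_ids = kept_ids + sp_ids
    all_cols = kept_cols + sp_cols
    all_prov = kept_prov + sp_prov
    if not all_ids:
        raise NetworkValidationError("projection yields zero interactions")
    return InteractionMatrix(
        species_order=species_order,
        interaction_order=all_ids,
        values=np.column_stack(all_cols),
        provenance={i: sorted(p) for i, p in zip(all_ids, all_prov)},
        species_compartment={
            s: matrix.species_compartment.get(s, "") for s in species_order
        },
    )
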