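"""Peptide sequences as attributed heavy-atom molecular graphs.

Amino-acid sequences (CDR3 loops, epitope peptides) are turned into
molecular graphs in two steps: each residue is instantiated from a
hand-authored heavy-atom template of the free amino acid, and consecutive
residues are joined by peptide-bond condensation (the hydroxyl oxygen of
residue *i* is removed and a C–N amide bond to residue *i+1* is added).

Hydrogens are never nodes; they are book-kept per atom in
``total_hydrogens``, following the heavy-atom graph convention.  All
residues are neutral (free N-terminal amine, free C-terminal carboxylic
acid, uncharged side chains).  Atom order is fixed — residues in sequence
order, atoms in template order — so identical sequences always produce
bit-identical graphs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable

import networkx as nx

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

_ELEMENT_NUMBERS = {"C": 6, "N": 7, "O": 8, "S": 16}

BACKBONE_ROLES = ("N", "CA", "C", "O", "sidechain", "terminal_O")

NODE_FEATURES = (
    "atomic_number",
    "aromaticity",
    "formal_charge",
    "hybridization",
    "degree",
    "total_hydrogens",
)
EDGE_FEATURES = (
    "bond_type",
    "aromaticity",
    "conjugation",
    "stereochemistry",
    "ring_membership",
)


class ResidueAlphabetError(ValueError):
    """Raised for characters outside the 20 standard one-letter codes."""


@dataclass(frozen=True)
class PeptideSequence:
    """A validated amino-acid string with an opaque identifier."""

    residues: str
    id: str = ""

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ResidueAlphabetError("empty sequence")
        bad = set(self.residues) - set(AMINO_ACIDS)
        if bad:
            raise ResidueAlphabetError(
                f"invalid residue(s) {sorted(bad)} in sequence {self.residues!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AtomNode:
    index: int
    element: int
    aromatic: bool
    formal_charge: int
    hybridization: str  # sp | sp2 | sp3 | other
    degree: int
    total_hydrogens: int
    residue_index: int
    backbone_role: str
    name: str = ""  # PDB-style atom name, for provenance/debugging


@dataclass
class BondEdge:
    endpoints: tuple[int, int]
    bond_type: str  # single | double | aromatic
    conjugated: bool
    in_ring: bool
    stereo: str = "none"


@dataclass
class MolecularGraph:
    nodes: list[AtomNode]
    edges: list[BondEdge]
    source_sequence: PeptideSequence

    def adjacency(self) -> list[list[tuple[int, int]]]:
        """Per-node list of (neighbor index, edge index) pairs."""
        adj: list[list[tuple[int, int]]] = [[] for _ in self.nodes]
        for ei, e in enumerate(self.edges):
            a, b = e.endpoints
            adj[a].append((b, ei))
            adj[b].append((a, ei))
        return adj

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(n.index, **vars(n))
        for e in self.edges:
            g.add_edge(*e.endpoints, bond_type=e.bond_type,
                       conjugated=e.conjugated, in_ring=e.in_ring,
                       stereo=e.stereo)
        return g


@dataclass(frozen=True)
class FeatureConfig:
    """Which node/edge attributes feed the WL labels.

    ``non_attributed=True`` discards all attributes and embeds pure
    connectivity (the structure-only baseline).
    """

    node_features: frozenset[str] = frozenset(NODE_FEATURES)
    edge_features: frozenset[str] = frozenset(EDGE_FEATURES)
    non_attributed: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_features", frozenset(self.node_features))
        object.__setattr__(self, "edge_features", frozenset(self.edge_features))
        unknown = self.node_features - set(NODE_FEATURES)
        if unknown:
            raise ValueError(f"unknown node features: {sorted(unknown)}")
        unknown = self.edge_features - set(EDGE_FEATURES)
        if unknown:
            raise ValueError(f"unknown edge features: {sorted(unknown)}")
        if self.non_attributed and (self.node_features or self.edge_features):
            raise ValueError("non_attributed config must have empty feature sets")


# ---------------------------------------------------------------------------
# Residue templates
#
# Atom tuples: (name, element, aromatic, hybridization, n_hydrogens, role)
# Bond tuples: (name_a, name_b, bond_type)
# Every template starts with the backbone N, CA, C, O, OXT of the free amino
# acid (N carries 2 H, 1 for proline; CA carries 1 H, 2 for glycine).
# ---------------------------------------------------------------------------

def _backbone(n_h: int = 2, ca_h: int = 1) -> list[tuple]:
    return [
        ("N", "N", False, "sp3", n_h, "N"),
        ("CA", "C", False, "sp3", ca_h, "CA"),
        ("C", "C", False, "sp2", 0, "C"),
        ("O", "O", False, "sp2", 0, "O"),
        ("OXT", "O", False, "sp3", 1, "terminal_O"),
    ]


_BACKBONE_BONDS = [("N", "CA", "single"), ("CA", "C", "single"),
                   ("C", "O", "double"), ("C", "OXT", "single")]


def _sc(name, element, n_h, aromatic=False, hyb="sp3"):
    return (name, element, aromatic, hyb, n_h, "sidechain")


_SIDE_CHAINS: dict[str, tuple[list, list]] = {
    "G": ([], []),
    "A": ([_sc("CB", "C", 3)], [("CA", "CB", "single")]),
    "V": ([_sc("CB", "C", 1), _sc("CG1", "C", 3), _sc("CG2", "C", 3)],
          [("CA", "CB", "single"), ("CB", "CG1", "single"), ("CB", "CG2", "single")]),
    "L": ([_sc("CB", "C", 2), _sc("CG", "C", 1), _sc("CD1", "C", 3), _sc("CD2", "C", 3)],
          [("CA", "CB", "single"), ("CB", "CG", "single"),
           ("CG", "CD1", "single"), ("CG", "CD2", "single")]),
    "I": ([_sc("CB", "C", 1), _sc("CG1", "C", 2), _sc("CG2", "C", 3), _sc("CD1", "C", 3)],
          [("CA", "CB", "single"), ("CB", "CG1", "single"),
           ("CB", "CG2", "single"), ("CG1", "CD1", "single")]),
    "P": ([_sc("CB", "C", 2), _sc("CG", "C", 2), _sc("CD", "C", 2)],
          [("CA", "CB", "single"), ("CB", "CG", "single"),
           ("CG", "CD", "single"), ("CD", "N", "single")]),
    "M": ([_sc("CB", "C", 2), _sc("CG", "C", 2), _sc("SD", "S", 0), _sc("CE", "C", 3)],
          [("CA", "CB", "single"), ("CB", "CG", "single"),
           ("CG", "SD", "single"), ("SD", "CE", "single")]),
    "C": ([_sc("CB", "C", 2), _sc("SG", "S", 1)],
          [("CA", "CB", "single"), ("CB", "SG", "single")]),
    "S": ([_sc("CB", "C", 2), _sc("OG", "O", 1)],
          [("CA", "CB", "single"), ("CB", "OG", "single")]),
    "T": ([_sc("CB", "C", 1), _sc("OG1", "O", 1), _sc("CG2", "C", 3)],
          [("CA", "CB", "single"), ("CB", "OG1", "single"), ("CB", "CG2", "single")]),
    "N": ([_sc("CB", "C", 2), _sc("CG", "C", 0, hyb="sp2"),
           _sc("OD1", "O", 0, hyb="sp2"), _sc("ND2", "N", 2, hyb="sp2")],
          [("CA", "CB", "single"), ("CB", "CG", "single"),
           ("CG", "OD1", "double"), ("CG", "ND2", "single")]),
    "Q": ([_sc("CB", "C", 2), _sc("CG", "C", 2), _sc("CD", "C", 0, hyb="sp2"),
           _sc("OE1", "O", 0, hyb="sp2"), _sc("NE2", "N", 2, hyb="sp2")],
          [("CA", "CB", "single"), ("CB", "CG", "single"), ("CG", "CD", "single"),
           ("CD", "OE1", "double"), ("CD", "NE2", "single")]),
    "D": ([_sc("CB", "C", 2), _sc("CG", "C", 0, hyb="sp2"),
           _sc("OD1", "O", 0, hyb="sp2"), _sc("OD2", "O", 1)],
          [("CA", "CB", "single"), ("CB", "CG", "single"),
           ("CG", "OD1", "double"), ("CG", "OD2", "single")]),
    "E": ([_sc("CB", "C", 2), _sc("CG", "C", 2), _sc("CD", "C", 0, hyb="sp2"),
           _sc("OE1", "O", 0, hyb="sp2"), _sc("OE2", "O", 1)],
          [("CA", "CB", "single"), ("CB", "CG", "single"), ("CG", "CD", "single"),
           ("CD", "OE1", "double"), ("CD", "OE2", "single")]),
    "K": ([_sc("CB", "C", 2), _sc("CG", "C", 2), _sc("CD", "C", 2),
           _sc("CE", "C", 2), _sc("NZ", "N", 2)],
          [("CA", "CB", "single"), ("CB", "CG", "single"), ("CG", "CD", "single"),
           ("CD", "CE", "single"), ("CE", "NZ", "single")]),
    # Neutral guanidine: NE–CZ single, CZ=NH1 double, CZ–NH2 single.
    "R": ([_sc("CB", "C", 2), _sc("CG", "C", 2), _sc("CD", "C", 2),
           _sc("NE", "N", 1, hyb="sp2"), _sc("CZ", "C", 0, hyb="sp2"),
           _sc("NH1", "N", 1, hyb="sp2"), _sc("NH2", "N", 2, hyb="sp2")],
          [("CA", "CB", "single"), ("CB", "CG", "single"), ("CG", "CD", "single"),
           ("CD", "NE", "single"), ("NE", "CZ", "single"),
           ("CZ", "NH1", "double"), ("CZ", "NH2", "single")]),
    # NE2-H imidazole tautomer.
    "H": ([_sc("CB", "C", 2), _sc("CG", "C", 0, True, "sp2"),
           _sc("ND1", "N", 0, True, "sp2"), _sc("CD2", "C", 1, True, "sp2"),
           _sc("CE1", "C", 1, True, "sp2"), _sc("NE2", "N", 1, True, "sp2")],
          [("CA", "CB", "single"), ("CB", "CG", "single"),
           ("CG", "ND1", "aromatic"), ("ND1", "CE1", "aromatic"),
           ("CE1", "NE2", "aromatic"), ("NE2", "CD2", "aromatic"),
           ("CD2", "CG", "aromatic")]),
    "F": ([_sc("CB", "C", 2), _sc("CG", "C", 0, True, "sp2"),
           _sc("CD1", "C", 1, True, "sp2"), _sc("CD2", "C", 1, True, "sp2"),
           _sc("CE1", "C", 1, True, "sp2"), _sc("CE2", "C", 1, True, "sp2"),
           _sc("CZ", "C", 1, True, "sp2")],
          [("CA", "CB", "single"), ("CB", "CG", "single"),
           ("CG", "CD1", "aromatic"), ("CD1", "CE1", "aromatic"),
           ("CE1", "CZ", "aromatic"), ("CZ", "CE2", "aromatic"),
           ("CE2", "CD2", "aromatic"), ("CD2", "CG", "aromatic")]),
    "Y": ([_sc("CB", "C", 2), _sc("CG", "C", 0, True, "sp2"),
           _sc("CD1", "C", 1, True, "sp2"), _sc("CD2", "C", 1, True, "sp2"),
           _sc("CE1", "C", 1, True, "sp2"), _sc("CE2", "C", 1, True, "sp2"),
           _sc("CZ", "C", 0, True, "sp2"), _sc("OH", "O", 1)],
          [("CA", "CB", "single"), ("CB", "CG", "single"),
           ("CG", "CD1", "aromatic"), ("CD1", "CE1", "aromatic"),
           ("CE1", "CZ", "aromatic"), ("CZ", "CE2", "aromatic"),
           ("CE2", "CD2", "aromatic"), ("CD2", "CG", "aromatic"),
           ("CZ", "OH", "single")]),
    # Indole: 5-ring fused to benzene through CD2/CE2.
    "W": ([_sc("CB", "C", 2), _sc("CG", "C", 0, True, "sp2"),
           _sc("CD1", "C", 1, True, "sp2"), _sc("NE1", "N", 1, True, "sp2"),
           _sc("CE2", "C", 0, True, "sp2"), _sc("CD2", "C", 0, True, "sp2"),
           _sc("CE3", "C", 1, True, "sp2"), _sc("CZ3", "C", 1, True, "sp2"),
           _sc("CH2", "C", 1, True, "sp2"), _sc("CZ2", "C", 1, True, "sp2")],
          [("CA", "CB", "single"), ("CB", "CG", "single"),
           ("CG", "CD1", "aromatic"), ("CD1", "NE1", "aromatic"),
           ("NE1", "CE2", "aromatic"), ("CE2", "CD2", "aromatic"),
           ("CD2", "CG", "aromatic"),
           ("CD2", "CE3", "aromatic"), ("CE3", "CZ3", "aromatic"),
           ("CZ3", "CH2", "aromatic"), ("CH2", "CZ2", "aromatic"),
           ("CZ2", "CE2", "aromatic")]),
}

_RING_BONDS: dict[str, set[frozenset[str]]] = {
    "P": {frozenset(p) for p in
          [("N", "CA"), ("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")]},
}


def _template_atoms_bonds(aa: str) -> tuple[list[tuple], list[tuple]]:
    if aa not in _SIDE_CHAINS:
        raise ResidueAlphabetError(f"unknown residue code {aa!r}")
    n_h = 1 if aa == "P" else 2
    ca_h = 2 if aa == "G" else 1
    atoms = _backbone(n_h=n_h, ca_h=ca_h) + _SIDE_CHAINS[aa][0]
    bonds = _BACKBONE_BONDS + _SIDE_CHAINS[aa][1]
    return atoms, bonds


def _bond_in_ring(aa: str, a: str, b: str, bond_type: str) -> bool:
    if bond_type == "aromatic":
        return True
    return frozenset((a, b)) in _RING_BONDS.get(aa, set())


def _assemble(sequence: PeptideSequence) -> MolecularGraph:
    nodes: list[AtomNode] = []
    edges: list[BondEdge] = []
    prev_c_index: int | None = None
    for ri, aa in enumerate(sequence.residues):
        atoms, bonds = _template_atoms_bonds(aa)
        last = ri == len(sequence.residues) - 1
        index_of: dict[str, int] = {}
        for name, elem, aromatic, hyb, n_h, role in atoms:
            if name == "OXT" and not last:
                continue  # condensed away by the next peptide bond
            if name == "N" and ri > 0:
                n_h -= 1  # amide nitrogen loses one hydrogen
            index_of[name] = len(nodes)
            nodes.append(AtomNode(
                index=len(nodes), element=_ELEMENT_NUMBERS[elem],
                aromatic=aromatic, formal_charge=0, hybridization=hyb,
                degree=0, total_hydrogens=n_h, residue_index=ri,
                backbone_role=role, name=name))
        for a, b, bt in bonds:
            if "OXT" in (a, b) and not last:
                continue
            conj = bt in ("double", "aromatic")
            edges.append(BondEdge(
                endpoints=(index_of[a], index_of[b]), bond_type=bt,
                conjugated=conj, in_ring=_bond_in_ring(aa, a, b, bt)))
        if prev_c_index is not None:
            # peptide (amide) bond: conjugated, never in a ring
            edges.append(BondEdge(endpoints=(prev_c_index, index_of["N"]),
                                  bond_type="single", conjugated=True,
                                  in_ring=False))
        prev_c_index = index_of["C"]
    for e in edges:
        a, b = e.endpoints
        nodes[a].degree += 1
        nodes[b].degree += 1
    return MolecularGraph(nodes=nodes, edges=edges, source_sequence=sequence)


def residue_template(aa: str) -> MolecularGraph:
    """Heavy-atom graph of the free amino acid ``aa`` (one-letter code)."""
    return _assemble(PeptideSequence(aa, id=aa))


def seq_to_graph(seq: PeptideSequence | str,
                 config: FeatureConfig | None = None) -> MolecularGraph:
    """Build the peptide's molecular graph by N-to-C condensation.

    ``config`` is accepted for interface parity with the embedding stage;
    the graph always carries the full attribute set and the config decides
    later which attributes are serialized into WL labels.
    """
    if isinstance(seq, str):
        seq = PeptideSequence(seq)
    return _assemble(seq)


def graph_census(g: MolecularGraph) -> dict:
    """Node/edge/ring counts and per-element composition of a graph."""
    elements: dict[int, int] = {}
    for n in g.nodes:
        elements[n.element] = elements.get(n.element, 0) + 1
    n_nodes, n_edges = len(g.nodes), len(g.edges)
    return {
        "nodes": n_nodes,
        "edges": n_edges,
        "rings": n_edges - n_nodes + 1,  # connected single-component graph
        "elements": elements,
        "aromatic_atoms": sum(n.aromatic for n in g.nodes),
    }


def graph_to_tables(g: MolecularGraph):
    """Node and edge tables (pandas DataFrames) for TSV export."""
    import pandas as pd

    node_rows = [vars(n) for n in g.nodes]
    edge_rows = [{"source": e.endpoints[0], "target": e.endpoints[1],
                  "bond_type": e.bond_type, "conjugated": e.conjugated,
                  "in_ring": e.in_ring, "stereo": e.stereo} for e in g.edges]
    return pd.DataFrame(node_rows), pd.DataFrame(edge_rows)
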