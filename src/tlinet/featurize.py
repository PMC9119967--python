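"""Molecular graph construction from SMILES strings and protein sequences.

Ligands and protein targets are both represented as bidirected heavy-atom
graphs: nodes are atoms, edges are chemical bonds stored explicitly in both
directions with identical feature rows. Node and edge features are
concatenations of one-hot blocks over closed categorical vocabularies
(nine atom descriptors, three bond descriptors). Hydrogens are not nodes;
they enter only through the "num_hydrogens" descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")


class SmilesParseError(ValueError):
    """The SMILES string could not be parsed into a molecule."""


class SchemaError(ValueError):
    """An atom or bond property falls outside its closed vocabulary."""


class SequenceError(ValueError):
    """A protein sequence contains characters outside the 20 standard residues."""


#: Ordered atom descriptors and their categorical vocabularies. The vocabulary
#: entries are the values produced by the corresponding RDKit atom accessors.
ATOM_DESCRIPTORS: tuple[tuple[str, tuple], ...] = (
    ("atomic_number", tuple(range(1, 120))),
    ("chirality", ("UNSPECIFIED", "TETRAHEDRAL_CW", "TETRAHEDRAL_CCW", "OTHER")),
    ("degree", tuple(range(0, 11))),
    ("formal_charge", tuple(range(-5, 6))),
    ("num_hydrogens", tuple(range(0, 9))),
    ("num_radical_electrons", tuple(range(0, 5))),
    ("hybridization", ("SP", "SP2", "SP3", "SP3D", "SP3D2")),
    ("aromaticity", (0, 1)),
    ("ring_membership", (0, 1)),
)

#: Ordered bond descriptors and vocabularies.
BOND_DESCRIPTORS: tuple[tuple[str, tuple], ...] = (
    ("bond_type", ("SINGLE", "DOUBLE", "TRIPLE", "AROMATIC")),
    ("stereochemistry", ("NONE", "Z", "E", "CIS", "TRANS", "ANY")),
    ("conjugation", (0, 1)),
)

ATOM_BLOCK_SIZES = tuple(len(v) for _, v in ATOM_DESCRIPTORS)
BOND_BLOCK_SIZES = tuple(len(v) for _, v in BOND_DESCRIPTORS)
ATOM_FEATURE_DIM = sum(ATOM_BLOCK_SIZES)  # 168
BOND_FEATURE_DIM = sum(BOND_BLOCK_SIZES)  # 12

_CHIRAL_TAGS = {
    Chem.ChiralType.CHI_UNSPECIFIED: "UNSPECIFIED",
    Chem.ChiralType.CHI_TETRAHEDRAL_CW: "TETRAHEDRAL_CW",
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW: "TETRAHEDRAL_CCW",
}

_HYBRIDIZATIONS = {
    Chem.HybridizationType.SP: "SP",
    Chem.HybridizationType.SP2: "SP2",
    Chem.HybridizationType.SP3: "SP3",
    Chem.HybridizationType.SP3D: "SP3D",
    Chem.HybridizationType.SP3D2: "SP3D2",
}

_BOND_TYPES = {
    Chem.BondType.SINGLE: "SINGLE",
    Chem.BondType.DOUBLE: "DOUBLE",
    Chem.BondType.TRIPLE: "TRIPLE",
    Chem.BondType.AROMATIC: "AROMATIC",
}

_BOND_STEREO = {
    Chem.BondStereo.STEREONONE: "NONE",
    Chem.BondStereo.STEREOZ: "Z",
    Chem.BondStereo.STEREOE: "E",
    Chem.BondStereo.STEREOCIS: "CIS",
    Chem.BondStereo.STEREOTRANS: "TRANS",
    Chem.BondStereo.STEREOANY: "ANY",
}

STANDARD_AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class MolecularGraph:
    """Bidirected molecular graph with one-hot node/edge feature matrices.

    ``directed_edges[i] = (v, u)`` means a directed edge from node ``v`` to
    node ``u``; each chemical bond contributes two consecutive rows (both
    directions, identical features). ``edge_bond_index[i]`` maps the directed
    edge back to its chemical bond.
    """

    source: str
    node_count: int
    directed_edges: np.ndarray  # (E, 2) int
    node_features: np.ndarray  # (N, ATOM_FEATURE_DIM) uint8
    edge_features: np.ndarray  # (E, BOND_FEATURE_DIM) uint8
    edge_bond_index: np.ndarray = field(default=None)  # (E,) int

    @property
    def num_bonds(self) -> int:
        return self.directed_edges.shape[0] // 2


def encode_atom(properties: dict) -> np.ndarray:
    """Encode one atom's descriptor values as a concatenated one-hot vector.

    ``properties`` maps each of the nine descriptor names to a value inside
    its vocabulary. Raises :class:`SchemaError` for out-of-vocabulary values.
    """
    return _encode(properties, ATOM_DESCRIPTORS, ATOM_FEATURE_DIM)


def encode_bond(properties: dict) -> np.ndarray:
    """Encode one bond's descriptor values; see :func:`encode_atom`."""
    return _encode(properties, BOND_DESCRIPTORS, BOND_FEATURE_DIM)


def _encode(properties, descriptors, dim) -> np.ndarray:
    vec = np.zeros(dim, dtype=np.uint8)
    offset = 0
    for name, vocab in descriptors:
        if name not in properties:
            raise SchemaError(f"missing descriptor {name!r}")
        value = properties[name]
        try:
            idx = vocab.index(value)
        except ValueError:
            raise SchemaError(
                f"value {value!r} outside the vocabulary of descriptor {name!r}"
            ) from None
        vec[offset + idx] = 1
        offset += len(vocab)
    return vec


def _atom_properties(atom: Chem.Atom) -> dict:
    tag = atom.GetChiralTag()
    hyb = atom.GetHybridization()
    if hyb not in _HYBRIDIZATIONS:
        raise SchemaError(
            f"hybridization {hyb} of atom {atom.GetIdx()} outside the vocabulary "
            "of descriptor 'hybridization'"
        )
    return {
        "atomic_number": atom.GetAtomicNum(),
        "chirality": _CHIRAL_TAGS.get(tag, "OTHER"),
        "degree": atom.GetTotalDegree(),
        "formal_charge": atom.GetFormalCharge(),
        "num_hydrogens": atom.GetTotalNumHs(),
        "num_radical_electrons": atom.GetNumRadicalElectrons(),
        "hybridization": _HYBRIDIZATIONS[hyb],
        "aromaticity": int(atom.GetIsAromatic()),
        "ring_membership": int(atom.IsInRing()),
    }


def _bond_properties(bond: Chem.Bond) -> dict:
    btype = bond.GetBondType()
    if btype not in _BOND_TYPES:
        raise SchemaError(
            f"bond type {btype} outside the vocabulary of descriptor 'bond_type'"
        )
    return {
        "bond_type": _BOND_TYPES[btype],
        "stereochemistry": _BOND_STEREO.get(bond.GetStereo(), "ANY"),
        "conjugation": int(bond.GetIsConjugated()),
    }


def mol_to_graph(mol: Chem.Mol, source: str) -> MolecularGraph:
    """Featurize an RDKit molecule (already in its canonical atom order)."""
    n = mol.GetNumAtoms()
    if n < 1:
        raise SmilesParseError(f"molecule from {source!r} has no heavy atoms")
    node_features = np.stack(
        [encode_atom(_atom_properties(a)) for a in mol.GetAtoms()]
    )
    edges, feats, bond_idx = [], [], []
    for b, bond in enumerate(mol.GetBonds()):
        row = encode_bond(_bond_properties(bond))
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.extend([(i, j), (j, i)])
        feats.extend([row, row])
        bond_idx.extend([b, b])
    directed_edges = (
        np.asarray(edges, dtype=np.int64)
        if edges
        else np.zeros((0, 2), dtype=np.int64)
    )
    edge_features = (
        np.stack(feats) if feats else np.zeros((0, BOND_FEATURE_DIM), dtype=np.uint8)
    )
    return MolecularGraph(
        source=source,
        node_count=n,
        directed_edges=directed_edges,
        node_features=node_features,
        edge_features=edge_features,
        edge_bond_index=np.asarray(bond_idx, dtype=np.int64),
    )


def canonical_mol(smiles: str) -> Chem.Mol:
    """Parse a SMILES and return the molecule re-parsed from its canonical
    form, fixing the atom order across spellings of the same structure."""
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparseable SMILES: {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    mol = Chem.MolFromSmiles(canonical)
    if mol is None:  # pragma: no cover - canonical SMILES always reparses
        raise SmilesParseError(f"canonical form failed to reparse: {canonical!r}")
    return mol


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Convert a SMILES string into a featurized bidirected molecular graph."""
    return mol_to_graph(canonical_mol(smiles), source=smiles)


def clean_sequence(sequence: str) -> str:
    """Strip FASTA headers/whitespace and validate the residue alphabet."""
    lines = [ln.strip() for ln in sequence.splitlines()]
    seq = "".join(ln for ln in lines if ln and not ln.startswith(">"))
    if not seq:
        raise SequenceError("empty protein sequence")
    bad = set(seq) - STANDARD_AMINO_ACIDS
    if bad:
        raise SequenceError(
            f"non-standard residue letter(s) {sorted(bad)} in sequence"
        )
    return seq


def fasta_to_graph(sequence: str) -> MolecularGraph:
    """Build the peptide molecule of a protein sequence and featurize it.

    The peptide is built with free N- and C-termini, no disulfides and no
    modifications; featurization is identical to :func:`smiles_to_graph`.
    """
    seq = clean_sequence(sequence)
    mol = Chem.MolFromFASTA(seq)
    if mol is None:
        raise SequenceError(f"could not build peptide for sequence {seq!r}")
    # route through canonical SMILES so node ordering matches the ligand path
    graph = smiles_to_graph(Chem.MolToSmiles(mol))
    return MolecularGraph(
        source=seq,
        node_count=graph.node_count,
        directed_edges=graph.directed_edges,
        node_features=graph.node_features,
        edge_features=graph.edge_features,
        edge_bond_index=graph.edge_bond_index,
    )


def validate_graph(graph: MolecularGraph) -> list[str]:
    """Check every structural invariant; return the violations (empty = valid)."""
    violations: list[str] = []
    n, edges = graph.node_count, graph.directed_edges
    if n < 1:
        violations.append("node_count must be >= 1")
    if graph.node_features.shape != (n, ATOM_FEATURE_DIM):
        violations.append("node_features shape mismatch")
    if graph.edge_features.shape != (len(edges), BOND_FEATURE_DIM):
        violations.append("edge_features shape mismatch")

    def check_blocks(matrix, sizes, what):
        offset = 0
        for k, size in enumerate(sizes):
            block = matrix[:, offset : offset + size]
            if not np.all(block.sum(axis=1) == 1):
                violations.append(f"{what} one-hot block {k} does not sum to 1")
            offset += size

    if graph.node_features.shape == (n, ATOM_FEATURE_DIM) and n:
        check_blocks(graph.node_features, ATOM_BLOCK_SIZES, "node")
    if graph.edge_features.shape == (len(edges), BOND_FEATURE_DIM) and len(edges):
        check_blocks(graph.edge_features, BOND_BLOCK_SIZES, "edge")

    if len(edges):
        if edges.min() < 0 or edges.max() >= n:
            violations.append("edge endpoint outside [0, node_count)")
        if np.any(edges[:, 0] == edges[:, 1]):
            violations.append("self-loop present")
        index = {(int(v), int(u)): i for i, (v, u) in enumerate(edges)}
        for i, (v, u) in enumerate(edges):
            j = index.get((int(u), int(v)))
            if j is None:
                violations.append(
                    f"bidirectionality violated: reverse of edge ({v},{u}) missing"
                )
            elif not np.array_equal(graph.edge_features[i], graph.edge_features[j]):
                violations.append(
                    f"bidirectionality violated: edge ({v},{u}) features differ "
                    "from reverse"
                )
    return violations
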