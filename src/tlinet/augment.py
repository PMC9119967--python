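"""Biologically-bounded adversarial molecule augmentation.

An augmented molecule is the original with one chemical bond deleted. A
binary coefficient (value 1) is attached to every bond and multiplies its
edge feature vector during graph construction; this leaves the model
output unchanged but makes the gradient of the training loss with respect
to each coefficient available through backpropagation. Bonds whose
coefficient gradient is negative are deletion candidates — removing them
moves the prediction toward the molecule's label — and are tried from most
negative to least.

The deletion is biologically bounded: the candidate is accepted only if
the augmented molecule stays within a distance ``mu`` of the Bemis-Murcko
scaffold of the original, where distance is

    d(M_s, M') = 1 - RGS(M_s, M')

over Morgan fingerprints, RGS being the Rogot-Goldberg similarity. ``mu``
is calibrated as the largest distance from a training active to its own
scaffold. Candidates whose deletion yields a chemically unrepresentable
structure, or exceed ``mu``, are skipped; if no candidate qualifies, no
augmentation is produced for that molecule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem.Scaffolds import MurckoScaffold

from . import autodiff as ad
from .featurize import MolecularGraph, canonical_mol, mol_to_graph
from .gcn import GraphBatch
from .model import FusionParams, bce_loss, ligand_only_logits


@dataclass(frozen=True)
class AugmentationConfig:
    """Distance threshold and fingerprint parameters."""

    mu: float | None = None
    fp_radius: int = 2
    fp_nbits: int = 2048


@dataclass(frozen=True)
class ScaffoldRef:
    """A molecule's Bemis-Murcko scaffold and the scaffold's fingerprint."""

    scaffold_smiles: str
    fingerprint: np.ndarray | None  # None when the scaffold is empty (acyclic)

    @property
    def empty(self) -> bool:
        return self.fingerprint is None


@dataclass(frozen=True)
class AugmentationResult:
    original_smiles: str
    augmented_smiles: str
    deleted_bond: tuple[int, int]  # atom indices in the canonical molecule
    gradient: float
    distance: float


def murcko_scaffold(mol_or_smiles) -> Chem.Mol:
    """Bemis-Murcko scaffold: ring systems plus linkers, side chains removed.

    Acyclic molecules yield an empty (zero-atom) molecule.
    """
    mol = _as_mol(mol_or_smiles)
    return MurckoScaffold.GetScaffoldForMol(mol)


def morgan_fp(mol_or_smiles, radius: int = 2, nbits: int = 2048) -> np.ndarray:
    """Morgan (circular-substructure, hashed) fingerprint as a 0/1 vector."""
    mol = _as_mol(mol_or_smiles)
    bv = AllChem.GetMorganFingerprintAsBitVect(mol, radius, nBits=nbits)
    arr = np.zeros(nbits, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return arr


def _as_mol(mol_or_smiles) -> Chem.Mol:
    if isinstance(mol_or_smiles, Chem.Mol):
        return mol_or_smiles
    return canonical_mol(mol_or_smiles)


def rogot_goldberg(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Rogot-Goldberg similarity of two equal-length binary fingerprints.

    With a = common on-bits, b/c = bits on in only one vector, d0 = common
    off-bits: RGS = a/(2a+b+c) + d0/(2d0+b+c). Identical vectors score
    exactly 1; a term with zero denominator otherwise contributes 0.
    """
    fp_a = np.asarray(fp_a, dtype=bool)
    fp_b = np.asarray(fp_b, dtype=bool)
    if fp_a.shape != fp_b.shape:
        raise ValueError("fingerprint length mismatch")
    if np.array_equal(fp_a, fp_b):
        return 1.0
    a = int(np.sum(fp_a & fp_b))
    b = int(np.sum(fp_a & ~fp_b))
    c = int(np.sum(~fp_a & fp_b))
    d0 = int(np.sum(~fp_a & ~fp_b))
    total = 0.0
    if 2 * a + b + c > 0:
        total += a / (2 * a + b + c)
    if 2 * d0 + b + c > 0:
        total += d0 / (2 * d0 + b + c)
    return total


def scaffold_ref(mol_or_smiles, config: AugmentationConfig = AugmentationConfig()) -> ScaffoldRef:
    """Compute a molecule's scaffold reference for distance bounding."""
    scaffold = murcko_scaffold(mol_or_smiles)
    smiles = Chem.MolToSmiles(scaffold)
    if scaffold.GetNumAtoms() == 0:
        return ScaffoldRef(scaffold_smiles=smiles, fingerprint=None)
    return ScaffoldRef(
        scaffold_smiles=smiles,
        fingerprint=morgan_fp(scaffold, config.fp_radius, config.fp_nbits),
    )


def scaffold_distance(
    augmented, ref: ScaffoldRef, config: AugmentationConfig = AugmentationConfig()
) -> float:
    """d(M_s, M') = 1 - RGS between the scaffold and the augmented molecule."""
    if ref.empty:
        raise ValueError("scaffold is empty (acyclic molecule); distance undefined")
    fp = morgan_fp(augmented, config.fp_radius, config.fp_nbits)
    return 1.0 - rogot_goldberg(ref.fingerprint, fp)


def calibrate_mu(
    actives: list[str], config: AugmentationConfig = AugmentationConfig()
) -> tuple[float, list[str]]:
    """Threshold mu = largest distance from an active to its own scaffold.

    Acyclic actives (empty scaffold) are excluded from the maximum and
    returned in the second element for logging.
    """
    if not actives:
        raise ValueError("cannot calibrate mu on an empty active set")
    distances, skipped = [], []
    for smiles in actives:
        ref = scaffold_ref(smiles, config)
        if ref.empty:
            skipped.append(smiles)
            continue
        distances.append(scaffold_distance(smiles, ref, config))
    if not distances:
        raise ValueError("all active scaffolds are empty; mu cannot be calibrated")
    return max(distances), skipped


@dataclass(frozen=True)
class EdgeCoefficients:
    """Per chemical bond: coefficient (1) and its loss gradient."""

    bond_atoms: list[tuple[int, int]]  # begin/end atom index per bond
    gradients: np.ndarray  # (num_bonds,)


def edge_gradients(
    params: FusionParams, graph: MolecularGraph, label: int = 1
) -> EdgeCoefficients:
    """Loss gradient of every bond's binary coefficient (at value 1).

    The coefficient multiplies both directed-edge feature rows of its bond;
    the bond gradient is the sum of the two directed-edge gradients.
    The training loss (binary cross-entropy at ``label``) is used, so for
    actives a negative gradient marks a bond whose deletion decreases the
    loss — the adversarial direction.
    """
    batch = GraphBatch.from_graphs([graph])
    coeffs = ad.parameter(np.ones((batch.edges.shape[0], 1)))
    logits, _ = ligand_only_logits(batch, params, edge_coeffs=coeffs)
    loss = bce_loss(logits, np.array([label]))
    loss.backward()
    per_edge = coeffs.grad[:, 0]
    num_bonds = graph.num_bonds
    grads = np.zeros(num_bonds)
    np.add.at(grads, graph.edge_bond_index, per_edge)
    bond_atoms = [
        (int(graph.directed_edges[2 * b, 0]), int(graph.directed_edges[2 * b, 1]))
        for b in range(num_bonds)
    ]
    return EdgeCoefficients(bond_atoms=bond_atoms, gradients=grads)


def delete_bond(mol: Chem.Mol, atom_i: int, atom_j: int) -> Chem.Mol | None:
    """Remove the bond between two atoms; None if the result cannot be
    chemically re-perceived (sanitization failure)."""
    rw = Chem.RWMol(mol)
    if rw.GetBondBetweenAtoms(atom_i, atom_j) is None:
        return None
    rw.RemoveBond(atom_i, atom_j)
    try:
        out = rw.GetMol()
        Chem.SanitizeMol(out)
    except Exception:
        return None
    if out.GetNumAtoms() == 0:
        return None
    return out


def select_and_delete(
    smiles: str,
    coefficients: EdgeCoefficients,
    ref: ScaffoldRef,
    mu: float,
    config: AugmentationConfig = AugmentationConfig(),
) -> AugmentationResult | None:
    """Pick and delete the admissible bond with the most negative gradient.

    Bonds with negative gradient are tried in ascending gradient order
    (ties by bond index). A candidate is accepted when the deletion is
    chemically representable and d(M_s, M') <= mu; otherwise the next
    candidate is tried. Returns None when no candidate qualifies (including
    molecules with an empty scaffold).
    """
    if ref.empty:
        return None
    mol = canonical_mol(smiles)
    grads = coefficients.gradients
    order = np.lexsort((np.arange(len(grads)), grads))
    for b in order:
        g = grads[b]
        if g >= 0:
            break  # ascending order: no negative candidates remain
        i, j = coefficients.bond_atoms[b]
        candidate = delete_bond(mol, i, j)
        if candidate is None:
            continue
        distance = scaffold_distance(candidate, ref, config)
        if distance <= mu:
            return AugmentationResult(
                original_smiles=Chem.MolToSmiles(mol),
                augmented_smiles=Chem.MolToSmiles(candidate),
                deleted_bond=(i, j),
                gradient=float(g),
                distance=distance,
            )
    return None


def augment_molecule(
    params: FusionParams,
    smiles: str,
    mu: float,
    config: AugmentationConfig = AugmentationConfig(),
    label: int = 1,
) -> AugmentationResult | None:
    """Full augmentation of one active: gradients, selection, deletion."""
    from .featurize import smiles_to_graph

    graph = smiles_to_graph(smiles)
    ref = scaffold_ref(smiles, config)
    if ref.empty:
        return None
    coeffs = edge_gradients(params, graph, label=label)
    return select_and_delete(smiles, coeffs, ref, mu, config)


def augment_batch(
    params: FusionParams,
    actives: list[str],
    mu: float,
    config: AugmentationConfig = AugmentationConfig(),
) -> list[AugmentationResult]:
    """Attempt one augmentation per active; return the successes.

    Augmented molecules are labeled active and appended to the training
    batch alongside the originals by the training loop.
    """
    results = []
    for smiles in actives:
        result = augment_molecule(params, smiles, mu, config)
        if result is not None:
            results.append(result)
    return results
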