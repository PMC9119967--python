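"""Synthetic desk-scale active/decoy benchmarks with known ground truth.

Generated datasets emulate the structure of per-target active/decoy
screening sets: actives share a Bemis-Murcko scaffold and carry a
label-determining functional motif (by default a carboxylate-bearing side
chain on a fused bicyclic core) plus random small substituents; decoys are
either property-matched molecules built on other scaffolds (easy split) or
molecules on the same scaffold lacking the motif (hard split). Because the
motif is a perfect label indicator, a trivial substructure-match oracle
achieves AP 1.0 on every generated benchmark — so a learning failure on
these fixtures indicates a model bug, not data noise. The motif atom
indices of every active are recorded so saliency maps can be scored
against a planted ground truth.

Proteins are short synthetic peptides (8-30 residues): the protein module
is exercised for correctness at desk scale, not for biology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .data import CurationReport, TLIDataset
from .featurize import STANDARD_AMINO_ACIDS

#: Fused bicyclic default core: single-bond deletions can sever the motif,
#: giving the augmentation engine meaningful candidates.
DEFAULT_SCAFFOLD = "c1ccc2ccccc2c1"
#: Carboxylate-bearing side chain; attached through its first carbon.
DEFAULT_MOTIF = "CC(=O)O"

_DECOY_SCAFFOLDS = (
    "c1ccccc1",
    "c1ccncc1",
    "C1CCCCC1",
    "c1ccc2[nH]ccc2c1",
    "c1ccoc1",
    "C1CCNCC1",
    "c1ccsc1",
)

_SUBSTITUENTS = ("F", "Cl", "C", "O", "N", "CC", "OC")


@dataclass(frozen=True)
class FixtureSpec:
    scaffold_smiles: str = DEFAULT_SCAFFOLD
    motif_smiles: str = DEFAULT_MOTIF
    n_actives: int = 40
    n_decoys: int = 40
    hard_split: bool = False
    max_heavy_atoms: int = 40
    seed: int = 0

    def __post_init__(self):
        if Chem.MolFromSmiles(self.scaffold_smiles) is None:
            raise ValueError(f"unparseable scaffold {self.scaffold_smiles!r}")
        if Chem.MolFromSmiles(self.motif_smiles) is None:
            raise ValueError(f"unparseable motif {self.motif_smiles!r}")
        if self.n_actives < 4 or self.n_decoys < 4:
            raise ValueError("n_actives and n_decoys must both be >= 4")


@dataclass
class Benchmark:
    """A generated dataset with its planted ground truth."""

    dataset: TLIDataset
    motif_atoms: dict[str, tuple[int, ...]]  # canonical SMILES -> atom indices
    protein_sequence: str
    spec: FixtureSpec = None


def _attachment_sites(mol: Chem.Mol) -> list[int]:
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetTotalNumHs() > 0 and a.GetAtomicNum() == 6
    ]


def _attach(mol: Chem.Mol, site: int, fragment_smiles: str) -> Chem.Mol | None:
    frag = Chem.MolFromSmiles(fragment_smiles)
    combo = Chem.RWMol(Chem.CombineMols(mol, frag))
    combo.AddBond(site, mol.GetNumAtoms(), Chem.BondType.SINGLE)
    try:
        out = combo.GetMol()
        Chem.SanitizeMol(out)
        return out
    except Exception:
        return None


def _decorate(
    scaffold: str,
    rng: np.random.Generator,
    fragments: list[str],
    max_heavy_atoms: int,
) -> str | None:
    mol = Chem.MolFromSmiles(scaffold)
    for frag in fragments:
        frag_mol = Chem.MolFromSmiles(frag)
        if mol.GetNumAtoms() + frag_mol.GetNumAtoms() > max_heavy_atoms:
            return None
        sites = _attachment_sites(mol)
        if not sites:
            return None
        new = _attach(mol, int(rng.choice(sites)), frag)
        if new is None:
            return None
        mol = new
    return Chem.MolToSmiles(mol)


def generate_benchmark(spec: FixtureSpec) -> Benchmark:
    """Generate a deterministic active/decoy benchmark from a spec."""
    rng = np.random.default_rng(spec.seed)
    motif_query = Chem.MolFromSmiles(spec.motif_smiles)

    seen: set[str] = set()
    actives: list[str] = []
    motif_atoms: dict[str, tuple[int, ...]] = {}
    attempts = 0
    while len(actives) < spec.n_actives:
        attempts += 1
        if attempts > 200 * spec.n_actives:
            raise ValueError(
                "could not generate enough distinct actives within the atom budget"
            )
        n_extra = int(rng.integers(0, 3))
        fragments = [spec.motif_smiles] + [
            str(rng.choice(_SUBSTITUENTS)) for _ in range(n_extra)
        ]
        smiles = _decorate(spec.scaffold_smiles, rng, fragments, spec.max_heavy_atoms)
        if smiles is None or smiles in seen:
            continue
        mol = Chem.MolFromSmiles(smiles)
        match = mol.GetSubstructMatch(motif_query)
        if not match:
            continue
        seen.add(smiles)
        actives.append(smiles)
        motif_atoms[smiles] = tuple(int(i) for i in match)

    decoys: list[str] = []
    attempts = 0
    while len(decoys) < spec.n_decoys:
        attempts += 1
        if attempts > 200 * spec.n_decoys:
            raise ValueError(
                "could not generate enough distinct decoys within the atom budget"
            )
        if spec.hard_split:
            scaffold = spec.scaffold_smiles
            n_extra = int(rng.integers(1, 4))
        else:
            scaffold = str(rng.choice(_DECOY_SCAFFOLDS))
            n_extra = int(rng.integers(1, 5))
        fragments = [str(rng.choice(_SUBSTITUENTS)) for _ in range(n_extra)]
        smiles = _decorate(scaffold, rng, fragments, spec.max_heavy_atoms)
        if smiles is None or smiles in seen:
            continue
        mol = Chem.MolFromSmiles(smiles)
        if mol.GetSubstructMatch(motif_query):
            continue  # a decoy must never contain the motif
        seen.add(smiles)
        decoys.append(smiles)

    records = [(s, 1) for s in actives] + [(s, 0) for s in decoys]
    length = int(rng.integers(8, 31))
    letters = sorted(STANDARD_AMINO_ACIDS)
    sequence = "".join(str(rng.choice(letters)) for _ in range(length))
    dataset = TLIDataset(target_id=f"synthetic-{spec.seed}", records=records)
    return Benchmark(
        dataset=dataset,
        motif_atoms=motif_atoms,
        protein_sequence=sequence,
        spec=spec,
    )


def motif_oracle_scores(benchmark: Benchmark) -> np.ndarray:
    """Scores of the trivial substructure-match oracle classifier (0/1)."""
    query = Chem.MolFromSmiles(benchmark.spec.motif_smiles)
    scores = []
    for smiles, _ in benchmark.dataset.records:
        mol = Chem.MolFromSmiles(smiles)
        scores.append(1.0 if mol.GetSubstructMatch(query) else 0.0)
    return np.array(scores)


def generate_duplicates_fixture(
    base: TLIDataset, n_dups: int, n_conflicts: int, seed: int = 0
) -> tuple[list[tuple[str, int]], CurationReport]:
    """Plant exact duplicates and label conflicts with known counts.

    Returns the corrupted raw record list and the curation report the
    curation step is expected to produce on it. Conflicted molecules are
    chosen disjoint from duplicated ones so each conflict removes exactly
    its two records.
    """
    rng = np.random.default_rng(seed)
    records = list(base.records)
    n_records = len(records)
    if n_conflicts > n_records:
        raise ValueError("more conflicts requested than available records")
    conflict_idx = rng.choice(n_records, size=n_conflicts, replace=False)
    conflict_set = set(int(i) for i in conflict_idx)
    dup_pool = [i for i in range(n_records) if i not in conflict_set]
    if n_dups > 0 and not dup_pool:
        raise ValueError("no records available for duplication")

    corrupted = list(records)
    for _ in range(n_dups):
        corrupted.append(records[int(rng.choice(dup_pool))])
    for i in conflict_set:
        smiles, label = records[i]
        corrupted.append((smiles, 1 - label))
    order = rng.permutation(len(corrupted))
    corrupted = [corrupted[i] for i in order]

    expected = CurationReport(
        records_in=len(corrupted),
        records_out=n_records - n_conflicts,
        duplicates_removed=n_dups,
        variably_labeled_removed=2 * n_conflicts,
        unparseable_removed=0,
        variably_labeled_molecules=n_conflicts,
        removed_fraction=(n_dups + 2 * n_conflicts) / len(corrupted) if corrupted else 0.0,
    )
    return corrupted, expected
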