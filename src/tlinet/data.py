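"""Dataset curation, splitting, screening and similarity diagnostics.

Per-target active/decoy record sets are curated by canonicalizing SMILES,
dropping exact duplicate (molecule, label) records, and dropping entirely
any molecule labeled both active and decoy for the same target —
contradictory and redundant records bias training. Splits are stratified
and deterministic under a seed. Virtual screening scores a molecule
library with a trained model, excludes training-set members, and reports
the top hits with their mean Rogot-Goldberg similarity to the training
actives.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .augment import AugmentationConfig, morgan_fp, rogot_goldberg
from .featurize import SmilesParseError, canonical_mol


@dataclass
class TLIDataset:
    """Curated per-target records with split assignments."""

    target_id: str
    records: list[tuple[str, int]]  # (canonical SMILES, label) label 1=active
    train_indices: np.ndarray | None = None
    test_indices: np.ndarray | None = None
    fold_assignments: np.ndarray | None = None

    @property
    def smiles(self) -> list[str]:
        return [s for s, _ in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([y for _, y in self.records])

    def subset(self, indices) -> list[tuple[str, int]]:
        return [self.records[i] for i in indices]

    def train_records(self) -> list[tuple[str, int]]:
        if self.train_indices is None:
            return list(self.records)
        return self.subset(self.train_indices)

    def test_records(self) -> list[tuple[str, int]]:
        if self.test_indices is None:
            return []
        return self.subset(self.test_indices)


@dataclass
class CurationReport:
    """Counts of records removed by each curation rule."""

    records_in: int = 0
    records_out: int = 0
    duplicates_removed: int = 0
    variably_labeled_removed: int = 0
    unparseable_removed: int = 0
    variably_labeled_molecules: int = 0
    removed_fraction: float = 0.0
    dropped_smiles: list[str] = field(default_factory=list)

    def conserved(self) -> bool:
        return self.records_in == (
            self.records_out
            + self.duplicates_removed
            + self.variably_labeled_removed
            + self.unparseable_removed
        )


def _normalize_label(label) -> int:
    if label in (1, "1", "active", "Active", True):
        return 1
    if label in (0, "0", "decoy", "Decoy", False):
        return 0
    raise ValueError(f"unrecognized label {label!r}")


def curate(
    records: list[tuple[str, object]], target_id: str = "target"
) -> tuple[TLIDataset, CurationReport]:
    """Curate raw (SMILES, label) records for one target.

    Canonicalizes each SMILES; unparseable entries are dropped and counted;
    duplicate (canonical SMILES, label) records beyond the first are
    dropped; molecules carrying both labels are removed entirely.
    """
    report = CurationReport(records_in=len(records))
    canonical: list[tuple[str, int]] = []
    for smiles, label in records:
        try:
            mol = canonical_mol(smiles)
        except SmilesParseError:
            report.unparseable_removed += 1
            report.dropped_smiles.append(smiles)
            continue
        canonical.append((Chem.MolToSmiles(mol), _normalize_label(label)))

    label_sets: dict[str, set[int]] = {}
    for smiles, label in canonical:
        label_sets.setdefault(smiles, set()).add(label)
    conflicted = {s for s, ls in label_sets.items() if len(ls) > 1}
    report.variably_labeled_molecules = len(conflicted)

    seen: set[tuple[str, int]] = set()
    kept: list[tuple[str, int]] = []
    for smiles, label in canonical:
        if smiles in conflicted:
            report.variably_labeled_removed += 1
            continue
        if (smiles, label) in seen:
            report.duplicates_removed += 1
            continue
        seen.add((smiles, label))
        kept.append((smiles, label))

    report.records_out = len(kept)
    if report.records_in:
        report.removed_fraction = (
            report.records_in - report.records_out
        ) / report.records_in
    return TLIDataset(target_id=target_id, records=kept), report


def split(dataset: TLIDataset, test_fraction: float = 0.10, seed: int = 0) -> TLIDataset:
    """Stratified train/test assignment, deterministic under ``seed``."""
    labels = dataset.labels
    for cls in (0, 1):
        if int((labels == cls).sum()) < 2:
            raise ValueError(f"class {cls} has fewer than 2 records; cannot split")
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        n_test = int(round(test_fraction * len(idx)))
        n_test = min(max(n_test, 1), len(idx) - 1)
        test_idx.extend(rng.permutation(idx)[:n_test].tolist())
    test = np.array(sorted(test_idx))
    train = np.array([i for i in range(len(dataset.records)) if i not in set(test_idx)])
    dataset.train_indices = train
    dataset.test_indices = test
    return dataset


def stratified_folds(labels: np.ndarray, folds: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment (0..folds-1 per record)."""
    rng = np.random.default_rng(seed)
    assignment = np.full(len(labels), -1)
    for cls in np.unique(labels):
        idx = rng.permutation(np.flatnonzero(labels == cls))
        for k, i in enumerate(idx):
            assignment[i] = k % folds
    return assignment


def mean_rgs_to_actives(
    smiles: str, actives: list[str], config: AugmentationConfig = AugmentationConfig()
) -> float:
    """Mean Rogot-Goldberg similarity of a molecule to a set of actives."""
    if not actives:
        raise ValueError("empty active set")
    fp = morgan_fp(smiles, config.fp_radius, config.fp_nbits)
    sims = [
        rogot_goldberg(fp, morgan_fp(a, config.fp_radius, config.fp_nbits))
        for a in actives
    ]
    return float(np.mean(sims))


@dataclass
class ScreeningResult:
    """Top-ranked screening hits with similarity diagnostics."""

    hits: list[tuple[str, float]]  # (canonical SMILES, probability), descending
    mean_rgs: list[float]  # per hit, similarity to the training actives
    excluded_unparseable: list[str] = field(default_factory=list)
    excluded_training: list[str] = field(default_factory=list)


def screen(
    score_fn,
    library: list[str],
    training_smiles: list[str],
    training_actives: list[str],
    top_n: int = 5,
    config: AugmentationConfig = AugmentationConfig(),
) -> ScreeningResult:
    """Virtual screening of a SMILES library against one target.

    ``score_fn(canonical_smiles) -> probability`` wraps the trained model.
    Unparseable entries and members of the training set (compared by
    canonical SMILES) are excluded and logged. Returns the ``top_n``
    highest-probability candidates (fewer when the library is small) with
    their mean Rogot-Goldberg similarity to the training actives.
    """
    training_set = {Chem.MolToSmiles(canonical_mol(s)) for s in training_smiles}
    result = ScreeningResult(hits=[], mean_rgs=[])
    candidates: list[str] = []
    seen: set[str] = set()
    for smiles in library:
        try:
            canonical = Chem.MolToSmiles(canonical_mol(smiles))
        except SmilesParseError:
            result.excluded_unparseable.append(smiles)
            continue
        if canonical in training_set:
            result.excluded_training.append(smiles)
            continue
        if canonical not in seen:
            seen.add(canonical)
            candidates.append(canonical)
    if not candidates:
        raise ValueError("no screenable candidates after filtering")
    scored = [(s, float(score_fn(s))) for s in candidates]
    scored.sort(key=lambda t: -t[1])
    result.hits = scored[:top_n]
    result.mean_rgs = [
        mean_rgs_to_actives(s, training_actives, config) for s, _ in result.hits
    ]
    return result


# --------------------------------------------------------------------------
# on-disk layouts


def load_smiles_csv(path: str) -> list[tuple[str, object]]:
    """Read a ``smiles,label`` CSV (header optional) into raw records."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "smiles" not in cols or "label" not in cols:
        raise ValueError(f"{path}: expected columns 'smiles' and 'label'")
    return list(zip(df[cols["smiles"]].astype(str), df[cols["label"]]))


def load_ad_layout(directory: str) -> dict[str, list[tuple[str, object]]]:
    """Read a per-target actives/decoys directory layout.

    Each target is a subdirectory containing ``actives.smi`` and
    ``decoys.smi`` (one SMILES per line), the layout used by per-target
    active/decoy benchmarks.
    """
    targets: dict[str, list[tuple[str, object]]] = {}
    for name in sorted(os.listdir(directory)):
        tdir = os.path.join(directory, name)
        if not os.path.isdir(tdir):
            continue
        records: list[tuple[str, object]] = []
        for fname, label in (("actives.smi", 1), ("decoys.smi", 0)):
            fpath = os.path.join(tdir, fname)
            if not os.path.exists(fpath):
                continue
            with open(fpath) as fh:
                for line in fh:
                    token = line.split()[0] if line.split() else ""
                    if token:
                        records.append((token, label))
        if records:
            targets[name] = records
    if not targets:
        raise ValueError(f"no target subdirectories with .smi files under {directory}")
    return targets


def duplicate_summary(all_records: dict[str, list[tuple[str, object]]]) -> dict:
    """Global and per-target duplicate counts across a multi-target set."""
    per_target = {}
    global_counter: Counter = Counter()
    for target, records in all_records.items():
        counter = Counter(records)
        per_target[target] = sum(c - 1 for c in counter.values())
        global_counter.update(counter.keys())
    return {
        "per_target_duplicate_sum": int(sum(per_target.values())),
        "per_target": per_target,
        "global_unique_records": len(global_counter),
    }
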