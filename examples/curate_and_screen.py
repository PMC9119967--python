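"""Curate a corrupted active/decoy set, then screen a molecule library.

Curation canonicalizes SMILES, removes exact duplicates and molecules
labeled both active and decoy. Screening scores library molecules with a
trained model, excludes training-set members, and reports the top hits
with their mean Rogot-Goldberg similarity to the training actives.
"""

from tlinet import (
    curate, fasta_to_graph, predict_ligand_only, screen, smiles_to_graph, split,
)
from tlinet.curriculum import DESK_BATCH_SIZE, StageConfig, run_curriculum
from tlinet.synth import FixtureSpec, generate_benchmark, generate_duplicates_fixture

benchmark = generate_benchmark(FixtureSpec(n_actives=20, n_decoys=20, seed=7))
corrupted, _ = generate_duplicates_fixture(benchmark.dataset, n_dups=4, n_conflicts=1, seed=0)
dataset, report = curate(corrupted)
print(f"curation: {report.records_in} in -> {report.records_out} out "
      f"({report.duplicates_removed} duplicates, "
      f"{report.variably_labeled_removed} variably-labeled records removed)")

dataset = split(dataset, seed=0)
protein = fasta_to_graph(benchmark.protein_sequence)
params, _ = run_curriculum(
    dataset, protein, stages=[StageConfig("LM", 25, 5e-3)], seed=0,
    batch_size=DESK_BATCH_SIZE,
)

library = [s for s, _ in benchmark.dataset.records] + [
    "c1ccc2ccccc2c1CCC(=O)O",  # unseen motif-bearing molecule
    "c1ccc2ccccc2c1CCO",       # unseen scaffold without the motif
    "this_is_not_a_smiles",
]
train_smiles = [s for s, _ in dataset.train_records()]
train_actives = [s for s, y in dataset.train_records() if y == 1]
result = screen(
    lambda s: predict_ligand_only(smiles_to_graph(s), params).probability,
    library, train_smiles, train_actives, top_n=5,
)
print(f"excluded: {len(result.excluded_training)} training members, "
      f"{len(result.excluded_unparseable)} unparseable")
print("top hits (probability, mean RGS to training actives):")
for (smiles, prob), rgs in zip(result.hits, result.mean_rgs):
    print(f"  {prob:.3f}  {rgs:.3f}  {smiles}")
# High-probability hits carrying the motif and high similarity to the
# training actives are the screening candidates a practitioner would
# inspect first.
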