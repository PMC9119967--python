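"""Generate biologically-bounded adversarial molecule augmentations.

For each active, the bond whose binary coefficient has the most negative
loss gradient is deleted, provided the result stays within the calibrated
Rogot-Goldberg distance mu of the molecule's Bemis-Murcko scaffold.
"""

from tlinet import FusionParams, augment_batch, calibrate_mu, fasta_to_graph, split
from tlinet.curriculum import DESK_BATCH_SIZE, StageConfig, run_curriculum
from tlinet.synth import FixtureSpec, generate_benchmark

benchmark = generate_benchmark(FixtureSpec(n_actives=20, n_decoys=20, seed=7))
dataset = split(benchmark.dataset, seed=0)
protein = fasta_to_graph(benchmark.protein_sequence)
params, _ = run_curriculum(
    dataset, protein, stages=[StageConfig("LM", 15, 5e-3)], seed=0,
    batch_size=DESK_BATCH_SIZE,
)

actives = [s for s, y in dataset.train_records() if y == 1]
mu, skipped = calibrate_mu(actives)
print(f"mu = {mu:.4f} (largest active-to-own-scaffold distance, "
      f"{len(skipped)} acyclic molecules excluded)")

for r in augment_batch(params, actives, mu)[:5]:
    print(f"  deleted bond {r.deleted_bond} (gradient {r.gradient:+.2e}, "
          f"scaffold distance {r.distance:.3f})")
    print(f"    {r.original_smiles} -> {r.augmented_smiles}")
# Every retained augmentation removes exactly one bond, had a strictly
# negative gradient, and stays within mu of the original's scaffold.
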