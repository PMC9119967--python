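"""Gradient saliency: which atoms drive an interaction prediction.

After brief training, the per-atom gradient of the loss at the active
label is computed; the most negative scores mark the atoms the model
relies on. On the synthetic benchmark the planted carboxylate motif
should dominate the top ranks.
"""

from tlinet import fasta_to_graph, saliency, smiles_to_graph, split
from tlinet.curriculum import DESK_BATCH_SIZE, StageConfig, run_curriculum
from tlinet.synth import FixtureSpec, generate_benchmark

benchmark = generate_benchmark(FixtureSpec(n_actives=20, n_decoys=20, seed=7))
dataset = split(benchmark.dataset, seed=0)
protein = fasta_to_graph(benchmark.protein_sequence)
params, _ = run_curriculum(
    dataset, protein, stages=[StageConfig("LM", 25, 5e-3)], seed=0,
    batch_size=DESK_BATCH_SIZE,
)

hits = total = 0
for smiles, label in dataset.test_records():
    if label != 1:
        continue
    motif = set(benchmark.motif_atoms[smiles])
    sal = saliency(smiles_to_graph(smiles), None, params, label=1)
    top = set(sal.top(len(motif)).tolist())
    overlap = len(top & motif)
    hits += overlap
    total += len(motif)
    print(f"  {smiles}: top-{len(motif)} atoms {sorted(top)}, "
          f"motif atoms {sorted(motif)}, overlap {overlap}/{len(motif)}")
print(f"overall motif recovery in top ranks: {hits}/{total}")
# An overlap well above len(motif)/n_atoms per molecule shows the model's
# attention concentrates on the label-determining substructure.
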