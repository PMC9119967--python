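# Methods

## Graph representation

Molecules (from SMILES) and proteins (peptides built from their
amino-acid sequence) are heavy-atom graphs. Hydrogens are not nodes;
they enter through the per-atom hydrogen-count descriptor. Every
chemical bond is stored as two directed edges with identical feature
rows, which makes the bidirectionality invariant directly testable and
lets message passing treat the edge list as flat.

Atom features are nine one-hot blocks over closed vocabularies
(sizes 119, 4, 11, 11, 9, 5, 5, 2, 2 — atomic number 1–119, chirality,
total degree 0–10, formal charge −5…+5, hydrogens 0–8, radical
electrons 0–4, hybridization SP…SP3D2, aromaticity, ring membership);
bond features are three blocks (sizes 4, 6, 2 — bond type, stereo,
conjugation). A value outside its vocabulary raises a schema error
rather than being clamped: the vocabularies are closed by design and
silent clamping would hide data problems. Inputs are canonicalized
before featurization, so any SMILES spelling of the same structure
yields an identical graph (fixed node order, deterministic matrices).

Protein graphs impose no size limit; resource control is left to the
caller. Peptides are built with free N- and C-termini, no disulfides,
no modifications — sequence-level chemistry only.

## Network

Both modules share one architecture: a linear projection of the
concatenated one-hot vectors to the hidden width (a single projection,
not per-descriptor embedding tables, because the concatenated one-hot
vector *is* the feature representation), then `num_layers`
pre-activation residual blocks, then pooling. Message construction is
`ReLU(h_u + x_e) + eps` with `eps = 1e-7` — the form used by the deep-GCN
family this architecture follows; the aggregation is a feature-wise
softmax with one learnable scalar inverse temperature per layer,
initialized at 1 (0 gives the mean, large values the max; a power-mean
variant is included as a reference alternative). The update MLP is
linear → batch norm → ReLU → linear with hidden width
`2 × hidden_dim`. Batch normalization uses batch statistics during
training and frozen running statistics in evaluation, so evaluation is
fully deterministic. Dropout defaults to 0.

Dilated k-NN neighborhoods (rank all other nodes by Euclidean distance
in the current embedding space, ties by node index, keep every d-th of
the first k·d) are implemented but disabled by default: message passing
follows chemical bonds, and the rewiring is exposed as a configuration
option for receptive-field experiments. Rewired edges carry zero edge
features.

The fused model concatenates the pooled ligand embedding with
`alpha ×` the pooled protein embedding. Placing the gate on the
embedding is mathematically equivalent to scaling the protein-associated
merge weights and is simpler to test. `alpha` starts at 0 so protein
information enters smoothly; the ligand-only stages use a separate
classifier head that is discarded at fusion. The final fusion stage
trains only the merge and classification layers; the two module
backbones and the gate (carried over from joint training) stay frozen —
the published schedule names only the fully connected and classification
layers for this step, and freezing the rest makes that reading explicit.
The output head is a single logit with a logistic link trained by
unweighted binary cross-entropy (the task is binary active/decoy).

Because no tensor framework is a dependency, the package ships a small
reverse-mode autodiff engine over numpy arrays (`tlinet.autodiff`):
tape-based, with the dozen primitives the model needs (broadcasting
arithmetic, matmul, relu/sigmoid/exp/log/sqrt, reductions, row gather,
segment sum/softmax). Gradient correctness is tested against central
differences, and the same mechanism serves training, atom saliency and
edge-coefficient gradients.

## Saliency

Per-atom importance is the gradient of the binary cross-entropy loss at
a given label with respect to the atom's post-projection input
embedding, summed over coordinates. For actives, the most negative
score marks the atom contributing most to minimizing the loss; the
ranking is ascending. Differentiating at the input embedding (rather
than at the one-hot features) gives one scalar per atom without a
choice of descriptor weighting. Automorphic atoms receive equal scores.

## Adversarial augmentation

Each bond's coefficient (1) multiplies both of its directed-edge feature
rows; this changes no forward value but exposes `dL/dc` per bond
(summed over the two directions; ties broken by bond index). Bonds with
negative gradient are candidates, most negative first. A candidate is
kept if (a) RDKit can re-perceive the modified structure (lenient:
deletions that fragment the molecule are allowed, the fingerprint then
covers all fragments; deletions that break aromatic perception are
skipped), and (b) the Rogot–Goldberg scaffold distance is at most `mu`.
`mu` is the largest active-to-own-scaffold distance among the target's
training actives; acyclic actives (empty Bemis–Murcko scaffold) are
excluded from calibration and from augmentation, since the distance is
undefined against an empty fingerprint. Morgan fingerprints default to
radius 2, 2048 bits (configurable). In the degenerate Rogot–Goldberg
cases, identical vectors score exactly 1 and a term with zero
denominator contributes 0. One augmentation is attempted per active per
batch; successes join the batch labeled active. The loss used for the
gradients is the training loss at the active label, matching the
training-time use of the method.

## Training curriculum and evaluation

Stages: LM (300 epochs, LR 5e-3), LM+PM (20 epochs, LR 5e-4 — this
stage's rate is not pinned by the published schedule), LM+A (a fresh LM,
300 epochs, LR 5e-4, per-batch augmentation), fusion (20 epochs, LR
5e-5). Optimizer: Adam with default moments, batch size 64, no
scheduler. Per stage, the checkpoint with the best validation AP is
kept; selection considers trained epochs only — an untrained model can
rank a small validation set well by luck, and keeping such a baseline
would silently disable a stage — and prefers the latest epoch among
ties, which in the saturated-validation regime of the synthetic
benchmarks consistently generalizes better than the earliest.

The desk-scale profile used by the tests and examples is 4 layers, 32-D,
batch 16, with 50/10/50/20 epochs and the fusion stage at LR 1e-3: a
desk epoch is only a handful of gradient steps, so the fusion head —
trained from scratch on frozen modules — needs a proportionally larger
step than its full-scale counterpart. Problem sizes throughout the test
suite (20–50 actives per benchmark, 3 seeds, 8–30-residue peptides) are
chosen so a full run stays in the minutes range on one CPU.

Average precision is the step-wise precision-recall sum
`Σ_k (R_k − R_{k−1}) P_k` with stable-order tie handling (ties are
flagged); it is verified against an independent brute-force integration
and scikit-learn. mAP is the arithmetic mean over targets. Splits are
stratified 90/10 with deterministic seeding; four-fold cross-validation
runs one curriculum per fold on the training split.

## Curation and screening

Curation canonicalizes SMILES, drops unparseable entries (counted
separately), drops exact duplicate (molecule, label) records beyond the
first, and removes entirely any molecule labeled both active and decoy
for the same target — removing both sides is the conservative reading of
"removed". The report satisfies exact conservation
(`in = out + duplicates + conflicts + unparseable`) and curation is
idempotent. Multi-target duplicate summaries report both the per-target
sum and the global unique count, since either convention may be wanted.
Screening excludes (by canonical SMILES) molecules present in the
training split, scores the rest, and reports the top-n with each hit's
mean Rogot–Goldberg similarity to the training actives.

## Synthetic benchmarks

The generator emulates per-target active/decoy screening sets: actives
are a shared fused-bicyclic scaffold (naphthalene by default) decorated
with a carboxylate-bearing motif plus 0–2 random small substituents;
decoys are property-matched molecules on other scaffolds (easy split) or
the same scaffold without the motif (hard split). The motif is a perfect
label indicator — a substructure-match oracle achieves AP 1.0 on every
generated set — so a learning failure indicates a model bug, not data
noise. Motif atom indices are recorded against the canonical atom order
for scoring saliency. Proteins are random 8–30-residue peptides: the
protein module is exercised for correctness, not biology. What these
fixtures do **not** model: activity cliffs, assay noise, label
imbalance at DUD-E ratios (1:50), realistic physicochemical property
matching, or any actual binding physics — passing desk-scale tests
demonstrates the machinery is correct, not that real-data accuracy
transfers.

## Known limitations

- The hard synthetic split places all class signal in a side chain that
  Bemis–Murcko scaffolds strip. Once the ligand module has learned the
  motif, the adversarial rule deletes exactly the motif bonds (they
  contribute most to minimizing the loss) and the scaffold-distance
  bound cannot protect them — a motif-less molecule is *closer* to the
  scaffold. Augmented "actives" then contradict the fixture's own label
  rule, and augmentation *reduces* hard-split held-out AP once the plain
  module is at ceiling. On real screening data, where scaffolds carry
  class-relevant structure, the bound is meaningful; on this fixture the
  expected augmentation benefit does not materialize, and the acceptance
  suite reports that honestly.
- Full-scale runs (20 layers, 128-D, hundreds of epochs, 102 targets)
  are supported by the same code path but are far outside desk-scale
  compute; no pretrained weights are distributed.
- CPU-only, float64; no GPU kernels, mixed precision, or multiclass
  head.
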