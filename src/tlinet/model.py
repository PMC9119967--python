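"""Two-module target-ligand interaction model.

A ligand GCN module and a protein GCN module each produce a fixed-size
graph embedding. The protein embedding is multiplied by a scalar gate
``alpha`` (initialized to zero, so protein information enters training
smoothly: at onset the fused model is exactly a function of the ligand
alone). Both embeddings are concatenated, merged by a fully connected
layer and classified into an interaction probability through a single
logit and the logistic function. A separate ligand-only classifier head
serves the stages trained without protein information.

Gradient saliency: the per-atom importance score is the gradient of the
binary cross-entropy loss (at a given label) with respect to the atom's
input embedding, summed over embedding coordinates. For active molecules
the most negative scores mark the atoms contributing most to minimizing
the loss, i.e. the substructures the model considers most important.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .featurize import MolecularGraph
from .gcn import (
    ConfigurationError,
    ForwardResult,
    GCNConfig,
    GraphBatch,
    ModuleParams,
    _glorot,
    forward,
)


@dataclass(frozen=True)
class Prediction:
    probability: float
    logit: float


class FusionParams:
    """Learnable state of the full two-module model."""

    def __init__(
        self,
        ligand_config: GCNConfig,
        protein_config: GCNConfig | None = None,
        rng: np.random.Generator | int = 0,
        alpha_init: float = 0.0,
    ):
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        protein_config = protein_config or ligand_config
        if protein_config.hidden_dim != ligand_config.hidden_dim:
            raise ConfigurationError("ligand and protein hidden_dim must match")
        h = ligand_config.hidden_dim
        self.ligand_config = ligand_config
        self.protein_config = protein_config
        self.ligand_module = ModuleParams(ligand_config, rng)
        self.protein_module = ModuleParams(protein_config, rng)
        self.alpha = ad.parameter(alpha_init)  # protein-contribution gate
        self.merge_w = ad.parameter(_glorot(rng, 2 * h, h))
        self.merge_b = ad.parameter(np.zeros(h))
        self.classifier_w = ad.parameter(_glorot(rng, h, 1))
        self.classifier_b = ad.parameter(np.zeros(1))
        # ligand-only head for the stages without protein information
        self.lm_classifier_w = ad.parameter(_glorot(rng, h, 1))
        self.lm_classifier_b = ad.parameter(np.zeros(1))

    def head_parameters(self) -> list[Tensor]:
        return [
            self.alpha,
            self.merge_w,
            self.merge_b,
            self.classifier_w,
            self.classifier_b,
        ]

    def parameters(self) -> list[Tensor]:
        return (
            self.ligand_module.parameters()
            + self.protein_module.parameters()
            + self.head_parameters()
            + [self.lm_classifier_w, self.lm_classifier_b]
        )


# --------------------------------------------------------------------------
# batched logits (training path) and single-graph predictions (user path)


def fused_logits(
    ligand_batch: GraphBatch,
    protein_batch: GraphBatch,
    params: FusionParams,
    training: bool = False,
    edge_coeffs: Tensor | None = None,
    protein_constant: np.ndarray | None = None,
) -> tuple[Tensor, ForwardResult]:
    """Logits of the fused model for a batch of ligands against one target.

    ``protein_batch`` holds a single protein graph whose (gated) embedding
    is broadcast across the ligand batch. ``protein_constant`` substitutes a
    fixed vector for the protein module output (the constant-vector
    ablation). Returns the logits and the ligand module's forward result.
    """
    lig = forward(ligand_batch, params.ligand_module, training=training, edge_coeffs=edge_coeffs)
    b = ligand_batch.num_graphs
    if protein_constant is not None:
        prot_emb = ad.constant(np.broadcast_to(protein_constant, (1, len(protein_constant))))
    else:
        prot_emb = forward(protein_batch, params.protein_module, training=training).graph_embeddings
    gated = ad.mul(prot_emb, params.alpha)
    tiled = ad.gather_rows(gated, np.zeros(b, dtype=np.int64))
    merged = ad.linear(
        ad.concat([lig.graph_embeddings, tiled], axis=1), params.merge_w, params.merge_b
    )
    merged = ad.relu(merged)
    logits = ad.linear(merged, params.classifier_w, params.classifier_b)
    return ad.reshape(logits, (b,)), lig


def ligand_only_logits(
    ligand_batch: GraphBatch,
    params: FusionParams,
    training: bool = False,
    edge_coeffs: Tensor | None = None,
) -> tuple[Tensor, ForwardResult]:
    """Logits of the ligand module routed through the ligand-only head."""
    lig = forward(ligand_batch, params.ligand_module, training=training, edge_coeffs=edge_coeffs)
    logits = ad.linear(lig.graph_embeddings, params.lm_classifier_w, params.lm_classifier_b)
    return ad.reshape(logits, (ligand_batch.num_graphs,)), lig


def bce_loss(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from logits (numerically stable form)."""
    y = ad.constant(np.asarray(labels, dtype=np.float64))
    p = ad.sigmoid(logits)
    eps = 1e-12
    term = ad.add(
        ad.mul(y, ad.log(ad.add(p, ad.constant(eps)))),
        ad.mul(ad.constant(1.0) - y, ad.log(ad.add(ad.constant(1.0) - p, ad.constant(eps)))),
    )
    return ad.mul(ad.tensor_sum(term), ad.constant(-1.0 / logits.data.shape[0]))


def _to_prediction(logits: Tensor) -> Prediction:
    logit = float(logits.data[0])
    return Prediction(probability=float(1.0 / (1.0 + np.exp(-logit))), logit=logit)


def predict(
    ligand: MolecularGraph, protein: MolecularGraph, params: FusionParams
) -> Prediction:
    """Fused interaction probability for one ligand against one target."""
    logits, _ = fused_logits(
        GraphBatch.from_graphs([ligand]), GraphBatch.from_graphs([protein]), params
    )
    return _to_prediction(logits)


def predict_ligand_only(ligand: MolecularGraph, params: FusionParams) -> Prediction:
    """Ligand-module probability through the ligand-only classification head."""
    logits, _ = ligand_only_logits(GraphBatch.from_graphs([ligand]), params)
    return _to_prediction(logits)


def constant_protein_ablation(
    ligand: MolecularGraph, params: FusionParams
) -> Prediction:
    """Fused prediction with the protein embedding replaced by all-ones.

    The gate still applies; the output is independent of any protein graph.
    """
    ones = np.ones(params.ligand_config.hidden_dim)
    logits, _ = fused_logits(
        GraphBatch.from_graphs([ligand]),
        GraphBatch.from_graphs([ligand]),  # placeholder, unused
        params,
        protein_constant=ones,
    )
    return _to_prediction(logits)


@dataclass(frozen=True)
class SaliencyMap:
    """Per-atom gradient scores; ranking ascending (most important first)."""

    scores: np.ndarray
    ranking: np.ndarray

    def top(self, n: int) -> np.ndarray:
        return self.ranking[:n]


def saliency(
    ligand: MolecularGraph,
    protein: MolecularGraph | None,
    params: FusionParams,
    label: int = 1,
) -> SaliencyMap:
    """Gradient saliency of the loss at ``label`` over the ligand's atoms.

    Scores are the per-atom sums of dL/d(node input embedding); the most
    negative score marks the atom whose features contribute most to
    minimizing the loss, hence the most important atom for the prediction.
    """
    batch = GraphBatch.from_graphs([ligand])
    if protein is None:
        logits, lig = ligand_only_logits(batch, params)
    else:
        logits, lig = fused_logits(batch, GraphBatch.from_graphs([protein]), params)
    loss = bce_loss(logits, np.array([label]))
    loss.backward()
    grads = lig.node_input.grad
    scores = grads.sum(axis=1)
    order = np.lexsort((np.arange(len(scores)), scores))
    return SaliencyMap(scores=scores, ranking=order)
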