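"""Checkpoint and graph-container serialization.

Checkpoints are numpy ``.npz`` archives (format version 1) holding every
learnable array and batch-norm running statistic under a dotted name, plus
a JSON metadata entry with the module configurations, so a checkpoint
fully reconstructs a :class:`~tlinet.model.FusionParams`.

Featurized graphs are written as a versioned JSON container with explicit
node/edge arrays.
"""

from __future__ import annotations

import json

import numpy as np

from .featurize import MolecularGraph
from .gcn import BatchNorm, GCNConfig, ModuleParams
from .model import FusionParams

CHECKPOINT_VERSION = 1
GRAPH_CONTAINER_VERSION = 1


def _module_state(module: ModuleParams, prefix: str) -> dict:
    state = {
        f"{prefix}.node_embed_w": module.node_embed_w.data,
        f"{prefix}.node_embed_b": module.node_embed_b.data,
        f"{prefix}.edge_embed_w": module.edge_embed_w.data,
        f"{prefix}.edge_embed_b": module.edge_embed_b.data,
    }
    for i, layer in enumerate(module.layers):
        lp = f"{prefix}.layers.{i}"
        state[f"{lp}.beta"] = layer.beta.data
        for norm_name, norm in (("pre_norm", layer.pre_norm), ("mlp_norm", layer.mlp_norm)):
            state[f"{lp}.{norm_name}.gamma"] = norm.gamma.data
            state[f"{lp}.{norm_name}.beta"] = norm.beta.data
            state[f"{lp}.{norm_name}.running_mean"] = norm.running_mean
            state[f"{lp}.{norm_name}.running_var"] = norm.running_var
        state[f"{lp}.mlp_w1"] = layer.mlp_w1.data
        state[f"{lp}.mlp_b1"] = layer.mlp_b1.data
        state[f"{lp}.mlp_w2"] = layer.mlp_w2.data
        state[f"{lp}.mlp_b2"] = layer.mlp_b2.data
    return state


def _load_module_state(module: ModuleParams, prefix: str, state: dict):
    module.node_embed_w.data[...] = state[f"{prefix}.node_embed_w"]
    module.node_embed_b.data[...] = state[f"{prefix}.node_embed_b"]
    module.edge_embed_w.data[...] = state[f"{prefix}.edge_embed_w"]
    module.edge_embed_b.data[...] = state[f"{prefix}.edge_embed_b"]
    for i, layer in enumerate(module.layers):
        lp = f"{prefix}.layers.{i}"
        layer.beta.data[...] = state[f"{lp}.beta"]
        for norm_name in ("pre_norm", "mlp_norm"):
            norm: BatchNorm = getattr(layer, norm_name)
            norm.gamma.data[...] = state[f"{lp}.{norm_name}.gamma"]
            norm.beta.data[...] = state[f"{lp}.{norm_name}.beta"]
            norm.running_mean = np.array(state[f"{lp}.{norm_name}.running_mean"])
            norm.running_var = np.array(state[f"{lp}.{norm_name}.running_var"])
        layer.mlp_w1.data[...] = state[f"{lp}.mlp_w1"]
        layer.mlp_b1.data[...] = state[f"{lp}.mlp_b1"]
        layer.mlp_w2.data[...] = state[f"{lp}.mlp_w2"]
        layer.mlp_b2.data[...] = state[f"{lp}.mlp_b2"]


def save_checkpoint(path: str, params: FusionParams):
    state = _module_state(params.ligand_module, "ligand")
    state.update(_module_state(params.protein_module, "protein"))
    state.update(
        {
            "alpha": params.alpha.data,
            "merge_w": params.merge_w.data,
            "merge_b": params.merge_b.data,
            "classifier_w": params.classifier_w.data,
            "classifier_b": params.classifier_b.data,
            "lm_classifier_w": params.lm_classifier_w.data,
            "lm_classifier_b": params.lm_classifier_b.data,
        }
    )
    meta = {
        "version": CHECKPOINT_VERSION,
        "ligand_config": params.ligand_config.__dict__ | {},
        "protein_config": params.protein_config.__dict__ | {},
    }
    for cfg in ("ligand_config", "protein_config"):
        d = dict(meta[cfg])
        d["dilation"] = list(d["dilation"]) if d["dilation"] else None
        meta[cfg] = d
    np.savez(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path: str) -> FusionParams:
    archive = np.load(path, allow_pickle=False)
    meta = json.loads(str(archive["__meta__"]))
    if meta["version"] != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta['version']}")

    def cfg(d):
        d = dict(d)
        d["dilation"] = tuple(d["dilation"]) if d["dilation"] else None
        return GCNConfig(**d)

    params = FusionParams(cfg(meta["ligand_config"]), cfg(meta["protein_config"]), rng=0)
    state = {k: archive[k] for k in archive.files if k != "__meta__"}
    _load_module_state(params.ligand_module, "ligand", state)
    _load_module_state(params.protein_module, "protein", state)
    params.alpha.data[...] = state["alpha"]
    params.merge_w.data[...] = state["merge_w"]
    params.merge_b.data[...] = state["merge_b"]
    params.classifier_w.data[...] = state["classifier_w"]
    params.classifier_b.data[...] = state["classifier_b"]
    params.lm_classifier_w.data[...] = state["lm_classifier_w"]
    params.lm_classifier_b.data[...] = state["lm_classifier_b"]
    return params


def graph_to_json(graph: MolecularGraph) -> dict:
    return {
        "version": GRAPH_CONTAINER_VERSION,
        "source": graph.source,
        "node_count": graph.node_count,
        "directed_edges": graph.directed_edges.tolist(),
        "node_features": graph.node_features.tolist(),
        "edge_features": graph.edge_features.tolist(),
        "edge_bond_index": graph.edge_bond_index.tolist(),
    }


def graph_from_json(payload: dict) -> MolecularGraph:
    if payload.get("version") != GRAPH_CONTAINER_VERSION:
        raise ValueError("unsupported graph container version")
    return MolecularGraph(
        source=payload["source"],
        node_count=payload["node_count"],
        directed_edges=np.asarray(payload["directed_edges"], dtype=np.int64).reshape(-1, 2),
        node_features=np.asarray(payload["node_features"], dtype=np.uint8),
        edge_features=np.asarray(payload["edge_features"], dtype=np.uint8),
        edge_bond_index=np.asarray(payload["edge_bond_index"], dtype=np.int64),
    )
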