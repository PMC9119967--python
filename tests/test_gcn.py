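"""Deep GCN module: message passing, aggregation limits, residual identity,
dilated k-NN, pooling, and a hand-computed forward-pass trace."""

import math

import numpy as np
import pytest

from tlinet import autodiff as ad
from tlinet.featurize import MolecularGraph, smiles_to_graph
from tlinet.gcn import (
    MESSAGE_EPS,
    ConfigurationError,
    GCNConfig,
    GraphBatch,
    ModuleParams,
    aggregate_softmax,
    dilated_knn,
    embed_inputs,
    forward,
    message_construct,
    node_update,
    pool,
)


def zero_blocks(params: ModuleParams):
    """Zero every block's final linear layer, making each block the identity."""
    for layer in params.layers:
        layer.mlp_w2.data[...] = 0.0
        layer.mlp_b2.data[...] = 0.0


class TestConfig:
    def test_default_configuration_is_full_scale(self):
        cfg = GCNConfig()
        assert cfg.num_layers == 20
        assert cfg.hidden_dim == 128
        assert cfg.aggregation == "softmax"
        assert cfg.pooling == "mean"

    @pytest.mark.parametrize(
        "kwargs", [{"num_layers": -1}, {"hidden_dim": 0}, {"dilation": (0, 1)}, {"dropout": 1.0}]
    )
    def test_invalid_configurations_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            GCNConfig(**kwargs)


class TestEmbedInputs:
    def test_zero_weights_give_zero_embeddings(self):
        params = ModuleParams(GCNConfig(num_layers=0, hidden_dim=4), rng=0)
        params.node_embed_w.data[...] = 0
        params.edge_embed_w.data[...] = 0
        batch = GraphBatch.from_graphs([smiles_to_graph("CCO")])
        x, e = embed_inputs(batch, params)
        assert np.allclose(x.data, 0) and np.allclose(e.data, 0)

    def test_identical_atoms_get_identical_embeddings(self):
        params = ModuleParams(GCNConfig(num_layers=0, hidden_dim=4), rng=0)
        batch = GraphBatch.from_graphs([smiles_to_graph("c1ccccc1")])
        x, _ = embed_inputs(batch, params)
        assert np.allclose(x.data, x.data[0])

    def test_single_node_graph_has_no_edge_embeddings(self):
        params = ModuleParams(GCNConfig(num_layers=0, hidden_dim=4), rng=0)
        batch = GraphBatch.from_graphs([smiles_to_graph("C")])
        x, e = embed_inputs(batch, params)
        assert x.data.shape == (1, 4)
        assert e.data.shape[0] == 0


class TestMessageConstruct:
    def test_zero_inputs_give_epsilon_message(self):
        m = message_construct(None, ad.constant(np.zeros(3)), ad.constant(np.zeros(3)))
        assert np.allclose(m.data, MESSAGE_EPS)

    def test_negative_sum_clipped_to_epsilon(self):
        m = message_construct(None, ad.constant([-1.0, -2.0]), ad.constant([0.5, 1.0]))
        assert np.allclose(m.data, MESSAGE_EPS)

    def test_unit_basis_sum(self):
        m = message_construct(None, ad.constant([1.0, 0.0]), ad.constant([0.0, 1.0]))
        assert np.allclose(m.data, [1.0 + MESSAGE_EPS, 1.0 + MESSAGE_EPS])


class TestSoftmaxAggregation:
    def test_single_message_is_returned_unchanged(self, rng):
        m = rng.normal(size=(1, 5))
        out = aggregate_softmax(ad.constant(m), beta=2.0)
        assert np.allclose(out.data, m[0])

    def test_beta_zero_recovers_arithmetic_mean_exactly(self, rng):
        m = rng.normal(size=(4, 3))
        out = aggregate_softmax(ad.constant(m), beta=0.0)
        assert np.array_equal(out.data, m.mean(axis=0)) or np.allclose(
            out.data, m.mean(axis=0), atol=0, rtol=1e-15
        )

    def test_large_beta_approaches_feature_wise_max(self):
        m = np.array([[0.0, 5.0], [10.0, 1.0]])
        out = aggregate_softmax(ad.constant(m), beta=100.0)
        assert np.allclose(out.data, [10.0, 5.0], atol=1e-3)

    def test_approach_to_max_is_monotone_in_beta(self, rng):
        m = rng.normal(size=(5, 4))
        target = m.max(axis=0)
        gaps = [
            np.abs(aggregate_softmax(ad.constant(m), beta=b).data - target).max()
            for b in (1.0, 4.0, 16.0, 64.0)
        ]
        assert all(g2 <= g1 + 1e-12 for g1, g2 in zip(gaps, gaps[1:]))

    def test_empty_message_set_aggregates_to_zero(self):
        out = aggregate_softmax(ad.constant(np.zeros((0, 3))), beta=1.0)
        assert np.allclose(out.data, 0.0)


class TestNodeUpdate:
    def _identity_layer(self):
        cfg = GCNConfig(num_layers=1, hidden_dim=1)
        params = ModuleParams(cfg, rng=0)
        layer = params.layers[0]
        layer.mlp_w1.data[...] = [[1.0, 0.0]]
        layer.mlp_b1.data[...] = 0.0
        layer.mlp_norm.running_var[...] = 1.0 - layer.mlp_norm.eps  # exact identity norm
        layer.mlp_w2.data[...] = [[1.0], [0.0]]
        layer.mlp_b2.data[...] = 0.0
        return layer

    def test_identity_mlp_returns_sum_of_state_and_message(self):
        layer = self._identity_layer()
        out = node_update(ad.constant([[2.0]]), ad.constant([[3.0]]), layer)
        assert np.allclose(out.data, 5.0, atol=1e-12)

    def test_zero_message_identity_mlp_returns_state(self):
        layer = self._identity_layer()
        out = node_update(ad.constant([[1.5]]), ad.constant([[0.0]]), layer)
        assert np.allclose(out.data, 1.5, atol=1e-12)

    def test_all_zero_inputs_and_biases_give_zero(self):
        layer = self._identity_layer()
        out = node_update(ad.constant([[0.0]]), ad.constant([[0.0]]), layer)
        assert np.allclose(out.data, 0.0)


class TestResidualIdentity:
    @pytest.mark.parametrize("depth", [1, 2, 6])
    def test_zeroed_blocks_make_the_stack_the_identity(self, depth):
        cfg = GCNConfig(num_layers=depth, hidden_dim=8)
        params = ModuleParams(cfg, rng=1)
        zero_blocks(params)
        batch = GraphBatch.from_graphs([smiles_to_graph("CC(=O)Oc1ccccc1C(=O)O")])
        result = forward(batch, params)
        x0, _ = embed_inputs(batch, params)
        expected = x0.data.mean(axis=0)
        assert np.allclose(result.graph_embeddings.data[0], expected, atol=1e-12)

    def test_depth_zero_forward_is_pool_of_input_embedding(self):
        cfg = GCNConfig(num_layers=0, hidden_dim=8)
        params = ModuleParams(cfg, rng=1)
        batch = GraphBatch.from_graphs([smiles_to_graph("CCO")])
        result = forward(batch, params)
        x0, _ = embed_inputs(batch, params)
        assert np.allclose(result.graph_embeddings.data[0], x0.data.mean(axis=0))


class TestDilatedKnn:
    def test_d_one_is_ordinary_knn(self, rng):
        emb = rng.normal(size=(6, 3))
        neigh = dilated_knn(emb, k=2, d=1)
        for v in range(6):
            dist = np.linalg.norm(emb - emb[v], axis=1)
            order = [u for u in np.lexsort((np.arange(6), dist)) if u != v]
            assert neigh[v] == order[:2]

    def test_line_graph_skip_pattern(self):
        emb = np.array([[0.0], [1.0], [2.0], [3.0]])
        assert dilated_knn(emb, k=1, d=3)[0] == [3]

    def test_full_neighborhood(self, rng):
        emb = rng.normal(size=(5, 2))
        neigh = dilated_knn(emb, k=4, d=1)
        for v in range(5):
            assert sorted(neigh[v]) == [u for u in range(5) if u != v]

    def test_oversized_neighborhood_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            dilated_knn(rng.normal(size=(4, 2)), k=2, d=2)


class TestPool:
    def test_single_node_all_methods_agree(self, rng):
        x = ad.constant(rng.normal(size=(1, 4)))
        for method in ("mean", "max", "sum"):
            assert np.allclose(pool(x, method).data, x.data[0])

    def test_two_node_arithmetic(self):
        x = ad.constant([[0.0, 2.0], [2.0, 0.0]])
        assert np.allclose(pool(x, "mean").data, [1.0, 1.0])
        assert np.allclose(pool(x, "sum").data, [2.0, 2.0])
        assert np.allclose(pool(x, "max").data, [2.0, 2.0])

    def test_empty_graph_rejected(self):
        with pytest.raises(ConfigurationError):
            pool(ad.constant(np.zeros((0, 3))), "mean")


def permute_graph(g: MolecularGraph, perm: np.ndarray) -> MolecularGraph:
    """Relabel nodes: new index of old node i is perm[i]."""
    inv = np.argsort(perm)
    return MolecularGraph(
        source=g.source,
        node_count=g.node_count,
        directed_edges=perm[g.directed_edges],
        node_features=g.node_features[inv],
        edge_features=g.edge_features,
        edge_bond_index=g.edge_bond_index,
    )


class TestForward:
    def test_permutation_invariance_of_pooled_embedding(self, rng):
        cfg = GCNConfig(num_layers=3, hidden_dim=16)
        params = ModuleParams(cfg, rng=3)
        g = smiles_to_graph("CC(=O)Oc1ccccc1C(=O)O")
        perm = rng.permutation(g.node_count)
        out1 = forward(g, params).graph_embeddings.data[0]
        out2 = forward(permute_graph(g, perm), params).graph_embeddings.data[0]
        assert np.allclose(out1, out2, atol=1e-6)

    def test_batched_and_single_forward_agree(self):
        cfg = GCNConfig(num_layers=2, hidden_dim=8)
        params = ModuleParams(cfg, rng=0)
        graphs = [smiles_to_graph(s) for s in ("CCO", "c1ccccc1", "CC(N)C(=O)O")]
        batch_out = forward(GraphBatch.from_graphs(graphs), params).graph_embeddings.data
        for i, g in enumerate(graphs):
            single = forward(g, params).graph_embeddings.data[0]
            assert np.allclose(batch_out[i], single, atol=1e-10)

    def test_gradient_reaches_first_layer_of_a_twenty_layer_stack(self):
        cfg = GCNConfig(num_layers=20, hidden_dim=8)
        params = ModuleParams(cfg, rng=2)
        result = forward(smiles_to_graph("CCO"), params)
        ad.tensor_sum(result.graph_embeddings).backward()
        assert np.linalg.norm(params.layers[0].mlp_w1.grad) > 0
        assert np.linalg.norm(params.node_embed_w.grad) > 0

    def test_dilated_forward_runs_and_differs_from_bonded(self):
        cfg_b = GCNConfig(num_layers=2, hidden_dim=8)
        cfg_d = GCNConfig(num_layers=2, hidden_dim=8, dilation=(2, 2))
        params = ModuleParams(cfg_b, rng=0)
        g = smiles_to_graph("CCCCCCCC")
        out_b = forward(g, params, cfg_b).graph_embeddings.data
        out_d = forward(g, params, cfg_d).graph_embeddings.data
        assert out_b.shape == out_d.shape
        assert not np.allclose(out_b, out_d)


class TestHandTrace:
    """A hidden_dim=1, two-layer forward pass on the 3-node path graph of
    ethanol, recomputed independently with plain-float arithmetic."""

    def test_forward_matches_hand_computation(self):
        cfg = GCNConfig(num_layers=2, hidden_dim=1)
        params = ModuleParams(cfg, rng=0)
        nw = 0.01 * (np.arange(168) % 7)[:, None]
        ew = 0.02 * (np.arange(12) % 5)[:, None]
        params.node_embed_w.data[...] = nw
        params.node_embed_b.data[...] = 0.1
        params.edge_embed_w.data[...] = ew
        params.edge_embed_b.data[...] = 0.05
        weights = [
            dict(w1=[0.3, -0.2], b1=[0.1, 0.2], w2=[0.4, 0.25], b2=0.05),
            dict(w1=[0.2, 0.1], b1=[-0.05, 0.15], w2=[0.3, -0.1], b2=0.02),
        ]
        for layer, w in zip(params.layers, weights):
            layer.mlp_w1.data[...] = np.array([w["w1"]])
            layer.mlp_b1.data[...] = w["b1"]
            layer.mlp_w2.data[...] = np.array(w["w2"])[:, None]
            layer.mlp_b2.data[...] = w["b2"]

        g = smiles_to_graph("CCO")
        got = forward(g, params).graph_embeddings.data[0, 0]

        # ---- independent plain-float recomputation -----------------------
        eps_bn = 1e-5
        x = [float(g.node_features[i] @ nw[:, 0]) + 0.1 for i in range(g.node_count)]
        e = [float(g.edge_features[i] @ ew[:, 0]) + 0.05 for i in range(len(g.directed_edges))]
        beta = 1.0
        for w in weights:
            h = [max(xi / math.sqrt(1.0 + eps_bn), 0.0) for xi in x]
            m = [0.0] * len(x)
            for v in range(len(x)):
                msgs = [
                    max(h[u] + e[i], 0.0) + MESSAGE_EPS
                    for i, (dest, u) in enumerate(g.directed_edges)
                    if dest == v
                ]
                if msgs:
                    ws = [math.exp(beta * mm) for mm in msgs]
                    total = sum(ws)
                    m[v] = sum(wi / total * mm for wi, mm in zip(ws, msgs))
            new_x = []
            for v in range(len(x)):
                z = h[v] + m[v]
                hid = [
                    max((z * w["w1"][j] + w["b1"][j]) / math.sqrt(1.0 + eps_bn), 0.0)
                    for j in range(2)
                ]
                new_x.append(x[v] + hid[0] * w["w2"][0] + hid[1] * w["w2"][1] + w["b2"])
            x = new_x
        expected = sum(x) / len(x)
        assert abs(got - expected) < 1e-10
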