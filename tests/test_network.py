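import numpy as np
import pytest

from geomsite import (GPSiteModel, ModelConfig, build_radius_graph,
                      featurize_structure, generate_backbone)
from geomsite import autodiff as ad
from geomsite.network import GraphTransformerLayer

from conftest import rigid_transform
from dense_oracle import dense_forward


def tiny_config(**kw):
    base = dict(node_in_dim=7, edge_in_dim=5, hidden_dim=8, n_layers=2,
                n_heads=2, n_tasks=3, dropout=0.0, seed=0)
    base.update(kw)
    return ModelConfig(**base)


def random_graph(rng, n, n_tasks=3, node_dim=7, edge_dim=5):
    """Random connected-ish digraph with symmetric edges and self-loops."""
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)
             if rng.random() < 0.5]
    edges = [(j, i) for i, j in pairs] + [(i, j) for i, j in pairs]
    edges += [(i, i) for i in range(n)]
    edge_index = np.array(sorted(edges, key=lambda e: (e[1], e[0])))
    node_feats = rng.normal(0, 1, (n, node_dim))
    edge_feats = rng.normal(0, 1, (len(edge_index), edge_dim))
    return node_feats, edge_feats, edge_index


class TestInputProjection:
    def test_zero_features_zero_bias_gives_zero_state(self):
        model = GPSiteModel(tiny_config())
        for mlp in (model.node_proj, model.edge_proj):
            for layer in mlp.layers:
                layer.b.data[:] = 0.0
        h, e = model.input_projection(np.zeros((4, 7)), np.zeros((6, 5)))
        assert np.allclose(h.data, 0) and np.allclose(e.data, 0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        nf, ef, ei = random_graph(rng, 6)
        a = GPSiteModel(tiny_config(seed=9)).forward(nf, ef, ei).data
        b = GPSiteModel(tiny_config(seed=9)).forward(nf, ef, ei).data
        assert np.array_equal(a, b)


class TestMessagePassing:
    def test_single_node_attention_is_one(self):
        cfg = tiny_config(use_layer_norm=False)
        layer = GraphTransformerLayer(cfg, np.random.default_rng(0))
        h = ad.as_tensor(np.random.default_rng(1).normal(0, 1, (1, 8)))
        e = ad.as_tensor(np.random.default_rng(2).normal(0, 1, (1, 8)))
        _, alpha = layer.message_passing(h, e, np.array([[0, 0]]))
        assert np.all(alpha.data == 1.0)

    def test_zero_value_and_edge_weights_reduce_to_identity(self):
        cfg = tiny_config(use_layer_norm=False)
        layer = GraphTransformerLayer(cfg, np.random.default_rng(0))
        layer.W_V.W.data[:] = 0.0
        layer.W_E.W.data[:] = 0.0
        layer.W_O.b.data[:] = 0.0
        rng = np.random.default_rng(3)
        nf, ef, ei = random_graph(rng, 5, node_dim=8, edge_dim=8)
        h = ad.as_tensor(nf)
        out, _ = layer.message_passing(h, ad.as_tensor(ef), ei)
        assert np.allclose(out.data, nf, atol=1e-12)

    def test_attention_rows_sum_to_one_every_layer(self):
        rng = np.random.default_rng(4)
        nf, ef, ei = random_graph(rng, 9)
        model = GPSiteModel(tiny_config(n_layers=3))
        h, e = model.input_projection(nf, ef)
        for layer in model.layers:
            h_hat, alpha = layer.message_passing(h, e, ei)
            sums = np.zeros((9, model.cfg.n_heads))
            np.add.at(sums, ei[:, 1], alpha.data)
            assert np.abs(sums - 1.0).max() < 1e-6
            h, e = layer(h, e, ei, np.zeros(9, dtype=int), 1)

    def test_missing_self_loop_softmax_still_normalizes_neighbors(self):
        # contract: Eq-style sum runs over N(i) u {i}; graph builder always
        # provides self-loops, and attention normalizes over incoming edges
        rng = np.random.default_rng(5)
        cfg = tiny_config()
        layer = GraphTransformerLayer(cfg, rng)
        h = ad.as_tensor(rng.normal(0, 1, (2, 8)))
        e = ad.as_tensor(rng.normal(0, 1, (2, 8)))
        ei = np.array([[0, 1], [1, 0]])
        _, alpha = layer.message_passing(h, e, ei)
        assert np.allclose(alpha.data, 1.0)


class TestEdgeUpdate:
    def test_zero_mlp_keeps_edges(self):
        cfg = tiny_config(use_layer_norm=False)
        layer = GraphTransformerLayer(cfg, np.random.default_rng(0))
        layer.edge_mlp.layers[-1].W.data[:] = 0.0
        layer.edge_mlp.layers[-1].b.data[:] = 0.0
        rng = np.random.default_rng(1)
        nf, ef, ei = random_graph(rng, 4, node_dim=8, edge_dim=8)
        out = layer.edge_update(ad.as_tensor(nf), ad.as_tensor(ef), ei)
        assert np.array_equal(out.data, ef)

    def test_directed_edges_stay_distinct(self):
        cfg = tiny_config(use_layer_norm=False)
        layer = GraphTransformerLayer(cfg, np.random.default_rng(0))
        rng = np.random.default_rng(2)
        h = rng.normal(0, 1, (2, 8))
        ei = np.array([[0, 1], [1, 0]])
        ef = rng.normal(0, 1, (2, 8))
        out = layer.edge_update(ad.as_tensor(h), ad.as_tensor(ef), ei)
        assert not np.allclose(out.data[0], out.data[1])

    def test_single_edge_matches_direct_formula(self):
        cfg = tiny_config(use_layer_norm=False)
        layer = GraphTransformerLayer(cfg, np.random.default_rng(0))
        rng = np.random.default_rng(3)
        h = rng.normal(0, 1, (2, 8))
        ef = rng.normal(0, 1, (1, 8))
        ei = np.array([[0, 1]])
        out = layer.edge_update(ad.as_tensor(h), ad.as_tensor(ef), ei)
        x = np.concatenate([h[0], ef[0], h[1]])
        for k, lin in enumerate(layer.edge_mlp.layers):
            x = x @ lin.W.data + lin.b.data
            if k < len(layer.edge_mlp.layers) - 1:
                x = np.where(x > 0, x, np.exp(np.minimum(x, 0)) - 1)
        assert np.abs(out.data[0] - (ef[0] + x)).max() < 1e-6


class TestGlobalContext:
    def test_identical_nodes_mean_is_that_vector(self):
        cfg = tiny_config()
        layer = GraphTransformerLayer(cfg, np.random.default_rng(0))
        v = np.random.default_rng(1).normal(0, 1, 8)
        h = np.tile(v, (5, 1))
        out = layer.global_node_update(ad.as_tensor(h), np.zeros(5, int), 1)
        gate = 1 / (1 + np.exp(-_run_mlp(layer.gate_mlp, v)))
        assert np.allclose(out.data, v * gate, atol=1e-10)

    def test_saturated_negative_gate_zeroes_nodes(self):
        cfg = tiny_config()
        layer = GraphTransformerLayer(cfg, np.random.default_rng(0))
        layer.gate_mlp.layers[-1].W.data[:] = 0.0
        layer.gate_mlp.layers[-1].b.data[:] = -50.0
        h = np.random.default_rng(2).normal(0, 1, (4, 8))
        out = layer.global_node_update(ad.as_tensor(h), np.zeros(4, int), 1)
        assert np.abs(out.data).max() < 1e-12

    def test_batched_equals_sequential_context(self):
        rng = np.random.default_rng(6)
        nf1, ef1, ei1 = random_graph(rng, 5)
        nf2, ef2, ei2 = random_graph(rng, 7)
        model = GPSiteModel(tiny_config())
        sep = np.vstack([model.forward(nf1, ef1, ei1).data,
                         model.forward(nf2, ef2, ei2).data])
        nf = np.vstack([nf1, nf2])
        ef = np.vstack([ef1, ef2])
        ei = np.vstack([ei1, ei2 + 5])
        pid = np.array([0] * 5 + [1] * 7)
        joint = model.forward(nf, ef, ei, pid).data
        assert np.abs(joint - sep).max() < 1e-10

    def test_empty_protein_rejected(self):
        cfg = tiny_config()
        layer = GraphTransformerLayer(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError):
            layer.global_node_update(ad.as_tensor(np.zeros((2, 8))),
                                     np.zeros(2, int), 2)


def _run_mlp(mlp, x):
    for k, lin in enumerate(mlp.layers):
        x = x @ lin.W.data + lin.b.data
        if k < len(mlp.layers) - 1:
            x = np.where(x > 0, x, np.exp(np.minimum(x, 0)) - 1)
    return x


class TestForward:
    def test_sparse_matches_dense_oracle_on_random_graphs(self):
        rng = np.random.default_rng(10)
        for trial in range(6):
            n = int(rng.integers(3, 13))
            nf, ef, ei = random_graph(rng, n)
            model = GPSiteModel(tiny_config(seed=trial))
            sparse = model.forward(nf, ef, ei).data
            dense = dense_forward(model, nf, ef, ei)
            assert np.abs(sparse - dense).max() < 1e-5

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(11)
        n = 8
        nf, ef, ei = random_graph(rng, n)
        model = GPSiteModel(tiny_config())
        base = model.forward(nf, ef, ei).data
        perm = rng.permutation(n)
        inv = np.argsort(perm)
        permuted = model.forward(nf[perm], ef, inv[ei]).data
        assert np.abs(permuted - base[perm]).max() < 1e-8

    def test_se3_invariant_logits_end_to_end(self):
        s = generate_backbone(40, "mixed", seed=5, noise=0.05)
        g = build_radius_graph(s)
        fb = featurize_structure(s, g)
        cfg = ModelConfig(node_in_dim=fb.node_features.shape[1],
                          edge_in_dim=fb.edge_features.shape[1],
                          hidden_dim=16, n_layers=2, n_heads=2, n_tasks=2,
                          dropout=0.0, seed=3)
        model = GPSiteModel(cfg)
        ref = model.forward(fb.node_features, fb.edge_features, fb.edge_index).data
        rng = np.random.default_rng(6)
        for _ in range(3):
            R, t = rigid_transform(rng)
            moved = s.transformed(R, t)
            fb2 = featurize_structure(moved, build_radius_graph(moved))
            out = model.forward(fb2.node_features, fb2.edge_features,
                                fb2.edge_index).data
            assert np.abs(out - ref).max() < 1e-4

    def test_cross_protein_isolation(self):
        rng = np.random.default_rng(12)
        nf1, ef1, ei1 = random_graph(rng, 5)
        nf2, ef2, ei2 = random_graph(rng, 6)
        model = GPSiteModel(tiny_config())
        pid = np.array([0] * 5 + [1] * 6)
        ei = np.vstack([ei1, ei2 + 5])
        base = model.forward(np.vstack([nf1, nf2]), np.vstack([ef1, ef2]),
                             ei, pid).data
        zeroed = model.forward(np.vstack([nf1, np.zeros_like(nf2)]),
                               np.vstack([ef1, np.zeros_like(ef2)]), ei, pid).data
        assert np.abs(zeroed[:5] - base[:5]).max() < 1e-12

    def test_width_mismatch_raises(self):
        model = GPSiteModel(tiny_config())
        with pytest.raises(ValueError):
            model.forward(np.zeros((3, 4)), np.zeros((3, 5)),
                          np.array([[0, 0], [1, 1], [2, 2]]))


class TestCheckpoint:
    def test_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(13)
        nf, ef, ei = random_graph(rng, 6)
        model = GPSiteModel(tiny_config(seed=21))
        path = str(tmp_path / "model.npz")
        model.save(path)
        loaded = GPSiteModel.load(path)
        assert np.array_equal(model.forward(nf, ef, ei).data,
                              loaded.forward(nf, ef, ei).data)

    def test_feature_version_mismatch_refused(self, tmp_path):
        import json
        model = GPSiteModel(tiny_config())
        path = str(tmp_path / "model.npz")
        model.save(path)
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
        cfg = json.loads(bytes(arrays["__config__"]).decode())
        cfg["feature_version"] = "geomsite-features-0"
        arrays["__config__"] = np.frombuffer(json.dumps(cfg).encode(), np.uint8)
        np.savez(path, **arrays)
        with pytest.raises(ValueError, match="feature version"):
            GPSiteModel.load(path)
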