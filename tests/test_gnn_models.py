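"""Propagation-rule correctness, parameter counting, and equivariance."""

import numpy as np
import pytest

import cortexgnn as cg
from cortexgnn.autodiff import Tensor
from cortexgnn.gnn_models import (ConfigurationError, GATLayer, GCNLayer,
                                  TopKPool, directed_edges_with_self_loops,
                                  load_checkpoint, normalized_adjacency,
                                  save_checkpoint)
from cortexgnn.surface_mesh import VertexGraph

from .oracles import dense_gat_head, dense_gcn_layer


def random_graph(rng, n_max=30):
    n = int(rng.integers(2, n_max + 1))
    possible = [(i, j) for i in range(n) for j in range(i + 1, n)]
    m = int(rng.integers(0, len(possible) + 1))
    chosen = rng.choice(len(possible), size=m, replace=False) if m else []
    edges = np.asarray([possible[c] for c in chosen], dtype=np.int64).reshape(-1, 2)
    return VertexGraph(node_count=n, edges=edges)


class TestGCNLayer:
    def test_edgeless_graph_is_plain_linear(self):
        rng = np.random.default_rng(0)
        layer = GCNLayer(4, 3, rng)
        g = VertexGraph(node_count=5)
        h = rng.normal(size=(5, 4))
        out = layer(Tensor(h), normalized_adjacency(g))
        assert np.allclose(out.data, h @ layer.weight.data + layer.bias.data)

    def test_two_node_edge_averages_features(self):
        # D-hat = 2I so every S entry is 1/2: each row becomes (h_i + h_j)/2.
        rng = np.random.default_rng(1)
        layer = GCNLayer(3, 3, rng)
        layer.weight.data = np.eye(3)
        layer.bias.data[:] = 0.0
        g = VertexGraph(node_count=2, edges=[[0, 1]])
        h = rng.normal(size=(2, 3))
        out = layer(Tensor(h), normalized_adjacency(g))
        expected = np.vstack([(h[0] + h[1]) / 2, (h[0] + h[1]) / 2])
        assert np.allclose(out.data, expected)

    def test_matches_dense_oracle_on_random_graphs(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            g = random_graph(rng)
            layer = GCNLayer(6, 4, rng)
            h = rng.normal(size=(g.node_count, 6))
            out = layer(Tensor(h), normalized_adjacency(g))
            oracle = dense_gcn_layer(h, g.edges, g.node_count,
                                     layer.weight.data, layer.bias.data)
            assert np.abs(out.data - oracle).max() < 1e-6

    def test_constant_features_on_regular_graph_stay_constant(self):
        g = cg.mesh_to_graph(cg.build_icosphere(0))  # 5-regular
        layer = GCNLayer(3, 2, np.random.default_rng(3))
        h = np.ones((12, 3)) * [1.0, -2.0, 0.5]
        out = layer(Tensor(h), normalized_adjacency(g)).data
        assert np.allclose(out, out[0])

    def test_dimension_mismatch_raises(self):
        layer = GCNLayer(4, 2, np.random.default_rng(0))
        g = VertexGraph(node_count=3)
        with pytest.raises(ValueError, match="in_dim"):
            layer(Tensor(np.ones((3, 5))), normalized_adjacency(g))


class TestGATLayer:
    def test_isolated_node_attends_only_to_itself(self):
        rng = np.random.default_rng(4)
        layer = GATLayer(3, 2, heads=1, rng=rng)
        g = VertexGraph(node_count=1)
        h = rng.normal(size=(1, 3))
        out = layer(Tensor(h), directed_edges_with_self_loops(g))
        assert np.allclose(out.data, h @ layer.weights[0].data + layer.bias.data)
        alpha = layer.attention(Tensor(h), directed_edges_with_self_loops(g))[0]
        assert np.allclose(alpha, 1.0)

    def test_identical_features_give_uniform_attention(self, ico1_graph):
        rng = np.random.default_rng(5)
        layer = GATLayer(3, 2, heads=2, rng=rng)
        h = np.tile([0.3, -1.2, 2.0], (ico1_graph.node_count, 1))
        edges = directed_edges_with_self_loops(ico1_graph)
        deg = ico1_graph.degrees()
        for alpha in layer.attention(Tensor(h), edges):
            assert np.allclose(alpha, 1.0 / (deg[edges[1]] + 1))

    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            g = random_graph(rng, n_max=15)
            layer = GATLayer(4, 3, heads=2, rng=rng)
            edges = directed_edges_with_self_loops(g)
            h = rng.normal(size=(g.node_count, 4))
            for alpha in layer.attention(Tensor(h), edges):
                sums = np.zeros(g.node_count)
                np.add.at(sums, edges[1], alpha)
                assert np.allclose(sums, 1.0, atol=1e-6)

    def test_matches_per_node_loop_oracle_on_random_graphs(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = random_graph(rng)
            layer = GATLayer(5, 3, heads=1, rng=rng)
            layer.bias.data[:] = 0.0
            h = rng.normal(size=(g.node_count, 5))
            out = layer(Tensor(h), directed_edges_with_self_loops(g))
            oracle = dense_gat_head(h, g.edges, g.node_count,
                                    layer.weights[0].data,
                                    layer.att_src[0].data, layer.att_dst[0].data)
            assert np.abs(out.data - oracle).max() < 1e-6


class TestGraphUNet:
    def test_pool_keeps_ceil_ratio(self):
        rng = np.random.default_rng(8)
        pool = TopKPool(4, ratio=0.5, rng=rng)
        idx, pooled = pool.select(Tensor(rng.normal(size=(10, 4))))
        assert len(idx) == 5 and pooled.shape == (5, 4)

    def test_retained_set_matches_bruteforce_topk(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            n = int(rng.integers(4, 40))
            pool = TopKPool(3, ratio=0.37, rng=rng)
            h = rng.normal(size=(n, 3))
            scores = (h @ pool.proj.data).ravel() / np.linalg.norm(pool.proj.data)
            k = int(np.ceil(0.37 * n))
            # brute force: sort by (-score, index)
            oracle = sorted(sorted(range(n)), key=lambda i: (-scores[i], i))[:k]
            idx, _ = pool.select(Tensor(h))
            assert set(idx) == set(oracle)

    def test_pool_then_unpool_restores_size_with_zeros(self):
        rng = np.random.default_rng(10)
        pool = TopKPool(3, ratio=0.4, rng=rng)
        h = Tensor(rng.normal(size=(10, 3)))
        idx, pooled = pool.select(h)
        up = pooled.scatter_rows(idx, 10)
        assert up.shape == (10, 3)
        dropped = np.setdiff1d(np.arange(10), idx)
        assert np.all(up.data[dropped] == 0)
        assert np.allclose(up.data[idx], pooled.data)

    def test_forward_emits_logit_per_original_vertex(self, ico1_graph):
        cfg = cg.ModelConfig(architecture="gunet", hidden=(8,), depth=3,
                             n_classes=4, seed=0)
        model = cg.build_model(cfg, in_dim=5)
        rng = np.random.default_rng(11)
        out = model.forward(rng.normal(size=(42, 5)), ico1_graph)
        assert out.data.shape == (42, 4)
        assert np.isfinite(out.data).all()


class TestModelAssembly:
    def test_gcn_closed_form_count(self):
        cfg = cg.ModelConfig(architecture="gcn", hidden=(7,), n_classes=4, seed=0)
        model = cg.build_model(cfg, in_dim=5)
        assert cg.count_parameters(model) == 5 * 7 + 7 + 7 * 4 + 4

    def test_feature_growth_adds_exactly_642_times_width(self):
        for arch, w1 in [("gcn", 11), ("gat", 11 * 3)]:  # GAT: heads x W per head
            cfg = cg.ModelConfig(architecture=arch, hidden=(11,), heads=3,
                                 n_classes=4, seed=0)
            small = cg.count_parameters(cg.build_model(cfg, in_dim=5))
            large = cg.count_parameters(cg.build_model(cfg, in_dim=647))
            assert large - small == 642 * w1

    def test_framework_count_equals_closed_form_random_configs(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            widths = tuple(int(w) for w in rng.integers(2, 30, size=rng.integers(1, 4)))
            heads = int(rng.integers(1, 4))
            k = int(rng.integers(2, 9))
            d = int(rng.integers(2, 50))
            gcn = cg.build_model(cg.ModelConfig(architecture="gcn", hidden=widths,
                                                n_classes=k, seed=0), d)
            dims = [d, *widths, k]
            expected = sum(a * b + b for a, b in zip(dims[:-1], dims[1:]))
            assert cg.count_parameters(gcn) == expected

            gat = cg.build_model(cg.ModelConfig(architecture="gat", hidden=widths,
                                                heads=heads, n_classes=k, seed=0), d)
            expected = 0
            din = d
            for w in widths:
                expected += heads * (din * w + 2 * w) + w * heads  # W, a_src/a_dst, bias
                din = w * heads
            expected += heads * (din * k + 2 * k) + k  # averaged output layer
            assert cg.count_parameters(gat) == expected

    def test_unknown_architecture_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown architecture"):
            cg.build_model(cg.ModelConfig(architecture="transformer"), 5)

    def test_checkpoint_round_trip(self, tmp_path, ico1_graph):
        cfg = cg.ModelConfig(architecture="gat", hidden=(6,), heads=2,
                             n_classes=3, seed=4)
        model = cg.build_model(cfg, in_dim=5)
        rng = np.random.default_rng(13)
        x = rng.normal(size=(42, 5))
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        back = load_checkpoint(path)
        assert np.array_equal(model.forward(x, ico1_graph).data,
                              back.forward(x, ico1_graph).data)


@pytest.mark.parametrize("arch", ["gcn", "gat", "gunet"])
def test_permutation_equivariance(arch, ico1_graph):
    """Relabeling vertices by a permutation permutes output rows identically
    (tie-free pooling scores hold almost surely for random features)."""
    rng = np.random.default_rng(14)
    cfg = cg.ModelConfig(architecture=arch, hidden=(6,), heads=2, depth=2,
                         n_classes=3, seed=5)
    model = cg.build_model(cfg, in_dim=4)
    x = rng.normal(size=(42, 4))
    out = model.forward(x, ico1_graph).data

    pi = rng.permutation(42)
    edges_perm = pi[ico1_graph.edges]
    g_perm = cg.VertexGraph(node_count=42, edges=edges_perm)
    x_perm = np.empty_like(x)
    x_perm[pi] = x
    out_perm = model.forward(x_perm, g_perm).data
    assert np.allclose(out_perm[pi], out, atol=1e-8)
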