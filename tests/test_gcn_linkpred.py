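"""Graph construction, negative sampling, pooling, embeddings, training."""

import numpy as np
import pandas as pd
import pytest

from inferreg import gcn_linkpred as gl
from inferreg import nn
from inferreg.io_formats import ExpressionMatrix


def _expr(genes, n_samples=6, seed=0):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(n_samples)]
    return ExpressionMatrix(
        list(genes), samples, rng.lognormal(3, 1, (len(genes), n_samples)),
        {s: "A" for s in samples},
    )


class TestBuildGraph:
    def test_nodes_and_duplicates(self, edge_frame):
        edges = edge_frame(
            [("a", "b"), ("a", "c"), ("d", "b"), ("a", "b")], importance=1.0
        )
        expr = _expr("abcd")
        g = gl.build_graph(edges, expr)
        assert g.n_nodes == 4
        assert len(g.edges) == 3  # duplicate collapsed

    def test_neighbours_match_bruteforce(self, edge_frame):
        rng = np.random.default_rng(4)
        genes = [f"n{i}" for i in range(10)]
        pairs = {(genes[i], genes[j])
                 for i, j in rng.integers(0, 10, (30, 2)) if i != j}
        g = gl.build_graph(edge_frame(sorted(pairs), importance=1.0),
                           _expr(genes))
        for tf in genes:
            brute = {u for t, u in pairs if t == tf}
            assert g.neighbours(tf) == brute

    def test_empty_errors(self, edge_frame):
        with pytest.raises(ValueError, match="empty"):
            gl.build_graph(edge_frame([], importance=[]), _expr("ab"))


class TestSampleNegatives:
    def test_counting(self, edge_frame):
        # |V|=6, N(t)={u1,u2} -> |S(t)|=2 from 3 eligible
        genes = ["t", "u1", "u2", "v1", "v2", "v3"]
        edges = edge_frame([("t", "u1"), ("t", "u2")], importance=1.0)
        g = gl.build_graph(edges, _expr(genes))
        # force all six genes into the graph
        g = gl.RegGraph(genes, g.edges, _expr(genes).values)
        split = gl.sample_negatives(g, set(g.edges), seed=0)
        negs = [e for e, y in zip(split.edges, split.labels) if y == 0]
        assert len(negs) == 2
        assert all(t == "t" and v in {"v1", "v2", "v3"} for t, v in negs)

    def test_saturated_tf_warns(self, edge_frame):
        genes = ["t", "a", "b"]
        edges = edge_frame([("t", "a"), ("t", "b")], importance=1.0)
        g = gl.build_graph(edges, _expr(genes))
        with pytest.warns(UserWarning, match="no eligible"):
            split = gl.sample_negatives(g, set(g.edges), seed=0)
        assert (split.labels == 0).sum() == 0

    def test_contract_on_random_graphs(self, edge_frame):
        """L_N disjoint from L_P, no self-pairs, per-TF counts exact."""
        rng = np.random.default_rng(9)
        for trial in range(100):
            n = int(rng.integers(4, 15))
            genes = [f"g{i}" for i in range(n)]
            pairs = {(genes[i], genes[j])
                     for i, j in rng.integers(0, n, (n * 2, 2)) if i != j}
            if not pairs:
                continue
            g = gl.RegGraph(genes, sorted(pairs),
                            np.ones((n, 3)))
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                split = gl.sample_negatives(g, set(g.edges), seed=trial)
            pos = {e for e, y in zip(split.edges, split.labels) if y == 1}
            neg = [e for e, y in zip(split.edges, split.labels) if y == 0]
            assert pos == pairs
            assert not (set(neg) & pos)
            assert all(t != v for t, v in neg)
            per_tf = {}
            for t, _ in neg:
                per_tf[t] = per_tf.get(t, 0) + 1
            for tf in {t for t, _ in pairs}:
                eligible = n - len(g.neighbours(tf)) - 1
                expected = min(len(g.neighbours(tf)), eligible)
                assert per_tf.get(tf, 0) == expected

    def test_split_proportions(self, edge_frame):
        genes = [f"g{i}" for i in range(40)]
        rng = np.random.default_rng(2)
        pairs = sorted({(genes[i], genes[j])
                        for i, j in rng.integers(0, 40, (200, 2)) if i != j})
        g = gl.RegGraph(genes, pairs, np.ones((40, 3)))
        split = gl.sample_negatives(g, set(pairs), seed=0)
        for label in (0, 1):
            m = split.labels == label
            n = m.sum()
            n_val = (split.partition[m] == "val").sum()
            n_test = (split.partition[m] == "test").sum()
            assert abs(n_val - n / 10) <= 1
            assert abs(n_test - n / 10) <= 1


class TestFeatureReduction:
    def test_adaptive_pool_arithmetic(self):
        out = gl.adaptive_avg_pool(np.array([[1.0, 2.0, 3.0, 4.0]]), 2)
        np.testing.assert_allclose(out, [[1.5, 3.5]])

    def test_constant_vector(self):
        out = gl.adaptive_avg_pool(np.full((1, 7), 3.0), 3)
        np.testing.assert_allclose(out, 3.0)

    def test_fixed_output_length_across_sample_counts(self):
        a = gl.adaptive_avg_pool(np.random.default_rng(0).random((2, 3400)), 256)
        b = gl.adaptive_avg_pool(np.random.default_rng(0).random((2, 833)), 256)
        assert a.shape == b.shape == (2, 256)
        # upsampling path: fewer inputs than outputs still works
        c = gl.adaptive_avg_pool(np.array([[1.0, 2.0]]), 4)
        assert c.shape == (1, 4)


class TestAdjacencyAndEmbedding:
    def test_single_node_self_loop(self, edge_frame):
        g = gl.RegGraph(["a"], [], np.ones((1, 2)))
        A = gl.normalized_adjacency(g)
        np.testing.assert_allclose(A, [[1.0]])

    def test_symmetric_spectral_radius(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(3, 12))
            genes = [f"g{i}" for i in range(n)]
            pairs = sorted({(genes[i], genes[j])
                            for i, j in rng.integers(0, n, (n, 2)) if i != j})
            g = gl.RegGraph(genes, pairs, np.ones((n, 2)))
            A = gl.normalized_adjacency(g)
            np.testing.assert_allclose(A, A.T, atol=1e-12)
            eig = np.linalg.eigvalsh(A)
            assert np.max(np.abs(eig)) <= 1.0 + 1e-9

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(8)]
        pairs = sorted({(genes[i], genes[j])
                        for i, j in rng.integers(0, 8, (12, 2)) if i != j})
        X = rng.lognormal(2, 1, (8, 10))
        cfg = gl.ModelConfig(feature_len=8, embed_dim=4, hidden_dim=4,
                             dropout=0.0, seed=3)
        perm = rng.permutation(8)
        g1 = gl.RegGraph(genes, pairs, X)
        g2 = gl.RegGraph([genes[i] for i in perm], pairs, X[perm])

        net = gl._Net(cfg, np.random.default_rng(3))
        rng_d = np.random.default_rng(0)
        H1 = net.node_embeddings(gl.normalized_adjacency(g1),
                                 gl.reduce_features(X, 8), False, rng_d).data
        H2 = net.node_embeddings(gl.normalized_adjacency(g2),
                                 gl.reduce_features(X[perm], 8), False,
                                 rng_d).data
        np.testing.assert_allclose(H1[perm], H2, rtol=1e-4, atol=1e-5)

    def test_outer_product_properties(self):
        h_t, h_u = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        np.testing.assert_allclose(gl.edge_embed(h_t, h_u), [[0, 1], [0, 0]])
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=5), rng.normal(size=5)
        E = gl.edge_embed(a, b)
        assert not np.allclose(E, gl.edge_embed(b, a))
        assert np.linalg.norm(E) == pytest.approx(
            np.linalg.norm(a) * np.linalg.norm(b)
        )
        with pytest.raises(ValueError, match="mismatch"):
            gl.edge_embed(np.ones(3), np.ones(4))


class TestClassifierHead:
    def test_output_range_and_determinism(self):
        cfg = gl.ModelConfig(feature_len=8, embed_dim=8, hidden_dim=8,
                             dropout=0.0, seed=0)
        net = gl._Net(cfg, np.random.default_rng(0))
        rng = np.random.default_rng(1)
        H = nn.Tensor(rng.normal(size=(6, 8)))
        src, dst = np.array([0, 1, 2]), np.array([3, 4, 5])
        out1 = net.edge_logits(H, src, dst, False, rng)
        p = 1 / (1 + np.exp(-out1.data))
        assert np.all((p > 0) & (p < 1))
        out2 = net.edge_logits(H, src, dst, False, rng)
        np.testing.assert_array_equal(out1.data, out2.data)

    def test_zero_embedding_gives_bias(self):
        cfg = gl.ModelConfig(feature_len=8, embed_dim=8, hidden_dim=8,
                             dropout=0.0, seed=0)
        net = gl._Net(cfg, np.random.default_rng(0))
        # zero edge embeddings: the logit is a function of biases alone,
        # identical for every edge regardless of endpoints
        H = nn.Tensor(np.zeros((3, 8)))
        out = net.edge_logits(H, np.array([0, 1, 2]), np.array([1, 2, 0]),
                              False, np.random.default_rng(0))
        assert np.ptp(out.data) == 0.0
        # and nonzero embeddings break the degeneracy
        H2 = nn.Tensor(np.random.default_rng(2).normal(size=(3, 8)))
        out2 = net.edge_logits(H2, np.array([0, 1, 2]), np.array([1, 2, 0]),
                               False, np.random.default_rng(0))
        assert np.ptp(out2.data) > 0.0


class TestThresholdSweep:
    def test_separable_case(self):
        scores = np.array([0.9, 0.95, 0.1, 0.2])
        labels = np.array([1, 1, 0, 0])
        sweep = gl.threshold_postprocess(scores, labels)
        assert sweep.chosen == pytest.approx(0.9)
        assert sweep.f1[sweep.grid <= 0.9].min() >= 0.8

    def test_recall_non_increasing(self):
        rng = np.random.default_rng(0)
        scores = rng.random(200)
        labels = (rng.random(200) < 0.5).astype(float)
        sweep = gl.threshold_postprocess(scores, labels)
        assert np.all(np.diff(sweep.recall) <= 1e-12)

    def test_degenerate_warns(self):
        scores = np.full(10, 0.4)
        labels = np.array([1, 0] * 5)
        with pytest.warns(UserWarning, match="defaulting"):
            sweep = gl.threshold_postprocess(scores, labels)
        assert sweep.chosen == 0.5


class TestGradients:
    def test_full_stack_matches_finite_differences(self, monkeypatch):
        monkeypatch.setattr(nn, "DTYPE", np.float64)
        rng = np.random.default_rng(0)
        d = 6
        W = nn.Parameter(rng.normal(size=(d, d)) * 0.3)
        K1 = nn.Parameter(rng.normal(size=(2, 1, 3, 3)) * 0.3)
        b1 = nn.Parameter(np.zeros(2))
        Wo = nn.Parameter(rng.normal(size=(2, 1)) * 0.3)
        bo = nn.Parameter(np.zeros(1))
        X = rng.normal(size=(5, d))
        A = rng.random((5, 5))
        src, dst = np.array([0, 1, 2]), np.array([3, 4, 0])
        y = np.array([1.0, 0.0, 1.0])

        def forward():
            H = nn.Tensor(X).matmul(W).relu().left_matmul(A)
            E = nn.Tensor.outer_batch(H.gather_rows(src), H.gather_rows(dst))
            x = E.reshape(3, 1, d, d).conv2d(K1, b1).relu().global_avg_pool()
            return nn.bce_with_logits(
                x.matmul(Wo).add(bo).reshape(3), y
            )

        loss = forward()
        loss.backward()
        eps = 1e-6
        for p in (W, K1, b1, Wo, bo):
            g = p.grad.copy()
            idx = tuple(rng.integers(0, s) for s in p.data.shape)
            p.data[idx] += eps
            lp = float(forward().data)
            p.data[idx] -= 2 * eps
            lm = float(forward().data)
            p.data[idx] += eps
            num = (lp - lm) / (2 * eps)
            assert g[idx] == pytest.approx(num, rel=1e-4, abs=1e-8)


class TestTraining:
    @pytest.fixture(scope="class")
    def trained(self, request):
        small_world = request.getfixturevalue("small_world")
        truth, expr = small_world["truth"], small_world["expr"]
        edges = pd.DataFrame(
            {"tf": [e.tf for e in truth.edges],
             "target": [e.target for e in truth.edges]}
        )
        graph = gl.build_graph(edges, expr)
        split = gl.sample_negatives(graph, set(graph.edges), seed=0)
        cfg = gl.ModelConfig(feature_len=24, embed_dim=8, hidden_dim=16,
                             patience=30, max_epochs=120, seed=0)
        model, report = gl.train(graph, split, cfg)
        return graph, split, cfg, model, report

    def test_loss_decreases_initially(self, trained):
        _, _, _, _, report = trained
        losses = [h["train_loss"] for h in report["history"][:10]]
        assert losses[-1] < losses[0]

    def test_single_class_partition_rejected(self, edge_frame):
        genes = [f"g{i}" for i in range(6)]
        g = gl.RegGraph(genes, [("g0", "g1")], np.ones((6, 4)))
        split = gl.EdgeSplit([("g0", "g1")], np.ones(1),
                             np.array(["train"], dtype=object))
        with pytest.raises(ValueError, match="lacks both classes"):
            gl.train(g, split, gl.ModelConfig(feature_len=4, embed_dim=4))

    def test_scores_reproducible_under_fixed_weights(self, trained):
        graph, split, _, model, _ = trained
        s1 = model.score_edges(graph, split.edges[:20])
        s2 = model.score_edges(graph, split.edges[:20])
        np.testing.assert_array_equal(s1, s2)

    def test_save_load_roundtrip(self, trained, tmp_path):
        graph, split, _, model, _ = trained
        model.save(tmp_path / "m")
        back = gl.TrainedModel.load(tmp_path / "m")
        np.testing.assert_array_equal(
            model.score_edges(graph, split.edges[:10]),
            back.score_edges(graph, split.edges[:10]),
        )

    def test_shuffle_ablation_preserves_edge_count(self, trained):
        graph, *_ = trained
        rng = np.random.default_rng(7)
        n, m = graph.n_nodes, len(graph.edges)
        pairs = set()
        while len(pairs) < m:
            i, j = rng.integers(0, n, size=2)
            if i != j:
                pairs.add((int(i), int(j)))
        assert len(pairs) == m

    def test_grid_search_picks_best_val_auc(self, trained):
        graph, split, cfg, *_ = trained
        from dataclasses import replace

        base = replace(cfg, max_epochs=30, patience=10)
        model, report, trials = gl.grid_search(
            graph, split, base, {"dropout": [0.0, 0.5]}
        )
        assert len(trials) == 2
        best_auc = max(t["val_auc"] for t in trials)
        assert report["val"]["auc"] == best_auc

    def test_transfer_to_different_sample_count(self, trained):
        """A model trained on world A scores a world B with other n."""
        from dataclasses import replace

        from inferreg import synthetic

        graph, _, cfg, model, _ = trained
        cfg_b = replace(synthetic.SimConfig(
            n_tfs=8, n_genes=80, n_tissues=3, samples_per_tissue=6, seed=2,
        ))
        truth_b = synthetic.generate_grn(cfg_b)
        expr_b = synthetic.simulate_expression(truth_b, cfg_b)
        edges_b = pd.DataFrame(
            {"tf": [e.tf for e in truth_b.edges],
             "target": [e.target for e in truth_b.edges]}
        )
        graph_b = gl.build_graph(edges_b, expr_b)
        scored = gl.transfer_predict(model, graph_b)
        assert len(scored) == len(graph_b.edges)
        assert scored["gcn_score"].between(0, 1).all()
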