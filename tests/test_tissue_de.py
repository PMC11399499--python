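"""logCPM, voom weights, moderated contrasts, DEG calling, regulon assembly."""

import numpy as np
import pandas as pd
import pytest

from inferreg import synthetic, tissue_de as de
from inferreg.io_formats import ExpressionMatrix


def _expr(values, tissue_of, gene_ids=None):
    values = np.asarray(values, dtype=float)
    genes = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    samples = [f"s{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values,
                            {s: tissue_of[i] for i, s in enumerate(samples)})


def _design(expr):
    return np.array([
        [1.0 if expr.tissue_labels[s] == t else 0.0 for t in expr.tissues]
        for s in expr.sample_ids
    ])


class TestLogCpm:
    def test_analytic_value(self):
        # count 0, libsize 999,999: log2(0.5/1e6 * 1e6) = -1
        vals = np.array([[0.0], [999_999.0]])
        expr = _expr(vals, ["A"])
        y = de.logcpm(expr)
        assert y[0, 0] == pytest.approx(-1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(0)
        vals = rng.poisson(100, (20, 6)).astype(float)
        expr = _expr(vals, ["A"] * 3 + ["B"] * 3)
        y = de.logcpm(expr)
        lib = vals.sum(axis=0)
        expected = np.log2((vals + 0.5) / (lib + 1.0) * 1e6)
        np.testing.assert_allclose(y, expected, atol=1e-12)

    def test_monotone_in_count(self):
        vals = np.array([[1.0, 10.0], [100.0, 100.0]])
        expr = _expr(vals, ["A", "A"])
        y = de.logcpm(expr)
        assert y[0, 1] > y[0, 0] - np.log2(110 / 101) - 1e-9


class TestVoomWeights:
    def _sim(self, seed, heteroscedastic):
        rng = np.random.default_rng(seed)
        n_g, n_s = 400, 12
        tissue_of = ["A"] * 6 + ["B"] * 6
        base = rng.lognormal(4, 1.2, n_g)
        if heteroscedastic:
            counts = rng.negative_binomial(
                1 / 0.2, (1 / 0.2) / (1 / 0.2 + base[:, None]), (n_g, n_s)
            )
        else:
            counts = rng.poisson(base[:, None] * 0 + 200.0, (n_g, n_s))
        expr = _expr(counts.astype(float), tissue_of)
        return expr

    def test_weights_positive_and_clipped(self):
        expr = self._sim(1, True)
        w = de.voom_weights(de.logcpm(expr), _design(expr))
        assert np.all(w > 0)
        assert np.all(w <= 1e6)

    def test_homoscedastic_weights_flat(self):
        expr = self._sim(2, False)
        w = de.voom_weights(de.logcpm(expr), _design(expr))
        assert w.std() / w.mean() < 0.3

    def test_nb_weights_increase_with_mean(self):
        """NB counts: log-scale variance falls with mean, weights rise."""
        expr = self._sim(3, True)
        y = de.logcpm(expr)
        w = de.voom_weights(y, _design(expr))
        amean = y.mean(axis=1)
        lo = w[amean < np.quantile(amean, 0.3)].mean()
        hi = w[amean > np.quantile(amean, 0.7)].mean()
        assert hi > lo

    def test_insufficient_df_errors(self):
        expr = _expr(np.ones((5, 2)), ["A", "B"])
        with pytest.raises(ValueError):
            de.voom_weights(de.logcpm(expr), _design(expr))


class TestTmmFactors:
    def test_identical_libraries_give_unit_factors(self):
        rng = np.random.default_rng(11)
        base = rng.poisson(100, size=(300, 1)).astype(float)
        X = np.tile(base, (1, 5)) + rng.poisson(5, (300, 5))
        f = de.tmm_norm_factors(X)
        np.testing.assert_allclose(f, 1.0, atol=0.05)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)

    def test_corrects_composition_shift(self):
        """A sample where 20% of genes are 8x up gets a factor > 1."""
        rng = np.random.default_rng(12)
        base = rng.lognormal(4, 1, 500)
        mu = np.tile(base[:, None], (1, 6))
        mu[:100, 3:] *= 8.0  # composition shift in samples 3-5
        X = rng.poisson(mu).astype(float)
        f = de.tmm_norm_factors(X)
        # composition-inflated libraries get factors < 1 so that null-gene
        # CPMs become comparable again
        assert f[3:].mean() < 0.95
        # effective CPM of a null gene becomes comparable across samples
        lib_raw, lib_eff = X.sum(axis=0), X.sum(axis=0) * f
        null_cpm_raw = X[200] / lib_raw
        null_cpm_eff = X[200] / lib_eff
        spread = lambda v: abs(np.log2(v[3:].mean() / v[:3].mean()))
        assert spread(null_cpm_eff) < spread(null_cpm_raw)

    def test_agrees_with_edger(self, tmp_path):
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(13)
        base = rng.lognormal(4, 1, 400)
        mu = np.tile(base[:, None], (1, 4))
        mu[:80, 2:] *= 6.0
        X = rng.poisson(mu).astype(float)
        np.savetxt(tmp_path / "x.txt", X, fmt="%d")
        script = tmp_path / "tmm.R"
        script.write_text(
            "suppressMessages(library(edgeR))\n"
            f'x <- as.matrix(read.table("{tmp_path}/x.txt"))\n'
            'cat(calcNormFactors(x, method="TMM"), sep="\\n")\n'
        )
        try:
            out = subprocess.run(["Rscript", str(script)],
                                 capture_output=True, text=True,
                                 timeout=120, check=True)
        except (subprocess.CalledProcessError, subprocess.TimeoutExpired):
            pytest.skip("Rscript/edgeR not functional")
        ref = np.array([float(v) for v in out.stdout.split()])
        mine = de.tmm_norm_factors(X)
        np.testing.assert_allclose(mine, ref, rtol=0.05)


class TestBenjaminiHochberg:
    def test_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        for n in (1, 7, 100, 1000):
            p = rng.random(n)
            mine = de.benjamini_hochberg(p)
            # brute force: adj[i] = min over j with p_j >= p_i of p_j*m/rank_j
            order = np.argsort(p)
            brute = np.empty(n)
            running = 1.0
            for rank in range(n, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * n / rank)
                brute[i] = running
            np.testing.assert_allclose(mine, brute, atol=1e-12)

    def test_matches_r_p_adjust(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        p = rng.random(200)
        mine = de.benjamini_hochberg(p)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(mine, ref, atol=1e-12)


class TestContrasts:
    def test_planted_logfc_recovered(self):
        # few DE genes, so library-size composition stays negligible
        rng = np.random.default_rng(7)
        n_g = 1000
        n_de = 10
        tissue_of = ["A"] * 20 + ["B"] * 20
        base = rng.lognormal(4, 1, n_g)
        lfc = np.zeros(n_g)
        lfc[:n_de] = 3.0
        mu = np.tile(base[:, None], (1, 40))
        mu[:, :20] *= 2.0 ** lfc[:, None]
        counts = rng.negative_binomial(10, 10 / (10 + mu))
        expr = _expr(counts.astype(float), tissue_of)
        y = de.logcpm(expr)
        w = de.voom_weights(y, _design(expr))
        res = de.fit_contrasts(y, w, expr)
        sub = res[(res["tissue"] == "A")].set_index("gene_id")
        est = sub.loc[[f"g{i}" for i in range(n_de)], "logfc"]
        assert np.abs(est - 3.0).mean() < 0.3

    def test_null_moderated_t_centred(self):
        rng = np.random.default_rng(8)
        counts = rng.negative_binomial(
            10, 10 / (10 + 100.0), size=(2000, 30)
        )
        expr = _expr(counts.astype(float), ["A"] * 10 + ["B"] * 10 + ["C"] * 10)
        y = de.logcpm(expr)
        w = de.voom_weights(y, _design(expr))
        res = de.fit_contrasts(y, w, expr)
        t = res[res["tissue"] == "A"]["moderated_t"]
        assert abs(t.mean()) < 0.1

    def test_moderation_is_convex_combination(self):
        rng = np.random.default_rng(9)
        s2 = rng.chisquare(5, 500) / 5 * 0.3
        df0, s0 = de._fit_f_dist(s2, 5)
        post = (df0 * s0 + 5 * s2) / (df0 + 5)
        lo, hi = np.minimum(s2, s0), np.maximum(s2, s0)
        assert np.all(post >= lo - 1e-12) and np.all(post <= hi + 1e-12)

    def test_single_tissue_rejected(self):
        expr = _expr(np.ones((4, 4)) * 50, ["A"] * 4)
        with pytest.raises(ValueError, match="tissues"):
            de.fit_contrasts(de.logcpm(expr), np.ones((4, 4)), expr)


def test_fit_f_dist_matches_limma(tmp_path):
    """Empirical-Bayes prior fit agrees with the reference R implementation."""
    import shutil
    import subprocess

    if shutil.which("Rscript") is None:
        pytest.skip("Rscript unavailable")
    rng = np.random.default_rng(10)
    s2 = rng.chisquare(8, 300) / 8 * 0.5
    np.savetxt(tmp_path / "s2.txt", s2)
    script = tmp_path / "fit.R"
    script.write_text(
        'suppressMessages(library(limma))\n'
        f's2 <- scan("{tmp_path}/s2.txt", quiet=TRUE)\n'
        "f <- fitFDist(s2, df1=8)\n"
        'cat(f$scale, f$df2, sep="\\n")\n'
    )
    try:
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True,
            timeout=120, check=True,
        )
    except (subprocess.CalledProcessError, subprocess.TimeoutExpired):
        pytest.skip("Rscript/limma not functional")
    scale_r, df2_r = [float(x) for x in out.stdout.split()]
    df0, s0 = de._fit_f_dist(s2, 8.0)
    assert s0 == pytest.approx(scale_r, rel=1e-4)
    assert df0 == pytest.approx(df2_r, rel=1e-4)


class TestCallDegs:
    def _frame(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "tissue", "other", "logfc",
                           "moderated_t", "pvalue", "fdr"]
        )

    def test_threshold_rules(self):
        res = self._frame([
            ("g1", "A", "rest", 1.2, 5, 1e-4, 0.005),   # DEG
            ("g2", "A", "rest", 3.0, 5, 1e-3, 0.02),    # fdr too high
            ("g3", "A", "rest", -2.0, -5, 1e-5, 0.001), # downregulated
            ("g4", "A", "rest", 1.0, 5, 1e-5, 0.001),   # logfc not > 1
        ])
        assert de.call_degs(res) == {"A": {"g1"}}

    def test_pairwise_requires_all_contrasts(self):
        res = self._frame([
            ("g1", "A", "B", 2.0, 5, 1e-5, 1e-4),
            ("g1", "A", "C", 2.0, 5, 1e-5, 1e-4),
            ("g2", "A", "B", 2.0, 5, 1e-5, 1e-4),
            ("g2", "A", "C", 0.2, 1, 0.5, 0.9),
            ("g1", "B", "A", 0.1, 0, 0.9, 0.9),
            ("g1", "C", "A", 0.1, 0, 0.9, 0.9),
        ])
        out = de.call_degs(res, mode="pairwise")
        assert out["A"] == {"g1"}


class TestRegulons:
    def test_intersection_rule(self, edge_frame):
        degs = {"A": {"TF1", "g1"}, "B": {"TF1"}}
        edges = edge_frame(
            [("TF1", "g1"), ("TF1", "g2")],
            predicted=[True, True], gcn_score=[0.9, 0.8],
        )
        regs = de.assemble_regulons(degs, edges)
        assert regs.by_tissue["A"] == {"TF1": {"g1"}}
        assert regs.by_tissue["B"] == {}  # g1 not DEG in B -> empty, dropped

    def test_same_tf_different_targets_across_tissues(self, edge_frame):
        degs = {"A": {"TF1", "g1"}, "B": {"TF1", "g2"}}
        edges = edge_frame(
            [("TF1", "g1"), ("TF1", "g2")], predicted=[True, True],
            gcn_score=[0.9, 0.8],
        )
        regs = de.assemble_regulons(degs, edges)
        assert regs.by_tissue["A"]["TF1"] == {"g1"}
        assert regs.by_tissue["B"]["TF1"] == {"g2"}

    def test_only_predicted_edges_used(self, edge_frame):
        degs = {"A": {"TF1", "g1", "g2"}}
        edges = edge_frame(
            [("TF1", "g1"), ("TF1", "g2")], predicted=[True, False],
            gcn_score=[0.9, 0.2],
        )
        regs = de.assemble_regulons(degs, edges)
        assert regs.by_tissue["A"]["TF1"] == {"g1"}

    def test_json_roundtrip(self, tmp_path, edge_frame):
        degs = {"A": {"TF1", "g1"}}
        edges = edge_frame([("TF1", "g1")], predicted=[True], gcn_score=[0.9])
        regs = de.assemble_regulons(degs, edges)
        regs.to_json(tmp_path / "r.json")
        back = de.RegulonSet.from_json(tmp_path / "r.json")
        assert back.by_tissue == regs.by_tissue


def test_deg_recovery_on_synthetic_fixture():
    """Planted one-vs-rest effects are detected; unplanted genes are not."""
    cfg = synthetic.strong_signal_config(seed=3, n_tfs=20, n_genes=300)
    truth = synthetic.generate_grn(cfg)
    expr = synthetic.simulate_expression(truth, cfg)
    y = de.logcpm(expr)
    D = np.array([
        [1.0 if expr.tissue_labels[s] == t else 0.0 for t in expr.tissues]
        for s in expr.sample_ids
    ])
    w = de.voom_weights(y, D)
    res = de.fit_contrasts(y, w, expr)
    degs = de.call_degs(res)

    tissues = cfg.tissues
    true_pos, affected = set(), set()
    for gene in truth.gene_ids:
        lfc = {t: truth.planted_logfc.get((gene, t), 0.0) for t in tissues}
        for t in tissues:
            others = [lfc[x] for x in tissues if x != t]
            if lfc[t] - float(np.mean(others)) > 1.0:
                true_pos.add((gene, t))
        if any(v != 0 for v in lfc.values()):
            affected.add(gene)
    called = {(g, t) for t, genes in degs.items() for g in genes}
    sens = len(true_pos & called) / len(true_pos)
    null_genes = set(truth.gene_ids) - affected
    null_called = {g for g, _ in called if g in null_genes}
    fpr = len(null_called) / len(null_genes)
    assert sens >= 0.9
    assert fpr <= 0.02
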