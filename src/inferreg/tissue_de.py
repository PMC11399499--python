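"""Voom-style differential expression across tissues and regulon assembly.

Counts are transformed to log2 counts-per-million with the half-count
offset, a lowess trend of sqrt(residual SD) against average log-count
yields per-observation precision weights (trend^-4), and per-gene weighted
least squares on a tissue-means design gives each tissue's contrast
against the mean of the other tissues.  Gene-wise variances are moderated
with an empirical-Bayes scaled-F prior fitted by method of moments on the
log variances, giving moderated t statistics; p-values are BH-adjusted
within each contrast.  A gene is a tissue DEG when fdr < 0.01 and
logFC > 1 (upregulated only).  Tissue regulons are the predicted edges
whose TF and target are both DEGs of that tissue.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io_formats import ExpressionMatrix

__all__ = [
    "logcpm",
    "tmm_norm_factors",
    "voom_weights",
    "fit_contrasts",
    "call_degs",
    "benjamini_hochberg",
    "RegulonSet",
    "assemble_regulons",
]


def logcpm(
    expr: ExpressionMatrix, norm_factors: np.ndarray | None = None
) -> np.ndarray:
    """log2((count + 0.5) / (libsize + 1) × 1e6).

    ``norm_factors`` multiplies library sizes (TMM-style effective
    libraries); by default raw library sizes are used.
    """
    lib = expr.values.sum(axis=0)
    if np.any(lib == 0):
        raise ValueError("sample with zero library size")
    if norm_factors is not None:
        lib = lib * np.asarray(norm_factors, dtype=float)
    return np.log2((expr.values + 0.5) / (lib + 1.0) * 1e6)


def tmm_norm_factors(
    values: np.ndarray,
    logratio_trim: float = 0.3,
    abundance_trim: float = 0.05,
) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors per sample.

    Corrects library sizes for composition bias (a tissue whose regulons
    drive up a large slice of the transcriptome inflates its library and
    deflates every CPM).  The reference sample is the one whose upper
    quartile of nonzero relative counts is closest to the mean; factors
    are weighted trimmed means of the per-gene log ratios, rescaled to
    geometric mean 1.  Assumes a majority of genes are not differentially
    expressed between samples.
    """
    X = np.asarray(values, dtype=float)
    N = X.sum(axis=0)
    if np.any(N == 0):
        raise ValueError("sample with zero library size")
    uq = np.array([
        np.quantile(X[:, j][X[:, j] > 0] / N[j], 0.75) for j in range(X.shape[1])
    ])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    xr, Nr = X[:, ref], N[ref]
    f = np.ones(X.shape[1])
    for j in range(X.shape[1]):
        if j == ref:
            continue
        xi, Ni = X[:, j], N[j]
        ok = (xi > 0) & (xr > 0)
        if ok.sum() < 10:
            continue
        M = np.log2((xi[ok] / Ni) / (xr[ok] / Nr))
        A = 0.5 * np.log2((xi[ok] / Ni) * (xr[ok] / Nr))
        # inverse asymptotic variance of M (delta method on two binomials)
        w = (Ni - xi[ok]) / (Ni * xi[ok]) + (Nr - xr[ok]) / (Nr * xr[ok])
        mlo, mhi = np.quantile(M, [logratio_trim, 1 - logratio_trim])
        alo, ahi = np.quantile(A, [abundance_trim, 1 - abundance_trim])
        keep = (M >= mlo) & (M <= mhi) & (A >= alo) & (A <= ahi)
        if keep.sum() == 0:
            continue
        f[j] = 2.0 ** (np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    return f / np.exp(np.mean(np.log(f)))


def _design(expr: ExpressionMatrix) -> tuple[np.ndarray, list[str]]:
    tissues = expr.tissues
    labels = [expr.tissue_labels[s] for s in expr.sample_ids]
    D = np.array([[1.0 if lab == t else 0.0 for t in tissues] for lab in labels])
    return D, tissues

def _group_counts(D: np.ndarray) -> np.ndarray:
    return D.sum(axis=0)


def voom_weights(
    y: np.ndarray, design: np.ndarray, span: float = 0.5
) -> np.ndarray:
    """Per-observation precision weights from the mean–variance trend.

    ``y`` is the logCPM matrix (genes × samples), ``design`` a full-rank
    group-membership matrix.  Fits per-gene OLS, smooths sqrt(residual SD)
    against average log-count with lowess, evaluates the trend at each
    observation's fitted value, and returns trend^-4 clipped to
    [1e-6, 1e6].
    """
    n, p = design.shape[0], design.shape[1]
    df_resid = n - p
    if df_resid < 1:
        raise ValueError("fewer than 1 residual degree of freedom")
    counts = _group_counts(design)
    if np.any(counts < 2):
        raise ValueError("need >= 2 samples per tissue")
    # per-gene group means and residual SD (cell-means design: closed form)
    means = (y @ design) / counts  # genes × groups
    fitted = means @ design.T
    resid = y - fitted
    s = np.sqrt((resid**2).sum(axis=1) / df_resid)
    amean = y.mean(axis=1)
    sqrt_s = np.sqrt(np.sqrt(s**2 + 1e-12))  # sqrt of SD
    smooth = lowess(sqrt_s, amean, frac=span, return_sorted=True)
    xs, ys = smooth[:, 0], smooth[:, 1]
    trend = np.interp(fitted, xs, ys)
    trend = np.clip(trend, 1e-3, None)
    return np.clip(trend**-4.0, 1e-6, 1e6)


def _trigamma_inverse(x: np.ndarray) -> np.ndarray:
    """Solve trigamma(y) = x by Newton iteration (vectorized)."""
    x = np.asarray(x, dtype=float)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y = y - dif
        if np.all(np.abs(dif) < 1e-10 * y):
            break
    return y


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moments fit of a scaled-F prior to gene variances → (df0, s0²)."""
    s2 = np.clip(s2, 1e-10, None)
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar > 0:
        df0 = 2.0 * float(_trigamma_inverse(np.array([evar]))[0])
        s0_2 = float(np.exp(emean + special.digamma(df0 / 2.0) - np.log(df0 / 2.0)))
    else:
        # no excess spread beyond sampling noise: infinitely strong prior
        df0 = np.inf
        s0_2 = float(np.mean(s2))
    return df0, s0_2


def fit_contrasts(
    y: np.ndarray,
    weights: np.ndarray,
    expr: ExpressionMatrix,
    mode: str = "rest",
) -> pd.DataFrame:
    """Moderated one-vs-rest (or all pairwise) tissue contrasts.

    Returns a frame with columns gene_id, tissue, other, logfc,
    moderated_t, pvalue, fdr.  ``mode='rest'`` contrasts each tissue mean
    against the mean of the other tissue means; ``mode='pairwise'`` emits
    every ordered pair.
    """
    D, tissues = _design(expr)
    if len(tissues) < 2:
        raise ValueError("need >= 2 tissues")
    counts = _group_counts(D)
    n, p = D.shape
    df_resid = n - p
    G = y.shape[0]
    w = np.asarray(weights, dtype=float)

    # weighted group means and unscaled variances per gene
    sw = w @ D  # genes × groups: sum of weights
    mu = (w * y) @ D / sw
    fitted = mu @ D.T
    s2 = (w * (y - fitted) ** 2).sum(axis=1) / df_resid
    var_mu = 1.0 / sw  # unscaled variance of each group mean

    df0, s0_2 = _fit_f_dist(s2, df_resid)
    s2_post = (
        (df0 * s0_2 + df_resid * s2) / (df0 + df_resid)
        if np.isfinite(df0)
        else np.full(G, s0_2)
    )
    df_total = df0 + df_resid if np.isfinite(df0) else np.inf

    T = len(tissues)
    rows = []
    pairs = (
        [(i, None) for i in range(T)]
        if mode == "rest"
        else [(i, j) for i in range(T) for j in range(T) if i != j]
    )
    for i, j in pairs:
        if j is None:
            others = [k for k in range(T) if k != i]
            lfc = mu[:, i] - mu[:, others].mean(axis=1)
            uvar = var_mu[:, i] + var_mu[:, others].sum(axis=1) / (T - 1) ** 2
            other_name = "rest"
        else:
            lfc = mu[:, i] - mu[:, j]
            uvar = var_mu[:, i] + var_mu[:, j]
            other_name = tissues[j]
        tstat = lfc / np.sqrt(s2_post * uvar)
        if np.isfinite(df_total):
            pval = 2.0 * stats.t.sf(np.abs(tstat), df_total)
        else:
            pval = 2.0 * stats.norm.sf(np.abs(tstat))
        fdr = benjamini_hochberg(pval)
        for g in range(G):
            rows.append(
                (expr.gene_ids[g], tissues[i], other_name,
                 float(lfc[g]), float(tstat[g]), float(max(pval[g], 5e-324)),
                 float(max(fdr[g], 5e-324)))
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "tissue", "other", "logfc", "moderated_t",
                 "pvalue", "fdr"],
    )


def benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out


def call_degs(
    results: pd.DataFrame, fdr_max: float = 0.01, lfc_min: float = 1.0,
    mode: str = "rest",
) -> dict[str, set[str]]:
    """Per-tissue upregulated DEG sets at fdr < fdr_max and logFC > lfc_min.

    In pairwise mode a gene must pass against every other tissue.
    """
    hits = results[(results["fdr"] < fdr_max) & (results["logfc"] > lfc_min)]
    tissues = sorted(results["tissue"].unique())
    out: dict[str, set[str]] = {}
    if mode == "rest":
        for t in tissues:
            out[t] = set(hits.loc[hits["tissue"] == t, "gene_id"])
    else:
        n_other = len(tissues) - 1
        for t in tissues:
            sub = hits[hits["tissue"] == t]
            cnt = sub.groupby("gene_id")["other"].nunique()
            out[t] = set(cnt.index[cnt == n_other])
    return out


@dataclass
class RegulonSet:
    """tissue → TF → set of target genes, with per-edge score provenance."""

    by_tissue: dict[str, dict[str, set[str]]]
    edge_scores: dict[tuple[str, str], float] = field(default_factory=dict)

    def network_edges(self, tissue: str) -> list[tuple[str, str]]:
        reg = self.by_tissue.get(tissue, {})
        return [(tf, tg) for tf, tgs in reg.items() for tg in sorted(tgs)]

    def to_json(self, path: str | Path) -> None:
        payload = {
            tis: {tf: sorted(tgs) for tf, tgs in regs.items()}
            for tis, regs in self.by_tissue.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "RegulonSet":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            {tis: {tf: set(tgs) for tf, tgs in regs.items()}
             for tis, regs in payload.items()}
        )


def assemble_regulons(
    degs: dict[str, set[str]], predicted_edges: pd.DataFrame
) -> RegulonSet:
    """Tissue regulons: predicted edges whose TF and target are tissue DEGs."""
    pred = predicted_edges
    if "predicted" in pred.columns:
        pred = pred[pred["predicted"].fillna(False).astype(bool)]
    scores = {}
    if "gcn_score" in pred.columns:
        scores = {
            (t, u): float(s) if s == s else float("nan")
            for t, u, s in zip(pred["tf"], pred["target"], pred["gcn_score"])
        }
    by_tissue: dict[str, dict[str, set[str]]] = {}
    for tissue, genes in degs.items():
        regs: dict[str, set[str]] = {}
        for tf, tg in zip(pred["tf"], pred["target"]):
            if tf in genes and tg in genes:
                regs.setdefault(tf, set()).add(tg)
        by_tissue[tissue] = {tf: tgs for tf, tgs in regs.items() if tgs}
    return RegulonSet(by_tissue, scores)
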