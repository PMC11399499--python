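"""Co-expression edge scoring and the first two filter stages.

Candidate TF→target edges are scored by a stochastic gradient-boosted tree
ensemble: each target gene's log1p(CPM) expression is regressed on all TF
expressions, and a TF's importance (IM) for the target is its share of the
ensemble's total split gain, normalized to sum to 1 over TFs per target.
Edges are then filtered by IM (inclusive threshold, default 0.005) and by
the pooled-sample Spearman correlation (strict signed threshold, default
0.03).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingRegressor

from .io_formats import EDGE_COLUMNS, ExpressionMatrix

__all__ = [
    "FilterConfig",
    "importance_scores",
    "filter_importance",
    "spearman_filter",
    "log1p_cpm",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterConfig:
    """IM filter is inclusive (>=), Spearman is strict and signed (>)."""

    im_min: float = 0.005
    rho_min: float = 0.03
    rho_absolute: bool = False

    def __post_init__(self) -> None:
        if self.im_min < 0:
            raise ValueError("im_min must be >= 0")


def log1p_cpm(expr: ExpressionMatrix) -> np.ndarray:
    """log1p of counts-per-million, the regression scale for tree fitting."""
    libsize = expr.values.sum(axis=0)
    if np.any(libsize == 0):
        raise ValueError("sample with zero library size")
    return np.log1p(expr.values / libsize * 1e6)


def importance_scores(
    expr: ExpressionMatrix,
    tf_ids: list[str],
    seed: int = 0,
    n_estimators: int = 500,
    learning_rate: float = 0.01,
    subsample: float = 0.9,
    max_features: float = 0.1,
    early_stop_rounds: int = 25,
) -> pd.DataFrame:
    """Per-target boosted-tree importances for every TF.

    Returns an edge table with one row per (tf, target) with importance
    > 0.  Zero-variance targets yield no rows (logged, not fatal).
    ``max_features`` (fraction of TFs considered per split) keeps
    attribution spread across correlated TFs: with all features available
    at every split, one member of a co-expressed TF group absorbs the
    whole signal and the others get exactly zero importance.
    """
    gene_idx = expr.gene_index()
    missing = [t for t in tf_ids if t not in gene_idx]
    if missing:
        raise ValueError(f"TFs absent from expression matrix: {missing[:5]}")
    if expr.n_samples < 2:
        raise ValueError("need at least 2 samples")

    X_all = log1p_cpm(expr)
    tf_rows = np.array([gene_idx[t] for t in tf_ids])
    tf_mat = X_all[tf_rows].T  # samples × TFs
    rows = []
    rng = np.random.default_rng(seed)
    for gi, gene in enumerate(expr.gene_ids):
        y = X_all[gi]
        if np.ptp(y) == 0:
            log.info("zero-variance target %s skipped", gene)
            continue
        if gene in tf_ids:
            cols = [j for j, t in enumerate(tf_ids) if t != gene]
            if not cols:
                continue
            X = tf_mat[:, cols]
            names = [tf_ids[j] for j in cols]
        else:
            X = tf_mat
            names = tf_ids
        model = GradientBoostingRegressor(
            n_estimators=n_estimators,
            learning_rate=learning_rate,
            subsample=subsample,
            max_features=max(1, int(round(max_features * X.shape[1]))),
            max_depth=3,
            validation_fraction=0.1,
            n_iter_no_change=early_stop_rounds,
            random_state=int(rng.integers(2**31 - 1)),
        )
        model.fit(X, y)
        imp = model.feature_importances_
        total = imp.sum()
        if total <= 0:
            continue
        imp = imp / total
        for name, v in zip(names, imp):
            if v > 0:
                rows.append((name, gene, float(v)))
    df = pd.DataFrame(rows, columns=["tf", "target", "importance"])
    return df.reindex(columns=EDGE_COLUMNS)


def filter_importance(edges: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Keep rows with importance >= im_min, order preserved."""
    if edges.empty:
        return edges
    return edges[edges["importance"] >= cfg.im_min].reset_index(drop=True)


def spearman_filter(
    edges: pd.DataFrame, expr: ExpressionMatrix, cfg: FilterConfig
) -> pd.DataFrame:
    """Attach pooled-sample Spearman rho and keep rows with rho > rho_min.

    Tie-corrected rank correlation over all samples pooled.  Constant
    genes have undefined rho; their rows are dropped with a log entry.
    With ``cfg.rho_absolute`` the filter uses \\|rho\\| instead of signed rho.
    """
    if edges.empty:
        return edges
    gene_idx = expr.gene_index()
    missing = sorted(
        {g for g in pd.concat([edges["tf"], edges["target"]]) if g not in gene_idx}
    )
    if missing:
        raise ValueError(f"edge genes absent from expression: {missing[:5]}")
    # rank once per gene, then Pearson on ranks (tie-corrected == spearman)
    needed = sorted({*edges["tf"], *edges["target"]}, key=gene_idx.get)
    ranks = {}
    const = set()
    for g in needed:
        v = expr.values[gene_idx[g]]
        if np.ptp(v) == 0:
            const.add(g)
            continue
        r = stats.rankdata(v)
        ranks[g] = (r - r.mean()) / np.sqrt(((r - r.mean()) ** 2).sum())
    rhos = np.empty(len(edges))
    keep = np.ones(len(edges), dtype=bool)
    for i, (tf, tg) in enumerate(zip(edges["tf"], edges["target"])):
        if tf in const or tg in const:
            log.info("constant gene in edge (%s, %s): rho undefined, dropped", tf, tg)
            keep[i] = False
            rhos[i] = np.nan
            continue
        rhos[i] = float(ranks[tf] @ ranks[tg])
    out = edges.copy()
    out["spearman_rho"] = rhos
    stat = np.abs(rhos) if cfg.rho_absolute else rhos
    with np.errstate(invalid="ignore"):
        keep &= stat > cfg.rho_min
    return out[keep].reset_index(drop=True)
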