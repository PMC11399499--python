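"""Regulon prioritization by centrality, GO specificity, and Borda ranks.

Each tissue's regulons form a directed TF→target network.  Every regulon
(TF) is scored by out-degree, closeness centrality over outgoing paths
(Wasserman–Faust normalization, well-defined on disconnected graphs),
unnormalized directed betweenness, and the hypergeometric enrichment of
its target set in a tissue gold-standard gene set (−log10 of the upper
tail).  Each metric yields a tie-averaged ranking (1 = best); the Borda
score is the geometric mean of the four ranks and the final order ascends
in it.  Retrieval of a gold-standard set along a ranking is summarized by
R50, the depth at which half the gold set has been recovered.
"""

from __future__ import annotations

import math
import re
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TISSUE_KEYWORDS",
    "EVIDENCE_WHITELIST",
    "regulon_network",
    "centrality_scores",
    "go_specificity",
    "rank_metrics",
    "borda_combine",
    "r50_curve",
    "rank_table_summary",
    "build_go_gold_standard",
    "prioritize_tissue",
]

#: Default tissue → GO-term keywords for gold-standard construction.
TISSUE_KEYWORDS: dict[str, tuple[str, ...]] = {
    "flower": ("flower", "floral", "inflorescence", "anther", "stamen",
               "pistil", "carpel", "petal", "sepal", "pollen", "pollination",
               "fertilization"),
    "leaf": ("leaf", "foliage", "photosynthesis", "chloroplast", "stomata",
             "mesophyll", "cuticle"),
    "root": ("root", "xylem", "phloem", "vascular", "trichoblast", "trichome",
             "vasculature", "stele", "tracheary", "procambium", "sieve"),
    "seed": ("seed", "embryo", "endosperm", "aleurone", "maturation", "testa",
             "embryogenesis"),
    "seedling": ("seedling", "cotyledon", "hypocotyl", "epicotyl",
                 "germination", "plumule", "radicle", "shoot"),
}

#: Experimental / curated GO evidence codes accepted for the gold standard.
EVIDENCE_WHITELIST = frozenset(
    {"EXP", "IMP", "IDA", "IPI", "IGI", "IEP", "TAS", "NAS", "IC"}
)


def regulon_network(regulons, tissue: str) -> nx.DiGraph:
    """Directed TF→target network of one tissue's regulons."""
    if tissue not in regulons.by_tissue or not regulons.by_tissue[tissue]:
        raise ValueError(f"no regulons for tissue {tissue!r}")
    g = nx.DiGraph()
    for tf, tgs in regulons.by_tissue[tissue].items():
        for tg in tgs:
            g.add_edge(tf, tg)
    return g


def centrality_scores(graph: nx.DiGraph) -> pd.DataFrame:
    """Out-degree, outgoing closeness (Wasserman–Faust), betweenness.

    Closeness of node v is ((r−1)/(n−1)) · ((r−1)/Σd) where r counts nodes
    reachable FROM v (v included) and Σd sums shortest-path distances from
    v; betweenness is standard directed shortest-path betweenness,
    unnormalized.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    out_deg = dict(graph.out_degree())
    # networkx closeness uses incoming distances; reverse for outgoing
    closeness = nx.closeness_centrality(graph.reverse(), wf_improved=True)
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    nodes = sorted(graph.nodes())
    return pd.DataFrame(
        {
            "out_degree": [out_deg[n] for n in nodes],
            "closeness": [closeness[n] for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
        },
        index=nodes,
    )


def go_specificity(
    regulons,
    tissue: str,
    gold: Mapping[str, set[str]],
    universe: set[str],
) -> pd.Series:
    """−log10 hypergeometric upper-tail enrichment per regulon.

    Overlap k between the regulon's target set (size n) and the tissue
    gold set (size K) in a universe of N genes; p = P(X ≥ k).
    """
    tissue_set = set(gold.get(tissue, set())) & universe
    if not tissue_set:
        raise ValueError(f"empty gold set for tissue {tissue!r}")
    regs = regulons.by_tissue.get(tissue, {})
    missing = {g for tgs in regs.values() for g in tgs} - universe
    if missing:
        raise ValueError(f"regulon genes outside universe: {sorted(missing)[:3]}")
    N, K = len(universe), len(tissue_set)
    out = {}
    for tf, tgs in regs.items():
        n = len(tgs)
        k = len(tgs & tissue_set)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        out[tf] = -math.log10(max(p, 5e-324))
    return pd.Series(out).sort_index()


def rank_metrics(scores: Sequence[float]) -> np.ndarray:
    """Descending scores → ascending tie-averaged ranks starting at 1."""
    return stats.rankdata(-np.asarray(scores, dtype=float), method="average")


def borda_combine(rank_vectors: Sequence[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Geometric mean of per-metric ranks and the resulting final ranking."""
    lens = {len(r) for r in rank_vectors}
    if len(lens) != 1:
        raise ValueError("rank vectors of unequal length")
    R = np.vstack([np.asarray(r, dtype=float) for r in rank_vectors])
    if R.shape[1] == 0:
        raise ValueError("no regulons to combine")
    if np.any(R <= 0):
        raise ValueError("ranks must be positive")
    geo = np.exp(np.log(R).mean(axis=0))
    final = stats.rankdata(geo, method="average")
    return geo, final


def r50_curve(
    ranking: Sequence[str], gold: set[str]
) -> tuple[np.ndarray, int | None]:
    """Cumulative gold retrieval curve and the depth reaching half of gold."""
    if not gold:
        raise ValueError("empty gold set")
    hits = np.array([1 if r in gold else 0 for r in ranking])
    curve = np.cumsum(hits)
    half = math.ceil(len(gold) / 2)
    where = np.nonzero(curve >= half)[0]
    r50 = int(where[0]) + 1 if len(where) else None
    return curve, r50


def rank_table_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-metric column mean and sample SD (n−1); SD missing for n=1."""
    mean = table.mean(axis=0)
    sd = table.std(axis=0, ddof=1) if len(table) > 1 else mean * np.nan
    return pd.DataFrame({"mean": mean, "sd": sd})


def build_go_gold_standard(
    annotations: pd.DataFrame,
    keywords: Mapping[str, Iterable[str]] | None = None,
) -> dict[str, set[str]]:
    """Tissue gold sets from a gene–term table with evidence codes.

    ``annotations`` needs columns gene_id, term_name, evidence_code.  A
    gene enters a tissue's set when ≥1 of its annotations matches any
    tissue keyword (case-insensitive substring of the term name) and has a
    whitelisted (experimental or curated) evidence code.
    """
    kw = {t: tuple(v) for t, v in (keywords or TISSUE_KEYWORDS).items()}
    for t, words in kw.items():
        if not words:
            raise ValueError(f"empty keyword list for tissue {t!r}")
    need = {"gene_id", "term_name", "evidence_code"}
    if not need <= set(annotations.columns):
        raise ValueError(f"annotation table needs columns {sorted(need)}")
    ok = annotations[annotations["evidence_code"].isin(EVIDENCE_WHITELIST)]
    terms = ok["term_name"].str.lower()
    out: dict[str, set[str]] = {}
    for tissue, words in kw.items():
        pat = "|".join(re.escape(w.lower()) for w in words)
        m = terms.str.contains(pat, regex=True, na=False)
        out[tissue] = set(ok.loc[m, "gene_id"])
    return out


def prioritize_tissue(
    regulons,
    tissue: str,
    gold: Mapping[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """Full rank table for one tissue's regulons.

    Columns: raw scores, per-metric ranks, borda_geomean, final_rank; one
    row per regulon TF, sorted by final rank.
    """
    g = regulon_network(regulons, tissue)
    cents = centrality_scores(g)
    tfs = sorted(regulons.by_tissue[tissue])
    go = go_specificity(regulons, tissue, gold, universe)
    table = pd.DataFrame(
        {
            "out_degree": cents.loc[tfs, "out_degree"].to_numpy(dtype=float),
            "closeness": cents.loc[tfs, "closeness"].to_numpy(),
            "betweenness": cents.loc[tfs, "betweenness"].to_numpy(),
            "go_specificity": go.loc[tfs].to_numpy(),
        },
        index=tfs,
    )
    ranks = {c: rank_metrics(table[c]) for c in table.columns}
    for c, r in ranks.items():
        table[f"rank_{c}"] = r
    geo, final = borda_combine(list(ranks.values()))
    table["borda_geomean"] = geo
    table["final_rank"] = final
    return table.sort_values("final_rank")
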