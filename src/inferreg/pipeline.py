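"""End-to-end pipeline orchestration over a fixture-bundle directory.

A bundle directory holds the pipeline inputs in plain formats:
``counts.tsv`` + ``tissues.tsv`` (expression), ``genome.fa``,
``genes.gff3``, ``tfs.tsv`` (TF list with families), ``motifs.meme`` +
``motif_map.tsv``, and ``peaks/<tf>.bed``.  ``run_pipeline`` executes the
stage DAG, writes one plain TSV/JSON artifact per stage, logs per-stage
edge counts, and asserts the filter-stage counts are non-increasing.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import chip_labels, coexpression, gcn_linkpred, motif_scan, tissue_de
from .io_formats import (
    read_annotation,
    read_edges,
    read_expression,
    read_motifs,
    read_peaks,
    read_tf_table,
    write_edges,
)

__all__ = ["PipelineConfig", "run_pipeline", "load_bundle"]

log = logging.getLogger(__name__)

STAGES = ["coexpr", "scan", "label", "train", "de", "regulons"]


@dataclass
class PipelineConfig:
    """All stage thresholds in one validated, YAML-loadable object."""

    im_min: float = 0.005
    rho_min: float = 0.03
    upstream_bp: int = 2000
    p_max: float = 1e-4
    cluster_window: int = 200
    cluster_min: float = 5.0
    motif_min: float = 6.0
    min_overlap_bp: int = 1
    feature_len: int = 256
    embed_dim: int = 64
    hidden_dim: int = 64
    dropout: float = 0.5
    lr: float = 0.005
    weight_decay: float = 1e-4
    patience: int = 200
    max_epochs: int = 1000
    grid_start: float = 0.5
    grid_end: float = 1.0
    grid_step: float = 0.01
    f1_floor: float = 0.8
    fdr_max: float = 0.01
    lfc_min: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]

    def model_config(self) -> gcn_linkpred.ModelConfig:
        return gcn_linkpred.ModelConfig(
            feature_len=self.feature_len,
            embed_dim=self.embed_dim,
            hidden_dim=self.hidden_dim,
            dropout=self.dropout,
            lr=self.lr,
            weight_decay=self.weight_decay,
            patience=self.patience,
            max_epochs=self.max_epochs,
            seed=self.seed,
        )


@dataclass
class Bundle:
    expr: object
    annotations: list
    tf_families: dict[str, str]
    genome: dict[str, str]
    motifs: list
    peaks: list
    dir: Path = field(default=None)


def load_bundle(bundle_dir: str | Path) -> Bundle:
    bundle_dir = Path(bundle_dir)
    expr = read_expression(bundle_dir / "counts.tsv", bundle_dir / "tissues.tsv")
    tf_families = read_tf_table(bundle_dir / "tfs.tsv")
    annotations = read_annotation(bundle_dir / "genes.gff3", tf_families)
    genome = _read_fasta(bundle_dir / "genome.fa")
    motif_map = bundle_dir / "motif_map.tsv"
    motifs = read_motifs(
        bundle_dir / "motifs.meme", motif_map if motif_map.exists() else None
    )
    peaks = []
    peak_dir = bundle_dir / "peaks"
    if peak_dir.is_dir():
        for p in sorted(peak_dir.glob("*.bed")):
            peaks.append(read_peaks(p, p.stem))
    return Bundle(expr, annotations, tf_families, genome, motifs, peaks,
                  dir=bundle_dir)


def _read_fasta(path: Path) -> dict[str, str]:
    import pyfaidx

    with pyfaidx.Fasta(str(path)) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def run_pipeline(
    bundle_dir: str | Path,
    out_dir: str | Path,
    cfg: PipelineConfig | None = None,
    stages: list[str] | None = None,
) -> dict:
    """Run the stage DAG (a prefix of: coexpr scan label train de regulons).

    Writes per-stage artifacts into ``out_dir`` and returns the run
    report.  Candidate edge counts must be non-increasing through the
    IM → Spearman → TFBS → ChIP filter cascade; this is asserted.
    """
    cfg = cfg or PipelineConfig()
    stages = stages or STAGES
    if stages != STAGES[: len(stages)]:
        raise ValueError(f"stages must be a prefix of {STAGES}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    bundle = load_bundle(bundle_dir)
    fcfg = coexpression.FilterConfig(im_min=cfg.im_min, rho_min=cfg.rho_min)
    tf_ids = sorted(bundle.tf_families)

    import sklearn

    from . import __version__

    report: dict = {
        "config_hash": cfg.content_hash(),
        "seed": cfg.seed,
        "versions": {
            "inferreg": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "sklearn": sklearn.__version__,
        },
        "stages": {},
        "counts": {},
    }

    def record(stage: str, t0: float, **info):
        report["stages"][stage] = {"seconds": round(time.time() - t0, 3), **info}

    edges = None
    if "coexpr" in stages:
        t0 = time.time()
        raw = coexpression.importance_scores(bundle.expr, tf_ids, seed=cfg.seed)
        report["counts"]["grnboost"] = len(raw)
        edges = coexpression.filter_importance(raw, fcfg)
        report["counts"]["im_filter"] = len(edges)
        edges = coexpression.spearman_filter(edges, bundle.expr, fcfg)
        report["counts"]["spearman_filter"] = len(edges)
        write_edges(edges, out_dir / "edges_coexpr.tsv")
        record("coexpr", t0)

    promoters = None
    if "scan" in stages:
        t0 = time.time()
        if edges is None:
            edges = read_edges(out_dir / "edges_coexpr.tsv")
        lengths = {c: len(s) for c, s in bundle.genome.items()}
        promoters = motif_scan.promoter_regions(
            bundle.annotations, lengths, cfg.upstream_bp
        )
        hits = motif_scan.scan_sites(
            promoters, bundle.genome, bundle.motifs, p_max=cfg.p_max
        )
        site_conf = {(h.motif_id, h.gene_id) for h in hits}
        cluster_conf = motif_scan.scan_clusters(
            hits, cfg.cluster_window, cfg.cluster_min, cfg.motif_min
        )
        mapping = motif_scan.share_family_motifs(bundle.motifs, bundle.annotations)
        edges = motif_scan.tfbs_filter(edges, site_conf, cluster_conf, mapping)
        report["counts"]["tfbs_filter"] = len(edges)
        write_edges(edges, out_dir / "edges_tfbs.tsv")
        record("scan", t0, n_hits=len(hits))

    if "label" in stages:
        t0 = time.time()
        if edges is None:
            edges = read_edges(out_dir / "edges_tfbs.tsv")
        if promoters is None:
            lengths = {c: len(s) for c, s in bundle.genome.items()}
            promoters = motif_scan.promoter_regions(
                bundle.annotations, lengths, cfg.upstream_bp
            )
        edges = chip_labels.label_edges(
            edges, promoters, bundle.peaks, cfg.min_overlap_bp
        )
        report["counts"]["chip_positive"] = int((edges["chip_label"] == "positive").sum())
        write_edges(edges, out_dir / "edges_labeled.tsv")
        record("label", t0)

    _assert_monotone(report["counts"])

    scored = None
    if "train" in stages:
        t0 = time.time()
        if edges is None:
            edges = read_edges(out_dir / "edges_labeled.tsv")
        graph = gcn_linkpred.build_graph(edges, bundle.expr)
        positives = {
            (t, u)
            for t, u, lab in zip(edges["tf"], edges["target"], edges["chip_label"])
            if lab == "positive"
        }
        if not positives:
            raise ValueError("no ChIP-positive edges; cannot train")
        split = gcn_linkpred.sample_negatives(graph, positives, cfg.seed)
        model, metrics = gcn_linkpred.train(graph, split, cfg.model_config())
        va_e, va_y = split.part("val")
        sweep = gcn_linkpred.threshold_postprocess(
            model.score_edges(graph, va_e), va_y,
            cfg.grid_start, cfg.grid_end, cfg.grid_step, cfg.f1_floor,
        )
        model.threshold = sweep.chosen
        model.save(out_dir / "model")
        scores = model.score_edges(graph, list(zip(edges["tf"], edges["target"])))
        scored = edges.copy()
        scored["gcn_score"] = scores
        scored["predicted"] = scores >= model.threshold
        report["counts"]["gcn_predicted"] = int(scored["predicted"].sum())
        write_edges(scored, out_dir / "edges_scored.tsv")
        hist = metrics.pop("history", None)
        record("train", t0, threshold=model.threshold,
               test_auc=metrics["test"]["auc"], n_epochs=len(hist or []))

    degs = None
    if "de" in stages:
        t0 = time.time()
        factors = tissue_de.tmm_norm_factors(bundle.expr.values)
        y = tissue_de.logcpm(bundle.expr, factors)
        D = np.array([
            [1.0 if bundle.expr.tissue_labels[s] == t else 0.0
             for t in bundle.expr.tissues]
            for s in bundle.expr.sample_ids
        ])
        w = tissue_de.voom_weights(y, D)
        results = tissue_de.fit_contrasts(y, w, bundle.expr)
        results.to_csv(out_dir / "de_results.tsv", sep="\t", index=False)
        degs = tissue_de.call_degs(results, cfg.fdr_max, cfg.lfc_min)
        with open(out_dir / "degs.json", "w") as fh:
            json.dump({t: sorted(g) for t, g in degs.items()}, fh, indent=1)
        record("de", t0, **{f"n_degs_{t}": len(g) for t, g in degs.items()})

    if "regulons" in stages:
        t0 = time.time()
        if scored is None:
            scored = read_edges(out_dir / "edges_scored.tsv")
        if degs is None:
            with open(out_dir / "degs.json") as fh:
                degs = {t: set(g) for t, g in json.load(fh).items()}
        regulons = tissue_de.assemble_regulons(degs, scored)
        regulons.to_json(out_dir / "regulons.json")
        record("regulons", t0, **{
            f"n_regulons_{t}": len(r) for t, r in regulons.by_tissue.items()
        })

    with open(out_dir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report


def _assert_monotone(counts: dict) -> None:
    cascade = [counts[k] for k in
               ("grnboost", "im_filter", "spearman_filter", "tfbs_filter")
               if k in counts]
    if any(a < b for a, b in zip(cascade, cascade[1:])):
        raise AssertionError(f"filter cascade counts increased: {cascade}")
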