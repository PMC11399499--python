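"""Synthetic regulatory worlds with known ground truth.

The generator builds, from one seed: (1) a ground-truth GRN whose TFs have
heavy-tailed out-degrees and whose edges are active in random non-empty
tissue subsets; (2) a negative-binomial count matrix in which tissue-active
TFs and their targets carry planted log2 fold changes; (3) a synthetic
genome whose target promoters contain planted consensus motif sites; and
(4) ChIP-seq-like peaks covering planted sites, with configurable false
negative and false positive rates.  Every downstream stage of the pipeline
can therefore be scored against a known answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    ChipPeakSet,
    ExpressionMatrix,
    GeneAnnotation,
    GenomicInterval,
    MotifModel,
    write_expression,
    write_motifs_meme,
    write_peaks,
)

__all__ = [
    "SimConfig",
    "GrnEdge",
    "GroundTruth",
    "generate_grn",
    "simulate_expression",
    "emit_genome_and_motifs",
    "emit_chip_peaks",
    "write_fixture",
    "strong_signal_config",
]

_MOTIF_LEN = 8
_GENE_BODY = 200
_MARGIN = 100
_GENES_PER_CHROM = 50
_PEAK_PAD = 30


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic world.

    Defaults give a desk-scale fixture with clearly detectable signal:
    moderate overdispersion (NB dispersion 0.1, typical of bulk RNA-seq),
    TF fold changes of 1.5–3 on the log2 scale, and mostly clean motif and
    ChIP evidence.
    """

    n_tfs: int = 40
    n_genes: int = 500
    n_tissues: int = 3
    samples_per_tissue: int = 20
    dispersion: float = 0.1
    promoter_len: int = 2000
    motif_plant_rate: float = 0.9
    peak_fpr: float = 0.05
    peak_fnr: float = 0.1
    tf_logfc_low: float = 1.5
    tf_logfc_high: float = 3.0
    edge_weight_low: float = 0.6
    edge_weight_high: float = 1.0
    base_mean_logmu: float = 4.0
    base_mean_logsigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tfs <= 0:
            raise ValueError("n_tfs must be positive")
        if not self.n_tfs < self.n_genes:
            raise ValueError("n_tfs must be < n_genes")
        for name in ("motif_plant_rate", "peak_fpr", "peak_fnr"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def child_rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage RNG so stages can be regenerated alone."""
        stages = ["grn", "expression", "genome", "peaks"]
        ss = np.random.SeedSequence(self.seed)
        return np.random.default_rng(ss.spawn(len(stages))[stages.index(stage)])

    @property
    def tissues(self) -> list[str]:
        return [f"tissue{i + 1}" for i in range(self.n_tissues)]


def strong_signal_config(seed: int = 0, **overrides) -> SimConfig:
    """The strong-signal fixture: planted logFC >= 2, plant_rate 0.9, fnr 0.1."""
    kw = dict(tf_logfc_low=2.0, tf_logfc_high=3.0, motif_plant_rate=0.9,
              peak_fnr=0.1, seed=seed)
    kw.update(overrides)
    return SimConfig(**kw)


@dataclass(frozen=True)
class GrnEdge:
    tf: str
    target: str
    weight: float
    active_tissues: frozenset[str]


@dataclass
class GroundTruth:
    """The generated regulatory world; filled in stage by stage."""

    gene_ids: list[str]
    tf_ids: list[str]
    edges: list[GrnEdge]
    planted_logfc: dict[tuple[str, str], float]
    motif_sites: list[tuple[str, GenomicInterval]] = field(default_factory=list)
    annotations: list[GeneAnnotation] = field(default_factory=list)
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    motifs: list[MotifModel] = field(default_factory=list)
    site_edges: list[tuple[str, str, GenomicInterval]] = field(default_factory=list)

    def __post_init__(self) -> None:
        genes = set(self.gene_ids)
        for e in self.edges:
            if e.tf == e.target:
                raise ValueError(f"self-edge {e.tf}")
            if e.tf not in genes or e.target not in genes:
                raise ValueError(f"edge endpoint outside gene set: {e}")
            if not e.active_tissues:
                raise ValueError(f"edge {e.tf}->{e.target} active nowhere")

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.tf, e.target) for e in self.edges}

    def active_edges(self, tissue: str) -> set[tuple[str, str]]:
        return {(e.tf, e.target) for e in self.edges if tissue in e.active_tissues}


def _powerlaw_degrees(rng: np.random.Generator, n: int, kmax: int) -> np.ndarray:
    """Discrete power law P(k) ∝ k^-2 on 1..kmax."""
    k = np.arange(1, kmax + 1)
    p = k.astype(float) ** -2.0
    p /= p.sum()
    return rng.choice(k, size=n, p=p)


def generate_grn(config: SimConfig) -> GroundTruth:
    """Draw the ground-truth GRN.

    Out-degrees follow a truncated discrete power law (exponent 2,
    truncated at n_genes/2), targets are drawn without replacement, and
    each edge is active in a uniformly random non-empty tissue subset.
    """
    rng = config.child_rng("grn")
    tf_ids = [f"TF{i + 1:04d}" for i in range(config.n_tfs)]
    n_other = config.n_genes - config.n_tfs
    gene_ids = tf_ids + [f"G{i + 1:04d}" for i in range(n_other)]
    tissues = config.tissues

    kmax = max(1, config.n_genes // 2)
    degrees = _powerlaw_degrees(rng, config.n_tfs, kmax)
    # one home tissue per regulon: a TF upregulated everywhere has no
    # one-vs-rest contrast anywhere and could never seed a tissue regulon
    home = rng.integers(0, len(tissues), size=config.n_tfs)
    edges: list[GrnEdge] = []
    planted_logfc: dict[tuple[str, str], float] = {}
    all_genes = np.array(gene_ids)
    tf_logfc: dict[tuple[str, str], float] = {}
    for ti, (tf, k) in enumerate(zip(tf_ids, degrees)):
        tis = tissues[home[ti]]
        candidates = all_genes[all_genes != tf]
        targets = rng.choice(candidates, size=min(k, len(candidates)), replace=False)
        for tg in targets:
            weight = rng.uniform(config.edge_weight_low, config.edge_weight_high)
            edges.append(GrnEdge(tf, str(tg), weight, frozenset({tis})))
        tf_logfc[(tf, tis)] = rng.uniform(config.tf_logfc_low, config.tf_logfc_high)

    # each active target inherits logFC = TF logFC × edge weight, summed
    # over regulating TFs when several hit the same target in one tissue
    planted_logfc.update(tf_logfc)
    for e in edges:
        for tis in e.active_tissues:
            contrib = tf_logfc[(e.tf, tis)] * e.weight
            key = (e.target, tis)
            planted_logfc[key] = planted_logfc.get(key, 0.0) + contrib

    return GroundTruth(gene_ids, tf_ids, edges, planted_logfc)


def simulate_expression(truth: GroundTruth, config: SimConfig) -> ExpressionMatrix:
    """Negative-binomial counts with planted tissue effects.

    Gene base means are log-normal; a gene's mean in tissue T is
    base × 2^logFC(gene, T); counts are NB with the configured dispersion
    (variance μ + φμ²).
    """
    rng = config.child_rng("expression")
    n_genes = len(truth.gene_ids)
    base = rng.lognormal(config.base_mean_logmu, config.base_mean_logsigma, n_genes)

    tissues = config.tissues
    sample_ids: list[str] = []
    tissue_labels: dict[str, str] = {}
    cols: list[np.ndarray] = []
    gene_idx = {g: i for i, g in enumerate(truth.gene_ids)}
    # per-tissue mean vector
    for tis in tissues:
        mu = base.copy()
        for (gene, t), lfc in truth.planted_logfc.items():
            if t == tis:
                mu[gene_idx[gene]] = base[gene_idx[gene]] * 2.0 ** lfc
        r = 1.0 / config.dispersion
        p = r / (r + mu)
        for s in range(config.samples_per_tissue):
            sid = f"{tis}_s{s + 1:02d}"
            sample_ids.append(sid)
            tissue_labels[sid] = tis
            cols.append(rng.negative_binomial(r, p))
    values = np.column_stack(cols).astype(float)
    return ExpressionMatrix(list(truth.gene_ids), sample_ids, values, tissue_labels)


def _random_informative_pwm(rng: np.random.Generator, length: int = _MOTIF_LEN) -> np.ndarray:
    """PWM with a 0.85-dominant base per column (~1.15 bits/col, IC >= 8)."""
    pfm = np.full((4, length), 0.05)
    dom = rng.integers(0, 4, size=length)
    pfm[dom, np.arange(length)] = 0.85
    return pfm


def emit_genome_and_motifs(
    truth: GroundTruth, config: SimConfig
) -> tuple[dict[str, str], list[MotifModel], list[GeneAnnotation]]:
    """Lay out a synthetic genome and plant consensus motif sites.

    Genes are placed in fixed non-overlapping slots (one chromosome per 50
    genes) so promoters never collide; background sequence is i.i.d.
    uniform; for each true edge the TF's motif consensus is written into
    the target promoter with probability ``motif_plant_rate``.
    Fills ``truth.motif_sites``, ``annotations``, ``chrom_lengths``,
    ``motifs`` and ``site_edges`` in place and returns them.
    """
    rng = config.child_rng("genome")
    slot = config.promoter_len + _GENE_BODY + 2 * _MARGIN
    if config.promoter_len < _MOTIF_LEN:
        raise ValueError("promoter shorter than motif: layout impossible")

    annotations: list[GeneAnnotation] = []
    chrom_of: dict[str, str] = {}
    promoter_start: dict[str, int] = {}
    chrom_lengths: dict[str, int] = {}
    tf_set = set(truth.tf_ids)
    for gi, gene in enumerate(truth.gene_ids):
        chrom = f"chr{gi // _GENES_PER_CHROM + 1}"
        s = (gi % _GENES_PER_CHROM) * slot
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            # promoter [s+margin, s+margin+P), TSS base right after it
            p0 = s + _MARGIN
            tss0 = p0 + config.promoter_len
        else:
            # gene body first, promoter [tss0, tss0+P) to the right
            tss0 = s + _MARGIN + _GENE_BODY - 1
            p0 = tss0
        promoter_start[gene] = p0
        chrom_of[gene] = chrom
        annotations.append(
            GeneAnnotation(gene, chrom, strand, tss0 + 1, is_tf=gene in tf_set,
                           family=f"FAM{(truth.tf_ids.index(gene) % 8) + 1}"
                           if gene in tf_set else "")
        )
        chrom_lengths[chrom] = max(chrom_lengths.get(chrom, 0), s + slot)

    seqs = {
        c: rng.integers(0, 4, size=n).astype(np.int8)
        for c, n in chrom_lengths.items()
    }

    motifs = [
        MotifModel(f"M_{tf}", _random_informative_pwm(rng), tf_ids=[tf])
        for tf in truth.tf_ids
    ]
    motif_by_tf = {m.tf_ids[0]: m for m in motifs}
    base_idx = {b: i for i, b in enumerate("ACGT")}

    truth.motif_sites = []
    truth.site_edges = []
    occupied: dict[str, list[tuple[int, int]]] = {g: [] for g in truth.gene_ids}
    for e in truth.edges:
        if rng.random() >= config.motif_plant_rate:
            continue
        motif = motif_by_tf[e.tf]
        cons = motif.consensus()
        L = len(cons)
        p0 = promoter_start[e.target]
        placed = None
        for _ in range(100):
            off = int(rng.integers(0, config.promoter_len - L + 1))
            if all(off + L <= a or off >= b for a, b in occupied[e.target]):
                placed = off
                break
        if placed is None:
            continue  # promoter saturated; site skipped
        occupied[e.target].append((placed, placed + L))
        chrom = chrom_of[e.target]
        for j, b in enumerate(cons):
            seqs[chrom][p0 + placed + j] = base_idx[b]
        iv = GenomicInterval(chrom, p0 + placed, p0 + placed + L, "+")
        truth.motif_sites.append((motif.motif_id, iv))
        truth.site_edges.append((e.tf, e.target, iv))

    lut = np.array(list("ACGT"))
    genome = {c: "".join(lut[v]) for c, v in seqs.items()}
    truth.annotations = annotations
    truth.chrom_lengths = chrom_lengths
    truth.motifs = motifs
    return genome, motifs, annotations


def emit_chip_peaks(truth: GroundTruth, config: SimConfig) -> list[ChipPeakSet]:
    """Noisy ChIP peaks: planted sites kept with prob 1−fnr, plus false
    peaks at rate ``peak_fpr`` per (profiled TF, promoter)."""
    if not truth.annotations:
        raise ValueError("genome not laid out; call emit_genome_and_motifs first")
    rng = config.child_rng("peaks")
    peaks_by_tf: dict[str, list[GenomicInterval]] = {
        e.tf: [] for e in truth.edges
    }
    for tf, _tg, iv in truth.site_edges:
        if rng.random() < config.peak_fnr:
            continue
        peaks_by_tf[tf].append(
            GenomicInterval(iv.chrom, max(0, iv.start - _PEAK_PAD), iv.end + _PEAK_PAD)
        )
    if config.peak_fpr > 0:
        promoters = _promoter_intervals(truth, config)
        for tf in peaks_by_tf:
            hit = rng.random(len(promoters)) < config.peak_fpr
            for iv in np.array(promoters, dtype=object)[hit]:
                off = int(rng.integers(0, max(1, len(iv) - 2 * _PEAK_PAD)))
                peaks_by_tf[tf].append(
                    GenomicInterval(iv.chrom, iv.start + off,
                                    min(iv.end, iv.start + off + 2 * _PEAK_PAD))
                )
    return [ChipPeakSet(tf, pk) for tf, pk in sorted(peaks_by_tf.items())]


def _promoter_intervals(truth: GroundTruth, config: SimConfig) -> list[GenomicInterval]:
    out = []
    for a in truth.annotations:
        tss0 = a.tss - 1
        if a.strand == "+":
            start, end = max(0, tss0 - config.promoter_len), tss0
        else:
            start = tss0
            end = min(truth.chrom_lengths[a.chrom], tss0 + config.promoter_len)
        out.append(GenomicInterval(a.chrom, start, end, a.strand))
    return out


def write_fixture(config: SimConfig, outdir: str | Path) -> GroundTruth:
    """Generate the full world and write the fixture bundle.

    Layout: genome.fa, genes.gff3, tfs.tsv, motifs.meme, motif_map.tsv,
    peaks/<tf>.bed, counts.tsv, tissues.tsv, truth.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = generate_grn(config)
    expr = simulate_expression(truth, config)
    genome, motifs, annotations = emit_genome_and_motifs(truth, config)
    peak_sets = emit_chip_peaks(truth, config)

    with open(outdir / "genome.fa", "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(outdir / "genes.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for a in annotations:
            if a.strand == "+":
                start, end = a.tss, a.tss + _GENE_BODY - 1
            else:
                start, end = max(1, a.tss - _GENE_BODY + 1), a.tss
            fh.write(
                f"{a.chrom}\tsynthetic\tgene\t{start}\t{end}\t.\t{a.strand}\t.\t"
                f"ID={a.gene_id}\n"
            )
    with open(outdir / "tfs.tsv", "w") as fh:
        fh.write("gene_id\tfamily\n")
        for a in annotations:
            if a.is_tf:
                fh.write(f"{a.gene_id}\t{a.family}\n")
    write_motifs_meme(motifs, outdir / "motifs.meme")
    with open(outdir / "motif_map.tsv", "w") as fh:
        fh.write("motif_id\ttf_id\n")
        for m in motifs:
            for tf in m.tf_ids:
                fh.write(f"{m.motif_id}\t{tf}\n")
    peak_dir = outdir / "peaks"
    peak_dir.mkdir(exist_ok=True)
    for ps in peak_sets:
        write_peaks(ps, peak_dir / f"{ps.tf_id}.bed")
    write_expression(expr, outdir / "counts.tsv", outdir / "tissues.tsv")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(
            {
                "gene_ids": truth.gene_ids,
                "tf_ids": truth.tf_ids,
                "edges": [
                    {
                        "tf": e.tf,
                        "target": e.target,
                        "weight": e.weight,
                        "active_tissues": sorted(e.active_tissues),
                    }
                    for e in truth.edges
                ],
                "planted_logfc": [
                    {"gene": g, "tissue": t, "logfc": v}
                    for (g, t), v in sorted(truth.planted_logfc.items())
                ],
                "n_motif_sites": len(truth.motif_sites),
            },
            fh,
            indent=1,
        )
    return truth
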