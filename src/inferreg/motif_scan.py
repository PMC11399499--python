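"""Promoter motif scanning with exact PWM p-values and cluster scoring.

Two scanners decide motif support for an edge, and both must agree:

* a site-level scanner that scores every promoter position with the
  log-odds of the PWM against the background and converts scores to exact
  p-values via dynamic-programming convolution of the discretized
  per-position score distribution (the survival function of the score of a
  random background word);
* a cluster-level scanner that keeps sites above a per-motif score floor
  and slides a window over the promoter, confirming the (motif, gene) pair
  when the best window's summed score clears a cluster floor.

Motifs are shared across TFs of the same family before the edge filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .io_formats import GeneAnnotation, GenomicInterval, MotifModel

__all__ = [
    "PromoterSet",
    "ScanHit",
    "PwmPvalueTable",
    "promoter_regions",
    "pwm_pvalue_table",
    "scan_sites",
    "scan_clusters",
    "share_family_motifs",
    "tfbs_filter",
    "extract_promoter_seq",
]

log = logging.getLogger(__name__)

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class ScanHit:
    motif_id: str
    gene_id: str
    offset: int  # within promoter, 0-based, match start
    strand: str  # strand of the match relative to the promoter sequence
    logodds_score: float
    pvalue: float

    def __post_init__(self) -> None:
        if not 0.0 < self.pvalue <= 1.0:
            raise ValueError(f"pvalue {self.pvalue} outside (0, 1]")
        if self.offset < 0:
            raise ValueError("negative offset")


PromoterSet = dict[str, GenomicInterval]


def promoter_regions(
    annotations: Iterable[GeneAnnotation],
    genome_lengths: Mapping[str, int],
    upstream_bp: int = 2000,
) -> PromoterSet:
    """Strand-aware upstream promoter windows, clipped at chromosome bounds.

    With tss0 = tss − 1 (0-based TSS base): + strand promoters are
    [tss0 − upstream_bp, tss0), − strand promoters are [tss0, tss0 +
    upstream_bp); the − strand window is reverse-complemented at scan time.
    Genes whose clipped window is empty are skipped with a log entry.
    """
    out: PromoterSet = {}
    for a in annotations:
        if a.chrom not in genome_lengths:
            raise ValueError(f"unknown chromosome {a.chrom!r} for gene {a.gene_id}")
        clen = genome_lengths[a.chrom]
        tss0 = a.tss - 1
        if tss0 >= clen:
            raise ValueError(f"tss of {a.gene_id} outside chromosome")
        if a.strand == "+":
            start, end = max(0, tss0 - upstream_bp), tss0
        else:
            start, end = tss0, min(clen, tss0 + upstream_bp)
        if start >= end:
            log.info("gene %s has empty promoter after clipping", a.gene_id)
            continue
        out[a.gene_id] = GenomicInterval(a.chrom, start, end, a.strand)
    return out


class PwmPvalueTable:
    """Exact score → p-value map for one PWM under its background.

    Scores are log2-odds in bits, discretized at ``granularity``; the
    distribution of the score of a random background word is built by
    convolving per-position score distributions.  ``pvalue(s)`` is
    conservative (rounded upward): it evaluates the survival function at
    floor(s / granularity).
    """

    def __init__(self, motif: MotifModel, granularity: float = 1e-3) -> None:
        if np.any(motif.background <= 0):
            raise ValueError(f"motif {motif.motif_id}: degenerate background")
        self.granularity = float(granularity)
        p = np.clip(motif.pfm, 1e-12, 1.0)
        self.score_matrix = np.log2(p / motif.background[:, None])  # 4 × L
        kk = np.rint(self.score_matrix / granularity).astype(np.int64)
        # allocate over every reachable partial sum, not just the final range
        pref_lo = np.concatenate([[0], np.cumsum(kk.min(axis=0))])
        pref_hi = np.concatenate([[0], np.cumsum(kk.max(axis=0))])
        lo, hi = int(pref_lo.min()), int(pref_hi.max())
        probs = np.zeros(hi - lo + 1)
        probs[-lo] = 1.0  # score 0 with probability 1 before any position
        bg = motif.background
        for j in range(kk.shape[1]):
            new = np.zeros_like(probs)
            for b in range(4):
                shift = kk[b, j]
                if shift >= 0:
                    new[shift:] += bg[b] * probs[: len(probs) - shift if shift else None]
                else:
                    new[:shift] += bg[b] * probs[-shift:]
            probs = new
        self._lo = lo
        # survival function: sf[i] = P(K >= lo + i)
        self._sf = np.minimum(1.0, probs[::-1].cumsum()[::-1])

    def _index(self, score: float) -> int:
        k = int(np.floor(score / self.granularity))
        return int(np.clip(k - self._lo, 0, len(self._sf) - 1))

    def pvalue(self, score: float) -> float:
        k = int(np.floor(score / self.granularity))
        if k < self._lo:
            return 1.0
        if k - self._lo >= len(self._sf):
            return float(self._sf[-1])
        return float(max(self._sf[k - self._lo], np.finfo(float).tiny))

    def score_threshold(self, p_max: float) -> float:
        """Smallest score whose (conservative) p-value is <= p_max."""
        idx = np.searchsorted(-self._sf, -p_max, side="left")
        if idx >= len(self._sf):
            return np.inf
        return (self._lo + idx) * self.granularity


def pwm_pvalue_table(motif: MotifModel, granularity: float = 1e-3) -> PwmPvalueTable:
    return PwmPvalueTable(motif, granularity)


_BASE_IDX = {b: i for i, b in enumerate("ACGTN")}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_BASE_IDX.get(c, 4) for c in seq.upper()), dtype=np.int8,
                       count=len(seq))


def extract_promoter_seq(
    genome: Mapping[str, str], promoter: GenomicInterval
) -> str:
    """Promoter sequence in reading orientation (− strand windows RC'd)."""
    chrom_seq = genome[promoter.chrom]
    if promoter.end > len(str(chrom_seq)):
        raise ValueError(f"promoter {promoter} outside FASTA sequence")
    seq = str(chrom_seq[promoter.start : promoter.end])
    return revcomp(seq) if promoter.strand == "-" else seq


def _slide_scores(enc: np.ndarray, smat5: np.ndarray) -> np.ndarray:
    """Log-odds score at every start offset; N contributes 0."""
    L = smat5.shape[1]
    n = len(enc) - L + 1
    if n <= 0:
        return np.empty(0)
    out = np.zeros(n)
    for j in range(L):
        out += smat5[enc[j : j + n], j]
    return out


def scan_sites(
    promoters: PromoterSet,
    genome: Mapping[str, str],
    motifs: Iterable[MotifModel],
    p_max: float = 1e-4,
    granularity: float = 1e-3,
    tables: Mapping[str, PwmPvalueTable] | None = None,
) -> list[ScanHit]:
    """Scan both strands of every promoter; emit hits with p <= p_max."""
    motifs = list(motifs)
    if tables is None:
        tables = {m.motif_id: pwm_pvalue_table(m, granularity) for m in motifs}
    seqs = {g: _encode(extract_promoter_seq(genome, iv)) for g, iv in promoters.items()}
    hits: list[ScanHit] = []
    for m in motifs:
        table = tables[m.motif_id]
        thr = table.score_threshold(p_max)
        smat = np.vstack([table.score_matrix, np.zeros((1, m.length))])  # N row
        # reverse-complement scoring matrix scans the opposite strand
        smat_rc = np.vstack([table.score_matrix[::-1, ::-1], np.zeros((1, m.length))])
        for gene, enc in seqs.items():
            for strand, sm in (("+", smat), ("-", smat_rc)):
                scores = _slide_scores(enc, sm)
                for off in np.nonzero(scores >= thr)[0]:
                    hits.append(
                        ScanHit(
                            m.motif_id,
                            gene,
                            int(off),
                            strand,
                            float(scores[off]),
                            table.pvalue(float(scores[off])),
                        )
                    )
    return hits


def scan_clusters(
    hits: Iterable[ScanHit],
    window_bp: int = 200,
    cluster_min: float = 5.0,
    motif_min: float = 6.0,
) -> set[tuple[str, str]]:
    """Window-sum cluster confirmation.

    Hits below ``motif_min`` are discarded; a sliding window of
    ``window_bp`` sums the surviving hit scores, and (motif, gene) is
    confirmed when the best window reaches ``cluster_min``.
    """
    by_pair: dict[tuple[str, str], list[tuple[int, float]]] = {}
    for h in hits:
        if h.logodds_score >= motif_min:
            by_pair.setdefault((h.motif_id, h.gene_id), []).append(
                (h.offset, h.logodds_score)
            )
    confirmed: set[tuple[str, str]] = set()
    for pair, sites in by_pair.items():
        sites.sort()
        offs = np.array([o for o, _ in sites])
        scs = np.array([s for _, s in sites])
        left = 0
        running = 0.0
        best = 0.0
        for right in range(len(sites)):
            running += scs[right]
            while offs[right] - offs[left] >= window_bp:
                running -= scs[left]
                left += 1
            best = max(best, running)
        if best >= cluster_min:
            confirmed.add(pair)
    return confirmed


def share_family_motifs(
    motifs: Iterable[MotifModel], annotations: Iterable[GeneAnnotation]
) -> dict[str, set[str]]:
    """Expand motif→TF mapping to the union of TFs in each mapped family."""
    family_of = {a.gene_id: a.family for a in annotations if a.is_tf}
    members: dict[str, set[str]] = {}
    for tf, fam in family_of.items():
        if fam:
            members.setdefault(fam, set()).add(tf)
    out: dict[str, set[str]] = {}
    for m in motifs:
        tfs = set(m.tf_ids)
        for tf in m.tf_ids:
            fam = family_of.get(tf, "")
            if not fam:
                log.info("TF %s has no family; mapping for motif %s unchanged",
                         tf, m.motif_id)
                continue
            tfs |= members.get(fam, set())
        out[m.motif_id] = tfs
    return out


def tfbs_filter(
    edges,
    site_confirmed: set[tuple[str, str]],
    cluster_confirmed: set[tuple[str, str]],
    motif_tf_map: Mapping[str, set[str]],
    match_level: str = "motif",
):
    """Keep edges whose (TF, target) is confirmed by BOTH scanners.

    ``match_level='motif'`` demands the same motif from both scanners;
    ``'tf'`` accepts any motif of the TF from each scanner.  Edges losing
    motif support are dropped; TFs with no motif at all lose all edges.
    """
    import pandas as pd  # local import keeps module import light

    tf_motifs: dict[str, set[str]] = {}
    for motif_id, tfs in motif_tf_map.items():
        for tf in tfs:
            tf_motifs.setdefault(tf, set()).add(motif_id)

    def supported(tf: str, tg: str) -> bool:
        mids = tf_motifs.get(tf)
        if not mids:
            return False
        if match_level == "motif":
            return any(
                (m, tg) in site_confirmed and (m, tg) in cluster_confirmed
                for m in mids
            )
        site = any((m, tg) in site_confirmed for m in mids)
        clus = any((m, tg) in cluster_confirmed for m in mids)
        return site and clus

    if edges.empty:
        return edges
    no_motif_tfs = sorted(set(edges["tf"]) - set(tf_motifs))
    if no_motif_tfs:
        log.info("%d TFs have no motif after sharing; their edges drop",
                 len(no_motif_tfs))
    mask = np.array(
        [supported(tf, tg) for tf, tg in zip(edges["tf"], edges["target"])]
    )
    out = edges[mask].reset_index(drop=True).copy()
    out["motif_support"] = True
    return pd.DataFrame(out)
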