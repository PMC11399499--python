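"""Edge labelling from ChIP-seq peak / promoter overlap.

An edge is a training positive when any peak of its TF overlaps the
target's promoter by at least ``min_overlap_bp`` (half-open intervals, so
adjacent regions do not overlap).  Edges of TFs with no peak file stay
unlabelled: they remain candidates for prediction but are never training
positives.  Negatives for training come from sampled non-edges, not from
ChIP absence.
"""

from __future__ import annotations

import logging
from typing import Iterable

import pandas as pd

from .io_formats import ChipPeakSet
from .motif_scan import PromoterSet

__all__ = ["label_edges"]

log = logging.getLogger(__name__)


def label_edges(
    edges: pd.DataFrame,
    promoters: PromoterSet,
    peaks: Iterable[ChipPeakSet],
    min_overlap_bp: int = 1,
    drop_unsupported: bool = False,
) -> pd.DataFrame:
    """Set chip_label = 'positive' where a TF peak overlaps the target promoter.

    ``drop_unsupported`` additionally removes edges of profiled TFs whose
    promoter shows no peak (reproducing hard-filter shrinkage); by default
    those edges are merely left unlabelled.
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    peaks_by_tf = {ps.tf_id: ps for ps in peaks}
    known_chroms = {iv.chrom for iv in promoters.values()}
    for ps in peaks_by_tf.values():
        stray = {p.chrom for p in ps.peaks} - known_chroms
        if stray:
            log.warning(
                "peaks of %s on chromosomes absent from annotation ignored: %s",
                ps.tf_id, sorted(stray)[:3],
            )

    labels: list[object] = []
    for tf, tg in zip(edges["tf"], edges["target"]):
        ps = peaks_by_tf.get(tf)
        prom = promoters.get(tg)
        if ps is None or prom is None:
            labels.append(None)  # unprofiled TF (or promoterless gene)
            continue
        hit = any(prom.overlap(p) >= min_overlap_bp for p in ps.peaks)
        labels.append("positive" if hit else "unlabelled")
    out = edges.copy()
    out["chip_label"] = labels
    if drop_unsupported:
        out = out[out["chip_label"] != "unlabelled"].reset_index(drop=True)
    return out
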