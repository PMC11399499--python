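"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions
----------------------
Internally every interval is 0-based half-open (``[start, end)``), the BED
convention.  GFF3 features (1-based inclusive) are converted on read.  A
gene's transcription start site (TSS) is stored 1-based, as annotated; the
0-based position of the TSS base is therefore ``tss - 1``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneAnnotation",
    "GenomicInterval",
    "ExpressionMatrix",
    "MotifModel",
    "ChipPeakSet",
    "EDGE_COLUMNS",
    "read_expression",
    "write_expression",
    "read_annotation",
    "read_motifs",
    "write_motifs_meme",
    "read_peaks",
    "write_peaks",
    "read_edges",
    "write_edges",
    "read_tf_table",
]

PFM_PSEUDOCOUNT = 0.01
BASES = "ACGT"


class FormatError(ValueError):
    """A malformed record in an input file."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise FormatError(f"negative coordinate: {self}")
        if not self.start < self.end:
            raise FormatError(f"empty or inverted interval: {self}")
        if self.strand not in {"+", "-", "."}:
            raise FormatError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with its TSS (1-based), strand, and optional TF family."""

    gene_id: str
    chrom: str
    strand: str
    tss: int
    is_tf: bool = False
    family: str = ""

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise FormatError(f"tss must be >= 1 for {self.gene_id}")
        if self.strand not in {"+", "-"}:
            raise FormatError(f"strand must be + or - for {self.gene_id}")


@dataclass
class ExpressionMatrix:
    """genes × samples raw counts with per-sample tissue labels."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    tissue_labels: dict[str, str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes × {len(self.sample_ids)} samples"
            )
        if np.any(self.values < 0):
            raise FormatError("negative expression value")
        missing = [s for s in self.sample_ids if s not in self.tissue_labels]
        if missing:
            raise FormatError(f"samples without tissue label: {missing[:5]}")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def tissues(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.sample_ids:
            seen.setdefault(self.tissue_labels[s], None)
        return list(seen)

    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.gene_ids)}

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class MotifModel:
    """Position frequency matrix (A,C,G,T rows) with motif→TF mapping."""

    motif_id: str
    pfm: np.ndarray
    tf_ids: list[str] = field(default_factory=list)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.pfm = np.asarray(self.pfm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pfm.ndim != 2 or self.pfm.shape[0] != 4:
            raise FormatError(f"motif {self.motif_id}: pfm must be 4 × L")
        colsums = self.pfm.sum(axis=0)
        if np.any(np.abs(colsums - 1.0) > 1e-6):
            raise FormatError(f"motif {self.motif_id}: pfm columns must sum to 1")
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise FormatError(f"motif {self.motif_id}: background must sum to 1")

    @property
    def length(self) -> int:
        return self.pfm.shape[1]

    @property
    def is_mapped(self) -> bool:
        return bool(self.tf_ids)

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pfm.argmax(axis=0))

    def information_content(self) -> float:
        """Total IC in bits relative to the background distribution."""
        p = np.clip(self.pfm, 1e-12, 1.0)
        return float(np.sum(p * np.log2(p / self.background[:, None])))


@dataclass
class ChipPeakSet:
    """ChIP-seq peaks for one TF, sorted by (chrom, start)."""

    tf_id: str
    peaks: list[GenomicInterval]

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end))

    def __len__(self) -> int:
        return len(self.peaks)


# ---------------------------------------------------------------------------
# expression


def read_expression(path: str | Path, tissue_path: str | Path) -> ExpressionMatrix:
    """Read a genes × samples count TSV plus a sample→tissue TSV.

    The count file has gene ids in the first column and sample ids in the
    header.  Malformed numeric cells and duplicate gene ids are errors.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        sample_ids = header[1:]
        gene_ids: list[str] = []
        rows: list[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(sample_ids) + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {len(sample_ids) + 1} columns, "
                    f"got {len(fields)}"
                )
            gene_ids.append(fields[0])
            try:
                rows.append(np.array([float(x) for x in fields[1:]]))
            except ValueError:
                bad = next(
                    i for i, x in enumerate(fields[1:]) if not _is_number(x)
                )
                raise FormatError(
                    f"{path}:{lineno}: malformed numeric cell "
                    f"{fields[1 + bad]!r} in column {sample_ids[bad]!r} "
                    f"(gene {fields[0]!r})"
                ) from None
    if len(set(gene_ids)) != len(gene_ids):
        dup = pd.Series(gene_ids)
        raise FormatError(
            f"{path}: duplicate gene ids: {sorted(dup[dup.duplicated()])[:5]}"
        )
    tissues = _read_tissue_labels(tissue_path)
    values = np.vstack(rows) if rows else np.empty((0, len(sample_ids)))
    return ExpressionMatrix(gene_ids, sample_ids, values, tissues)


def _is_number(x: str) -> bool:
    try:
        float(x)
        return True
    except ValueError:
        return False


def _read_tissue_labels(path: str | Path) -> dict[str, str]:
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[0] == "sample_id":  # optional header
                continue
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected sample<TAB>tissue")
            labels[fields[0]] = fields[1]
    return labels


def write_expression(
    expr: ExpressionMatrix, path: str | Path, tissue_path: str | Path
) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")
    with open(tissue_path, "w") as fh:
        fh.write("sample_id\ttissue\n")
        for s in expr.sample_ids:
            fh.write(f"{s}\t{expr.tissue_labels[s]}\n")


# ---------------------------------------------------------------------------
# annotation


def read_annotation(
    path: str | Path,
    tf_families: Mapping[str, str] | None = None,
) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 or BED (decided by extension).

    TSS is the feature start for + strand genes and the feature end for −
    strand genes, reported 1-based.  ``tf_families`` marks the listed genes
    as TFs and attaches their family.
    """
    path = Path(path)
    if path.suffix.lower() in {".bed", ".bed3", ".bed6"}:
        genes = _read_annotation_bed(path)
    else:
        genes = _read_annotation_gff3(path)
    if tf_families:
        genes = [
            GeneAnnotation(
                g.gene_id,
                g.chrom,
                g.strand,
                g.tss,
                is_tf=g.gene_id in tf_families,
                family=tf_families.get(g.gene_id, ""),
            )
            for g in genes
        ]
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate gene ids")
    return genes


def _read_annotation_gff3(path: Path) -> list[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if f[2] != "gene":
                continue
            chrom, start, end, strand = f[0], int(f[3]), int(f[4]), f[6]
            if end < start:
                raise FormatError(f"{path}:{lineno}: end < start")
            if strand not in {"+", "-"}:
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            m = re.search(r"ID=([^;]+)", f[8])
            if not m:
                raise FormatError(f"{path}:{lineno}: gene without ID attribute")
            tss = start if strand == "+" else end
            genes.append(GeneAnnotation(m.group(1), chrom, strand, tss))
    return genes


def _read_annotation_bed(path: Path) -> list[GeneAnnotation]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 required for strand")
            chrom, start, end, name, strand = f[0], int(f[1]), int(f[2]), f[3], f[5]
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative coordinate")
            if end < start:
                raise FormatError(f"{path}:{lineno}: end < start")
            if strand not in {"+", "-"}:
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            # BED is 0-based half-open; 1-based TSS is start+1 (+) or end (−)
            tss = start + 1 if strand == "+" else end
            genes.append(GeneAnnotation(name, chrom, strand, tss))
    return genes


def read_tf_table(path: str | Path) -> dict[str, str]:
    """Read a TF list TSV with columns gene_id, family → {gene_id: family}."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns:
        raise FormatError(f"{path}: missing required column 'gene_id'")
    fam = df["family"] if "family" in df.columns else pd.Series("", index=df.index)
    return dict(zip(df["gene_id"], fam.fillna("")))


# ---------------------------------------------------------------------------
# motifs


def read_motifs(
    path: str | Path, tf_map: str | Path | Mapping[str, Sequence[str]] | None = None
) -> list[MotifModel]:
    """Read motifs from JASPAR PFM or MEME minimal format.

    Count matrices get a 0.01 per-cell pseudocount before normalization;
    matrices whose columns already sum to ~1 are taken as probabilities.
    Motifs without a TF mapping are retained with an empty ``tf_ids``.
    """
    path = Path(path)
    text = path.read_text()
    if "MEME version" in text or text.lstrip().startswith("MEME"):
        parsed = _parse_meme(text, path)
    else:
        parsed = _parse_jaspar(text, path)
    mapping: dict[str, list[str]] = {}
    if tf_map is not None:
        if isinstance(tf_map, (str, Path)):
            df = pd.read_csv(tf_map, sep="\t", dtype=str)
            if not {"motif_id", "tf_id"} <= set(df.columns):
                raise FormatError(f"{tf_map}: need columns motif_id, tf_id")
            for m, t in zip(df["motif_id"], df["tf_id"]):
                mapping.setdefault(m, []).append(t)
        else:
            mapping = {k: list(v) for k, v in tf_map.items()}
    return [
        MotifModel(mid, pfm, tf_ids=mapping.get(mid, []), background=bg)
        for mid, pfm, bg in parsed
    ]


def _normalize_matrix(mat: np.ndarray, where: str) -> np.ndarray:
    mat = np.asarray(mat, dtype=float)
    if mat.shape[0] != 4:
        raise FormatError(f"{where}: matrix must have 4 rows (A,C,G,T)")
    colsums = mat.sum(axis=0)
    if np.any(colsums == 0):
        raise FormatError(f"{where}: column of all zeros")
    if np.allclose(colsums, 1.0, atol=0.01):
        return mat / colsums  # already probabilities
    mat = mat + PFM_PSEUDOCOUNT
    return mat / mat.sum(axis=0)


def _parse_jaspar(text: str, path: Path):
    out = []
    motif_id = None
    rows: list[list[float]] = []
    for line in text.splitlines() + [">"]:
        line = line.strip()
        if line.startswith(">"):
            if motif_id is not None:
                if len(rows) != 4:
                    raise FormatError(f"{path}: motif {motif_id}: need 4 base rows")
                out.append(
                    (motif_id, _normalize_matrix(np.array(rows), motif_id), np.full(4, 0.25))
                )
            motif_id = line[1:].split()[0] if len(line) > 1 else None
            rows = []
        elif line:
            nums = re.findall(r"[-+]?\d*\.?\d+(?:[eE][-+]?\d+)?", line.split("[")[-1])
            rows.append([float(x) for x in nums])
    return out


def _parse_meme(text: str, path: Path):
    lines = text.splitlines()
    background = np.full(4, 0.25)
    out = []
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            freq_line = lines[i + 1].strip()
            toks = freq_line.split()
            bg = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            background = np.array([bg[b] for b in BASES])
            i += 2
            continue
        if line.startswith("MOTIF"):
            motif_id = line.split()[1]
            j = i + 1
            while j < len(lines) and "letter-probability matrix" not in lines[j]:
                j += 1
            if j == len(lines):
                raise FormatError(f"{path}: motif {motif_id}: missing matrix")
            m = re.search(r"w=\s*(\d+)", lines[j])
            width = int(m.group(1)) if m else None
            cols = []
            j += 1
            while j < len(lines):
                row = lines[j].strip()
                if not row or row.startswith(("MOTIF", "URL")):
                    break
                vals = [float(x) for x in row.split()]
                if len(vals) != 4:
                    raise FormatError(f"{path}: motif {motif_id}: non-4-column row")
                cols.append(vals)
                j += 1
            if width is not None and len(cols) != width:
                raise FormatError(f"{path}: motif {motif_id}: w={width} but {len(cols)} rows")
            pfm = _normalize_matrix(np.array(cols).T, motif_id)
            out.append((motif_id, pfm, background))
            i = j
            continue
        i += 1
    return out


def write_motifs_meme(motifs: Iterable[MotifModel], path: str | Path) -> None:
    """Write motifs in MEME minimal format (probabilities, shared background)."""
    motifs = list(motifs)
    bg = motifs[0].background if motifs else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {p:.5f}" for b, p in zip(BASES, bg)) + "\n\n")
        for m in motifs:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.length} nsites= 20 E= 0\n"
            )
            for col in m.pfm.T:
                fh.write(" ".join(f"{x:.6f}" for x in col) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# ChIP peaks


def read_peaks(path: str | Path, tf_id: str) -> ChipPeakSet:
    """Read a BED3+ peak file for one TF; peaks are sorted, never merged."""
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: BED needs >= 3 columns")
            start, end = int(f[1]), int(f[2])
            if start < 0:
                raise FormatError(f"{path}:{lineno}: negative coordinate")
            peaks.append(GenomicInterval(f[0], start, end))
    return ChipPeakSet(tf_id, peaks)


def write_peaks(peaks: ChipPeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peaks.peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")


# ---------------------------------------------------------------------------
# edge tables

EDGE_COLUMNS = [
    "tf",
    "target",
    "importance",
    "spearman_rho",
    "motif_support",
    "chip_label",
    "gcn_score",
    "predicted",
]
_BOOL_COLS = ("motif_support", "predicted")
_FLOAT_COLS = ("importance", "spearman_rho", "gcn_score")


def empty_edge_table() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in EDGE_COLUMNS})
    return df


def write_edges(edges: pd.DataFrame, path: str | Path) -> None:
    """Write an edge table TSV with the canonical column set."""
    unknown = set(edges.columns) - set(EDGE_COLUMNS)
    if unknown:
        raise FormatError(f"unknown edge columns: {sorted(unknown)}")
    out = edges.reindex(columns=EDGE_COLUMNS)
    with open(path, "w") as fh:
        fh.write("\t".join(EDGE_COLUMNS) + "\n")
        for row in out.itertuples(index=False):
            cells = []
            for col, val in zip(EDGE_COLUMNS, row):
                if val is None or (isinstance(val, float) and np.isnan(val)):
                    cells.append("NA")
                elif col in _FLOAT_COLS:
                    cells.append(f"{float(val):.10g}")
                elif col in _BOOL_COLS:
                    cells.append("True" if val else "False")
                else:
                    cells.append(str(val))
            fh.write("\t".join(cells) + "\n")


def read_edges(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    missing = {"tf", "target"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    unknown = set(df.columns) - set(EDGE_COLUMNS)
    if unknown:
        raise FormatError(f"{path}: unknown column(s) {sorted(unknown)}")
    for col in _FLOAT_COLS:
        if col in df.columns:
            df[col] = df[col].astype(float)
    for col in _BOOL_COLS:
        if col in df.columns:
            df[col] = df[col].map({"True": True, "False": False, None: None})
    if "chip_label" in df.columns:
        df["chip_label"] = df["chip_label"].where(df["chip_label"].notna(), None)
    return df.reindex(columns=EDGE_COLUMNS)
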