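"""Feature assignment and counting of retained alignments.

Reads are assigned to annotated features by strand-aware interval
intersection (any overlap >= 1 bp); among multiple overlapping features
the largest overlap wins, with ties broken by lowest feature start then
feature id. Unassigned reads are labeled "other". The per-feature count
matrix and the per-class library composition summary are the inputs of
the downstream differential test.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pysam
from intervaltree import IntervalTree

OTHER = "other"
CLASSES = ["miRNA", "tRNA", "rRNA", OTHER]


@dataclass
class AlignedInterval:
    read_id: str
    contig: str
    start: int  # 0-based
    end: int  # half-open
    strand: str


@dataclass
class CountMatrix:
    """features x libraries integer counts plus per-library totals of
    retained mapped reads (lib_sizes >= column sums; unassigned allowed)."""

    counts: pd.DataFrame
    lib_sizes: pd.Series
    conditions: dict[str, str] | None = None


def read_retained_alignments(
    sam_path, mapq_threshold: int = 10
) -> list[AlignedInterval]:
    """Primary mapped records with MAPQ >= threshold from a SAM file."""
    out = []
    with pysam.AlignmentFile(str(sam_path), "r") as fh:
        for rec in fh:
            if rec.is_unmapped or rec.mapping_quality < mapq_threshold:
                continue
            out.append(
                AlignedInterval(
                    rec.query_name,
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                )
            )
    return out


def _validate_annotation(
    annotation: pd.DataFrame, contig_lengths: dict[str, int] | None
) -> None:
    if annotation["feature_id"].duplicated().any():
        raise ValueError("duplicate feature_ids in annotation")
    if (annotation["start"] < 0).any() or (
        annotation["end"] <= annotation["start"]
    ).any():
        raise ValueError("malformed annotation intervals")
    if contig_lengths is not None:
        for row in annotation.itertuples(index=False):
            if row.contig not in contig_lengths or row.end > contig_lengths[row.contig]:
                raise ValueError(
                    f"annotation interval {row.feature_id} outside genome bounds"
                )


def intersect_features(
    alignments: list[AlignedInterval],
    annotation: pd.DataFrame,
    contig_lengths: dict[str, int] | None = None,
    stranded: bool = True,
) -> pd.DataFrame:
    """Per-read feature assignment.

    Returns a DataFrame (read_id, feature_id, klass); reads overlapping no
    feature (or only antisense features, when ``stranded``) get
    feature_id = klass = "other".
    """
    _validate_annotation(annotation, contig_lengths)
    trees: dict[str, IntervalTree] = {}
    meta: dict[str, tuple[int, str, str]] = {}
    for row in annotation.itertuples(index=False):
        trees.setdefault(row.contig, IntervalTree()).addi(
            row.start, row.end, row.feature_id
        )
        meta[row.feature_id] = (row.start, row.strand, row.klass)

    rows = []
    for aln in alignments:
        best = None
        tree = trees.get(aln.contig)
        if tree is not None:
            for iv in tree.overlap(aln.start, aln.end):
                fid = iv.data
                fstart, fstrand, klass = meta[fid]
                if stranded and fstrand != aln.strand:
                    continue
                overlap = min(aln.end, iv.end) - max(aln.start, iv.begin)
                cand = (-overlap, fstart, fid, klass)
                if best is None or cand < best:
                    best = cand
        if best is None:
            rows.append((aln.read_id, OTHER, OTHER))
        else:
            rows.append((aln.read_id, best[2], best[3]))
    return pd.DataFrame(rows, columns=["read_id", "feature_id", "klass"])


def count_features(
    assignments_by_library: dict[str, pd.DataFrame],
    annotation: pd.DataFrame,
    conditions: dict[str, str] | None = None,
) -> CountMatrix:
    """counts[i, l] = reads of library l assigned to feature i; library
    sizes are totals of retained reads, so column sums plus the "other"
    bucket reconcile exactly with the retained-read ledger."""
    libraries = list(assignments_by_library)
    features = list(annotation["feature_id"])
    counts = pd.DataFrame(0, index=pd.Index(features, name="feature_id"),
                          columns=libraries, dtype=int)
    lib_sizes = pd.Series(0, index=libraries, dtype=int)
    for lib, df in assignments_by_library.items():
        lib_sizes[lib] = len(df)
        vc = df.loc[df["feature_id"] != OTHER, "feature_id"].value_counts()
        counts.loc[vc.index, lib] = vc.astype(int)
    return CountMatrix(counts=counts, lib_sizes=lib_sizes, conditions=conditions)


def class_summary(
    assignments_by_library: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Per-library fraction of retained reads per annotation class; rows
    sum to 1."""
    rows = {}
    for lib, df in assignments_by_library.items():
        n = len(df)
        frac = {}
        for klass in CLASSES:
            frac[klass] = (df["klass"] == klass).sum() / n if n else 0.0
        rows[lib] = frac
    out = pd.DataFrame(rows).T[CLASSES]
    out.index.name = "library"
    return out
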