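"""Demultiplexing, adaptor trimming and abundance/length filtering.

Reads carry a 5' adaptor with an embedded 4-nt sample barcode
(``ACAGGTTCAGAGTTCTACAGXXXXA``) and a 3' adaptor whose searchable DNA
portion is ``TCGTATGCCGTCTTCTGCTTG``. Demultiplexing requires an exact
barcode match (tolerating one mismatch in the constant 5' prefix);
trimming removes the leftmost suffix matching a 3'-adaptor prefix; known
artifact sequences (e.g. the transfected siRNA strands captured by the
protocol) are rejected outright; distinct insert sequences seen fewer than
10 times across all libraries are dropped; finally a length window is
applied.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field, replace

import pysam

from .simdata import ADAPTER3, ADAPTER5_TEMPLATE

UNASSIGNED = "UNASSIGNED"

# DNA forms of the transfected TERT siRNA strands (sense, antisense): reads
# identical to a captured siRNA are sequencing artifacts, not cellular RNA.
DEFAULT_ARTIFACTS = frozenset(
    {
        "GAGCAAGTTGCAAAGCATTTT",
        "AATGCTTTGCAACTTGCTCTT",
    }
)


@dataclass
class ShortRead:
    """A raw or trimmed read with provenance."""

    read_id: str
    seq: str
    qual: str
    sample: str = UNASSIGNED
    library: str = ""

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(f"seq/qual length mismatch in read {self.read_id}")


@dataclass
class ManifestEntry:
    tag: str
    condition: str
    library: str


@dataclass
class BarcodeManifest:
    entries: dict[str, ManifestEntry] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.entries:
            raise ValueError("empty barcode manifest")
        tags = [e.tag for e in self.entries.values()]
        if len(set(tags)) != len(tags):
            raise ValueError("duplicate barcode tags in manifest")
        for sample, e in self.entries.items():
            if len(e.tag) != 4:
                raise ValueError(f"barcode for {sample} is not 4 nt")

    @property
    def tag_to_sample(self) -> dict[str, str]:
        return {e.tag: s for s, e in self.entries.items()}

    @classmethod
    def from_tsv(cls, path) -> "BarcodeManifest":
        entries = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            idx = {c: i for i, c in enumerate(header)}
            for line in fh:
                if not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                entries[parts[idx["sample"]]] = ManifestEntry(
                    tag=parts[idx["tag"]],
                    condition=parts[idx["condition"]],
                    library=parts[idx.get("library", -1)] if "library" in idx else "lib1",
                )
        m = cls(entries)
        m.validate()
        return m


def read_fastq(path) -> Iterable[ShortRead]:
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            yield ShortRead(rec.name, rec.sequence, rec.quality or "")


def write_fastq(reads: Iterable[ShortRead], path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.seq}\n+\n{r.qual}\n")
            n += 1
    return n


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: Iterable[ShortRead],
    manifest: BarcodeManifest,
    adapter5: str = ADAPTER5_TEMPLATE,
) -> dict[str, list[ShortRead]]:
    """Assign reads to samples by exact 4-nt barcode match.

    A read is assigned to sample *s* iff the 4-mer at the barcode slot of
    ``adapter5`` equals *s*'s tag exactly, after verifying the constant 5'
    prefix with at most one mismatch. Assigned reads have the full adaptor
    (prefix + barcode + trailing constant base) removed; everything else
    lands untouched in the ``UNASSIGNED`` stream. Every input read appears
    in exactly one output stream.
    """
    manifest.validate()
    slot = adapter5.index("XXXX")
    prefix = adapter5[:slot]
    strip_len = len(adapter5)
    tag_to_sample = manifest.tag_to_sample

    out: dict[str, list[ShortRead]] = {s: [] for s in manifest.entries}
    out[UNASSIGNED] = []
    for read in reads:
        sample = None
        if len(read.seq) >= strip_len:
            if _hamming(read.seq[:slot], prefix) <= 1:
                sample = tag_to_sample.get(read.seq[slot : slot + 4])
        if sample is None:
            out[UNASSIGNED].append(read)
        else:
            entry = manifest.entries[sample]
            out[sample].append(
                ShortRead(
                    read.read_id,
                    read.seq[strip_len:],
                    read.qual[strip_len:],
                    sample=sample,
                    library=entry.library,
                )
            )
    return out


REJECT = None


def trim_adapter3(
    read: ShortRead,
    adapter3: str = ADAPTER3,
    min_overlap: int = 5,
    max_mismatch_rate: float = 0.1,
    artifacts: frozenset[str] = DEFAULT_ARTIFACTS,
) -> ShortRead | None:
    """Strip the 3' adaptor; returns ``None`` (REJECT) for empty inserts or
    known artifact sequences.

    The leftmost suffix of the read matching a prefix of ``adapter3`` over
    at least ``min_overlap`` bases with mismatch rate <= ``max_mismatch_rate``
    is removed. Reads without an adaptor occurrence are returned unchanged
    (minus the artifact check).
    """
    seq = read.seq
    n = len(seq)
    cut = n
    for i in range(0, n - min_overlap + 1):
        overlap = min(n - i, len(adapter3))
        if overlap < min_overlap:
            break
        mism = _hamming(seq[i : i + overlap], adapter3[:overlap])
        if mism <= max_mismatch_rate * overlap:
            cut = i
            break
    insert = seq[:cut]
    if not insert or insert in artifacts:
        return REJECT
    if cut == n:
        return read
    return replace(read, seq=insert, qual=read.qual[:cut])


def filter_low_abundance(
    counts_by_library: Mapping[str, Counter],
    min_total: int = 10,
) -> set[str]:
    """Return the distinct insert sequences retained by the abundance rule.

    A sequence is retained iff its summed count across ALL libraries is at
    least ``min_total`` (sequences found fewer than ``min_total`` times in
    all experiments are removed). Multiset semantics: idempotent and
    order-independent.
    """
    total: Counter = Counter()
    for counter in counts_by_library.values():
        total.update(counter)
    return {seq for seq, c in total.items() if c >= min_total}


def select_length(
    reads: Iterable[ShortRead], min_nt: int, max_nt: int
) -> list[ShortRead]:
    """Keep reads whose insert length lies in [min_nt, max_nt], ends inclusive."""
    if min_nt > max_nt:
        raise ValueError("min_nt > max_nt")
    return [r for r in reads if min_nt <= len(r.seq) <= max_nt]


def preprocess_library(
    reads: Iterable[ShortRead],
    manifest: BarcodeManifest,
    adapter5: str = ADAPTER5_TEMPLATE,
    adapter3: str = ADAPTER3,
    min_overlap: int = 5,
    max_mismatch_rate: float = 0.1,
    artifacts: frozenset[str] = DEFAULT_ARTIFACTS,
    length_range: tuple[int, int] = (15, 30),
    min_total: int = 10,
) -> tuple[dict[str, list[ShortRead]], dict]:
    """Full preprocessing of one pooled library; returns per-sample clean
    reads plus a stage ledger (input = output + rejected at every stage)."""
    demuxed = demultiplex(reads, manifest, adapter5)
    ledger: dict = {
        "demultiplex": {
            "assigned": {s: len(v) for s, v in demuxed.items() if s != UNASSIGNED},
            "unassigned": len(demuxed[UNASSIGNED]),
        }
    }
    trimmed: dict[str, list[ShortRead]] = {}
    n_reject = 0
    for sample, rs in demuxed.items():
        if sample == UNASSIGNED:
            continue
        kept = []
        for r in rs:
            t = trim_adapter3(r, adapter3, min_overlap, max_mismatch_rate, artifacts)
            if t is REJECT:
                n_reject += 1
            else:
                kept.append(t)
        trimmed[sample] = kept
    ledger["trim"] = {
        "kept": {s: len(v) for s, v in trimmed.items()},
        "rejected": n_reject,
    }
    sized = {
        s: select_length(v, length_range[0], length_range[1])
        for s, v in trimmed.items()
    }
    ledger["length"] = {
        "kept": {s: len(v) for s, v in sized.items()},
        "removed": sum(len(trimmed[s]) - len(sized[s]) for s in sized),
    }
    counts = {s: Counter(r.seq for r in v) for s, v in sized.items()}
    retained_seqs = filter_low_abundance(counts, min_total=min_total)
    clean = {s: [r for r in v if r.seq in retained_seqs] for s, v in sized.items()}
    ledger["abundance"] = {
        "kept": {s: len(v) for s, v in clean.items()},
        "removed": sum(len(sized[s]) - len(clean[s]) for s in clean),
        "min_total": min_total,
    }
    return clean, ledger
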