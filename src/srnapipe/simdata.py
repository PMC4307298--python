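"""Synthetic small-RNA screen generator.

Emulates a two-condition (control vs TERT-style knockdown) barcoded
small-RNA sequencing experiment at desk scale: a random toy genome with an
exact two-copy repeat, non-overlapping mature-miRNA-sized loci plus
tRNA/rRNA-like contaminant loci, negative-binomial per-feature counts with
a down-biased fold-change spectrum, and FASTQ reads carrying the 5'
barcoded adaptor / 3' adaptor architecture with position-dependent
substitution errors.

Every downstream stage of the pipeline (demultiplexing, trimming, mapping,
quantification, differential testing) is testable against the truth tables
written by this module, without any external download.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# 5' adaptor with the XXXX sample-barcode slot, and the searchable DNA
# portion of the biotinylated 3' adaptor.
ADAPTER5_TEMPLATE = "ACAGGTTCAGAGTTCTACAGXXXXA"
ADAPTER3 = "TCGTATGCCGTCTTCTGCTTG"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class CapacityError(ValueError):
    """Raised when feature placement is impossible at the requested density."""


@dataclass
class SampleSpec:
    """One pooled sample: its 4-nt barcode tag and its condition."""

    tag: str
    condition: str  # "control" or "knockdown"
    library: str = "lib1"


def default_samples() -> dict[str, SampleSpec]:
    return {
        "ctrl": SampleSpec("ACGT", "control"),
        "kd": SampleSpec("TGCA", "knockdown"),
    }


@dataclass
class SimulationConfig:
    """Parameters of the simulated screen.

    Defaults describe a deep, miRNA-focused two-library screen: 100 mature
    miRNA loci at a mean depth of 500 reads/feature/library, mild technical
    overdispersion (phi = 0.05), 40% of miRNAs truly down 2-4x in the
    knockdown and 5% up, and ~50% of reads coming from tRNA/rRNA-like
    contaminant loci.
    """

    seed: int = 0
    n_mirna: int = 100
    n_contaminant_loci: int = 20
    genome_length: int = 100_000
    mirna_length_range: tuple[int, int] = (18, 24)
    contaminant_length_range: tuple[int, int] = (70, 120)
    frac_down: float = 0.4
    fc_range_down: tuple[float, float] = (2.0, 4.0)
    frac_up: float = 0.05
    fc_range_up: tuple[float, float] = (2.0, 4.0)
    dispersion: float = 0.05
    mean_depth: float = 500.0
    mean_spread: float = 0.7  # sigma of the log-normal base-mean distribution
    contaminant_fraction: float = 0.5  # fraction of all reads from tRNA/rRNA loci
    error_profile_truth: np.ndarray | None = None  # per-cycle substitution prob
    samples: dict[str, SampleSpec] = field(default_factory=default_samples)
    adapter5: str = ADAPTER5_TEMPLATE
    adapter3: str = ADAPTER3
    insert_length_range: tuple[int, int] = (15, 30)
    read_length: int = 60
    repeat_length: int = 60
    contig_name: str = "chr1"

    def __post_init__(self) -> None:
        if self.error_profile_truth is None:
            self.error_profile_truth = np.full(self.read_length, 0.005)
        self.error_profile_truth = np.asarray(self.error_profile_truth, dtype=float)
        self.validate()

    def validate(self) -> None:
        if not (0.0 <= self.frac_down <= 1.0 and 0.0 <= self.frac_up <= 1.0):
            raise ValueError("frac_down/frac_up must lie in [0, 1]")
        if self.frac_down + self.frac_up > 1.0:
            raise ValueError("frac_down + frac_up must be <= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not (0.0 <= self.contaminant_fraction < 1.0):
            raise ValueError("contaminant_fraction must lie in [0, 1)")
        if np.any(self.error_profile_truth < 0) or np.any(self.error_profile_truth > 1):
            raise ValueError("error probabilities must lie in [0, 1]")
        if len(self.error_profile_truth) < self.read_length:
            raise ValueError("error_profile_truth shorter than read_length")
        tags = [s.tag for s in self.samples.values()]
        if len(set(tags)) != len(tags):
            raise ValueError("sample barcodes must be distinct")
        if any(len(t) != 4 or set(t) - set("ACGT") for t in tags):
            raise ValueError("barcodes must be 4-nt ACGT strings")
        lo, hi = self.mirna_length_range
        if lo > hi or lo < 1:
            raise ValueError("bad mirna_length_range")
        ilo, ihi = self.insert_length_range
        if ilo > ihi or ilo < 1:
            raise ValueError("bad insert_length_range")
        barcode_end = self.adapter5.index("XXXX") + 4
        if self.read_length < barcode_end + 1 + ilo:
            raise ValueError("read_length too short for barcode + minimal insert")


@dataclass
class ReferenceBundle:
    """Toy genome + annotation + expression truth for one simulated screen."""

    genome: dict[str, str]
    annotation: pd.DataFrame  # contig, start, end, strand, feature_id, klass
    truth: pd.DataFrame  # indexed by feature_id: base_mean, true_log2FC, klass
    repeat_regions: list[tuple[str, int, int]]

    def feature_sequence(self, feature_id: str) -> str:
        row = self.annotation.set_index("feature_id").loc[feature_id]
        seq = self.genome[row["contig"]][row["start"] : row["end"]]
        return revcomp(seq) if row["strand"] == "-" else seq


def _place_intervals(
    rng: np.random.Generator,
    occ: np.ndarray,
    n: int,
    length_range: tuple[int, int],
    max_tries: int = 20_000,
) -> list[tuple[int, int]]:
    glen = occ.size
    out: list[tuple[int, int]] = []
    tries = 0
    while len(out) < n:
        if tries >= max_tries:
            raise CapacityError(
                f"could not place {n} features of size {length_range} "
                f"in a {glen} bp genome after {max_tries} tries"
            )
        tries += 1
        width = int(rng.integers(length_range[0], length_range[1] + 1))
        if width >= glen:
            raise CapacityError("feature longer than genome")
        start = int(rng.integers(0, glen - width))
        if occ[start : start + width].any():
            continue
        occ[start : start + width] = True
        out.append((start, start + width))
    return out


def generate_reference(config: SimulationConfig) -> ReferenceBundle:
    """Build the toy genome, annotation and expression truth table.

    The genome is i.i.d. uniform over {A,C,G,T} except for one designated
    exact two-copy repeat (length ``config.repeat_length``) that exercises
    the mapper's multi-mapping / MAPQ logic. Features never overlap each
    other or the repeat copies, so every feature read has a unique origin.
    """
    rng = np.random.default_rng([config.seed, 101])
    glen = config.genome_length
    codes = rng.integers(0, 4, size=glen)
    genome_arr = _BASES[codes]

    # exact two-copy repeat: copy a segment to a disjoint location
    rl = config.repeat_length
    if glen < 4 * rl:
        raise CapacityError("genome too short for the designated repeat")
    while True:
        a = int(rng.integers(0, glen - rl))
        b = int(rng.integers(0, glen - rl))
        if abs(a - b) >= rl:
            break
    genome_arr[b : b + rl] = genome_arr[a : a + rl]
    genome = {config.contig_name: genome_arr.tobytes().decode("ascii")}
    repeat_regions = [
        (config.contig_name, a, a + rl),
        (config.contig_name, b, b + rl),
    ]

    occ = np.zeros(glen, dtype=bool)
    occ[a : a + rl] = True
    occ[b : b + rl] = True

    mirna_iv = _place_intervals(rng, occ, config.n_mirna, config.mirna_length_range)
    cont_iv = _place_intervals(
        rng, occ, config.n_contaminant_loci, config.contaminant_length_range
    )

    rows = []
    for i, (s, e) in enumerate(mirna_iv):
        rows.append(
            (config.contig_name, s, e, "+-"[int(rng.integers(0, 2))],
             f"mir-{i + 1:04d}", "miRNA")
        )
    for i, (s, e) in enumerate(cont_iv):
        klass = "tRNA" if i % 2 == 0 else "rRNA"
        prefix = "trna" if klass == "tRNA" else "rrna"
        rows.append(
            (config.contig_name, s, e, "+-"[int(rng.integers(0, 2))],
             f"{prefix}-{i + 1:04d}", klass)
        )
    annotation = pd.DataFrame(
        rows, columns=["contig", "start", "end", "strand", "feature_id", "klass"]
    )

    # expression truth: log-normal base means with E[mean] = mean_depth
    n = config.n_mirna
    sig = config.mean_spread
    mu = math.log(config.mean_depth) - sig * sig / 2.0
    base_means = rng.lognormal(mean=mu, sigma=sig, size=n)

    lfc = np.zeros(n)
    n_down = round(config.frac_down * n)
    n_up = round(config.frac_up * n)
    order = rng.permutation(n)
    down_idx = order[:n_down]
    up_idx = order[n_down : n_down + n_up]
    lfc[down_idx] = -np.log2(rng.uniform(*config.fc_range_down, size=n_down))
    lfc[up_idx] = np.log2(rng.uniform(*config.fc_range_up, size=n_up))

    # contaminant loci: unchanged between conditions; per-locus means scaled
    # so that contaminants contribute `contaminant_fraction` of all reads
    cf = config.contaminant_fraction
    total_mirna = float(base_means.sum())
    if config.n_contaminant_loci > 0 and cf > 0:
        raw = rng.lognormal(mean=0.0, sigma=sig, size=config.n_contaminant_loci)
        cont_means = raw / raw.sum() * total_mirna * cf / (1.0 - cf)
    else:
        cont_means = np.zeros(config.n_contaminant_loci)

    mir_ids = annotation.loc[annotation["klass"] == "miRNA", "feature_id"]
    cont_ids = annotation.loc[annotation["klass"] != "miRNA", "feature_id"]
    truth = pd.DataFrame(
        {
            "base_mean": np.concatenate([base_means, cont_means]),
            "true_log2FC": np.concatenate(
                [lfc, np.zeros(config.n_contaminant_loci)]
            ),
            "klass": (["miRNA"] * n)
            + list(annotation.loc[annotation["klass"] != "miRNA", "klass"]),
        },
        index=pd.Index(list(mir_ids) + list(cont_ids), name="feature_id"),
    )
    return ReferenceBundle(genome, annotation, truth, repeat_regions)


def draw_counts(
    bundle: ReferenceBundle,
    config: SimulationConfig,
    condition: str,
    stream: int = 0,
) -> pd.Series:
    """Draw one library's per-feature counts from the NB generative model.

    count_i ~ NB(mean = base_mean_i * 2^(true_log2FC_i * [knockdown]),
    dispersion = phi), with phi = 0 degenerating to Poisson. ``stream``
    separates the random streams of multiple libraries of one condition.
    """
    if condition not in ("control", "knockdown"):
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(
        [config.seed, 202, stream, 1 if condition == "knockdown" else 0]
    )
    means = bundle.truth["base_mean"].to_numpy(dtype=float).copy()
    if condition == "knockdown":
        means *= 2.0 ** bundle.truth["true_log2FC"].to_numpy(dtype=float)
    phi = config.dispersion
    if phi == 0.0:
        counts = rng.poisson(means)
    else:
        r = 1.0 / phi
        p = r / (r + means)
        counts = rng.negative_binomial(r, p)
    return pd.Series(counts, index=bundle.truth.index, name=condition)


def _phred33(errors: np.ndarray) -> str:
    q = np.where(errors <= 0, 40, np.minimum(40, np.rint(-10 * np.log10(
        np.clip(errors, 1e-12, 1.0))))).astype(int)
    q = np.maximum(q, 2)
    return "".join(chr(33 + int(v)) for v in q)


def synthesize_fastq(
    bundle: ReferenceBundle,
    counts_by_sample: dict[str, pd.Series],
    config: SimulationConfig,
    path,
) -> dict[str, int]:
    """Write the pooled, barcoded FASTQ for all samples of one library.

    Each read is ``adapter5(barcode) + insert + adapter3`` truncated to the
    read length, with per-cycle substitution errors injected according to
    ``config.error_profile_truth``. miRNA reads carry the full mature
    sequence as insert; contaminant reads are random fragments of their
    locus. Quality strings encode the *true* per-cycle error rate
    (Phred+33); the mapper must estimate its own profile and never trusts
    them. Read ids encode the originating sample, feature, genomic start
    and strand for truth-based evaluation:
    ``sample|feature_id|serial|origin_start|strand``.
    """
    rng = np.random.default_rng([config.seed, 303])
    L = config.read_length
    errs = config.error_profile_truth[:L]
    qual = _phred33(errs)
    ann = bundle.annotation.set_index("feature_id")
    ilo, ihi = config.insert_length_range

    records: list[str] = []
    n_per_sample: dict[str, int] = {}
    for sample in sorted(counts_by_sample):
        spec = config.samples[sample]
        prefix = config.adapter5.replace("XXXX", spec.tag)
        counts = counts_by_sample[sample]
        n_total = 0
        for feature_id, c in counts.items():
            c = int(c)
            if c == 0:
                continue
            row = ann.loc[feature_id]
            fstart, fend, strand = int(row["start"]), int(row["end"]), row["strand"]
            width = fend - fstart
            mature = bundle.feature_sequence(feature_id)
            is_mirna = row["klass"] == "miRNA"
            for i in range(c):
                if is_mirna:
                    insert = mature
                    g0, g1 = fstart, fend
                else:
                    flen = int(rng.integers(ilo, min(ihi, width) + 1))
                    off = int(rng.integers(0, width - flen + 1))
                    insert = mature[off : off + flen]
                    # mature coords run 3'->5' on '-' features
                    if strand == "+":
                        g0, g1 = fstart + off, fstart + off + flen
                    else:
                        g0, g1 = fend - off - flen, fend - off
                read = (prefix + insert + config.adapter3)[:L]
                # per-cycle substitutions
                rl = len(read)
                hit = rng.random(rl) < errs[:rl]
                if hit.any():
                    arr = np.frombuffer(read.encode(), dtype=np.uint8).copy()
                    for j in np.flatnonzero(hit):
                        cur = arr[j]
                        choices = _BASES[_BASES != cur]
                        arr[j] = choices[int(rng.integers(0, 3))]
                    read = arr.tobytes().decode("ascii")
                rid = f"{sample}|{feature_id}|{n_total + i}|{g0}|{strand}"
                records.append(f"@{rid}\n{read}\n+\n{qual[:rl]}\n")
            n_total += c
        n_per_sample[sample] = n_total

    # shuffle so the pooled library is not grouped by sample
    perm = rng.permutation(len(records))
    with open(path, "w") as fh:
        for i in perm:
            fh.write(records[i])
    return n_per_sample


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bed(annotation: pd.DataFrame, path) -> None:
    """BED6, 0-based half-open; name field is ``feature_id|class``."""
    with open(path, "w") as fh:
        for row in annotation.itertuples(index=False):
            fh.write(
                f"{row.contig}\t{row.start}\t{row.end}\t"
                f"{row.feature_id}|{row.klass}\t0\t{row.strand}\n"
            )


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["contig", "start", "end", "name", "score", "strand"],
    )
    split = df["name"].str.rsplit("|", n=1, expand=True)
    df["feature_id"] = split[0]
    df["klass"] = split[1].fillna("other")
    return df[["contig", "start", "end", "strand", "feature_id", "klass"]]


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t")


def write_manifest(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\ttag\tcondition\tlibrary\n")
        for name, spec in config.samples.items():
            fh.write(f"{name}\t{spec.tag}\t{spec.condition}\t{spec.library}\n")


def simulate_screen(config: SimulationConfig, outdir) -> dict:
    """Run the full generator: reference, counts, FASTQ, truth files.

    Returns a dict with the bundle, per-sample counts and written paths.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    bundle = generate_reference(config)
    counts_by_sample = {}
    stream = 0
    for sample in sorted(config.samples):
        counts_by_sample[sample] = draw_counts(
            bundle, config, config.samples[sample].condition, stream=stream
        )
        stream += 1
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "annotation": os.path.join(outdir, "annotation.bed"),
        "truth": os.path.join(outdir, "truth.tsv"),
        "manifest": os.path.join(outdir, "manifest.tsv"),
        "fastq": os.path.join(outdir, "reads.fastq"),
    }
    write_fasta(bundle.genome, paths["genome"])
    write_bed(bundle.annotation, paths["annotation"])
    write_truth(bundle.truth, paths["truth"])
    write_manifest(config, paths["manifest"])
    n_per_sample = synthesize_fastq(bundle, counts_by_sample, config, paths["fastq"])
    return {
        "bundle": bundle,
        "counts": counts_by_sample,
        "paths": paths,
        "n_reads": n_per_sample,
    }
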