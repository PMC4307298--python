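"""Seed-and-extend pair-HMM read mapper with iterative error estimation.

Candidate genome locations come from an exhaustive k-mer index of the toy
genome (forward strand; reverse-strand candidates via the read's reverse
complement). Each candidate window is scored with the pair-HMM forward
algorithm; the read is placed at the maximum-posterior location with a
Phred-scaled MAPQ, and placements below the MAPQ threshold (default 10,
i.e. <90% chance of being correct) are flagged as discarded but still
written to the SAM output as unmapped-with-tag records.

The per-cycle substitution profile is estimated iteratively: map all
reads with the current profile, re-estimate each cycle's error rate from
mismatches of confidently mapped (MAPQ >= 20), gapless alignments with a
pseudocount, and repeat until the profile stabilises.
"""

from __future__ import annotations

import math
from collections import defaultdict
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import numpy as np
import pysam

from .phmm import ErrorProfile, compute_mapq, encode_seq, forward_loglik, viterbi
from .preprocess import ShortRead
from .simdata import revcomp

_CIGAR_OPS = "MID"


@dataclass
class SeedIndex:
    """Exhaustive k-mer -> genome position index (forward strand)."""

    k: int
    contigs: list[str]
    lengths: dict[str, int]
    positions: dict[str, list[tuple[int, int]]]  # kmer -> [(contig_idx, pos)]

    @classmethod
    def build(cls, genome: Mapping[str, str], k: int = 12) -> "SeedIndex":
        if k < 1:
            raise ValueError("seed length k must be >= 1")
        contigs = sorted(genome)
        if all(len(genome[c]) < k for c in contigs):
            raise ValueError("k exceeds the length of every contig")
        positions: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for ci, name in enumerate(contigs):
            seq = genome[name].upper()
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" in kmer:
                    continue
                positions[kmer].append((ci, pos))
        return cls(
            k=k,
            contigs=contigs,
            lengths={c: len(genome[c]) for c in contigs},
            positions=dict(positions),
        )

    def lookup(self, kmer: str) -> list[tuple[int, int]]:
        return self.positions.get(kmer, [])


@dataclass
class Candidate:
    contig: str
    start: int  # window start, 0-based
    end: int  # window end, half-open
    strand: str
    n_hits: int


def candidate_locations(
    seq: str,
    index: SeedIndex,
    band: int = 3,
    max_candidates: int = 50,
) -> list[Candidate]:
    """Candidate windows anchored by exact k-mer hits of the read or its
    reverse complement; origins within ``2*band`` are merged into one
    window; capped at ``max_candidates`` by hit count with deterministic
    tie-break (lowest coordinate first)."""
    L = len(seq)
    k = index.k
    if L < k:
        return []
    cands: list[Candidate] = []
    for strand, qseq in (("+", seq.upper()), ("-", revcomp(seq.upper()))):
        anchors: dict[int, dict[int, int]] = defaultdict(lambda: defaultdict(int))
        for off in range(L - k + 1):
            for ci, pos in index.lookup(qseq[off : off + k]):
                anchors[ci][pos - off] += 1
        for ci, origins in anchors.items():
            contig = index.contigs[ci]
            clen = index.lengths[contig]
            sorted_origins = sorted(origins)
            group: list[int] = []
            for o in sorted_origins + [None]:
                if group and (o is None or o - group[-1] > 2 * band):
                    w0 = max(0, group[0] - band)
                    w1 = min(clen, group[-1] + L + band)
                    cands.append(
                        Candidate(
                            contig,
                            w0,
                            w1,
                            strand,
                            sum(origins[g] for g in group),
                        )
                    )
                    group = []
                if o is not None:
                    group.append(o)
    cands.sort(key=lambda c: (-c.n_hits, c.contig, c.start, c.strand))
    cands = cands[:max_candidates]
    cands.sort(key=lambda c: (c.contig, c.start, c.strand))
    return cands


@dataclass
class MappedRead:
    """One read's maximum-posterior placement."""

    seq: str
    contig: str
    start: int  # 0-based
    end: int  # half-open
    strand: str
    cigar: list[tuple[int, int]]  # pysam-style (op, length), ops in {0=M,1=I,2=D}
    n_mismatch: int
    mismatch_cycles: list[int]  # original read cycles (0-based), gapless only
    gapless: bool
    loglik: float
    posterior: float
    mapq: int
    n_candidates: int
    is_discarded: bool


class PairHmmMapper:
    """Maps insert sequences against a small genome."""

    def __init__(
        self,
        genome: Mapping[str, str],
        k: int = 12,
        band: int = 3,
        max_candidates: int = 50,
        mapq_cap: int = 60,
        mapq_threshold: int = 10,
        fallback_k: int = 8,
    ) -> None:
        self.genome = {c: genome[c].upper() for c in genome}
        self.index = SeedIndex.build(self.genome, k=k)
        # a short read with one central error can lose every exact k-mer;
        # a coarser second index rescues those reads without slowing the
        # common case
        self.fallback_index = None
        if fallback_k < k and any(len(s) >= fallback_k for s in self.genome.values()):
            self.fallback_index = SeedIndex.build(self.genome, k=fallback_k)
        self.encoded = {c: encode_seq(self.genome[c]) for c in self.genome}
        self.band = band
        self.max_candidates = max_candidates
        self.mapq_cap = mapq_cap
        self.mapq_threshold = mapq_threshold

    def map_sequence(self, seq: str, profile: ErrorProfile) -> MappedRead | None:
        """Score all candidate locations and place the read; ``None`` when
        no candidate window exists (unmapped)."""
        cands = candidate_locations(
            seq, self.index, band=self.band, max_candidates=self.max_candidates
        )
        if not cands and self.fallback_index is not None:
            cands = candidate_locations(
                seq,
                self.fallback_index,
                band=self.band,
                max_candidates=self.max_candidates,
            )
        if not cands:
            return None
        L = len(seq)
        fwd = encode_seq(seq.upper())
        rev = encode_seq(revcomp(seq.upper()))
        lm_f, lx_f = profile.log_terms(L, reverse=False)
        lm_r, lx_r = profile.log_terms(L, reverse=True)
        lls = np.empty(len(cands))
        for i, c in enumerate(cands):
            win = self.encoded[c.contig][c.start : c.end]
            if c.strand == "+":
                lls[i] = forward_loglik(
                    fwd, win, lm_f, lx_f, profile.gap_open, profile.gap_extend
                )
            else:
                lls[i] = forward_loglik(
                    rev, win, lm_r, lx_r, profile.gap_open, profile.gap_extend
                )
        keys = [(c.contig, c.start, c.strand) for c in cands]
        best_i, posterior, mapq = compute_mapq(lls, keys, mapq_cap=self.mapq_cap)
        best = cands[best_i]
        win = self.encoded[best.contig][best.start : best.end]
        if best.strand == "+":
            _, g0, g1, ops = viterbi(
                fwd, win, lm_f, lx_f, profile.gap_open, profile.gap_extend
            )
            q = fwd
        else:
            _, g0, g1, ops = viterbi(
                rev, win, lm_r, lx_r, profile.gap_open, profile.gap_extend
            )
            q = rev
        cigar: list[tuple[int, int]] = []
        for op in ops:
            op = int(op)
            if cigar and cigar[-1][0] == op:
                cigar[-1] = (op, cigar[-1][1] + 1)
            else:
                cigar.append((op, 1))
        gapless = len(cigar) == 1 and cigar[0][0] == 0
        n_mismatch = 0
        mism_cycles: list[int] = []
        qi = 0
        gi = g0
        for op, run in cigar:
            if op == 0:
                for _ in range(run):
                    if q[qi] != win[gi] or q[qi] >= 4:
                        n_mismatch += 1
                        cycle = qi if best.strand == "+" else L - 1 - qi
                        mism_cycles.append(cycle)
                    qi += 1
                    gi += 1
            elif op == 1:
                qi += run
            else:
                gi += run
        return MappedRead(
            seq=seq,
            contig=best.contig,
            start=best.start + g0,
            end=best.start + g1,
            strand=best.strand,
            cigar=cigar,
            n_mismatch=n_mismatch,
            mismatch_cycles=mism_cycles if gapless else [],
            gapless=gapless,
            loglik=float(lls[best_i]),
            posterior=posterior,
            mapq=mapq,
            n_candidates=len(cands),
            is_discarded=mapq < self.mapq_threshold,
        )

    def map_unique(
        self, seq_counts: Mapping[str, int], profile: ErrorProfile
    ) -> dict[str, MappedRead | None]:
        """Map each distinct sequence once (mapping depends only on the
        sequence and the profile)."""
        return {seq: self.map_sequence(seq, profile) for seq in seq_counts}


def estimate_error_profile(
    seq_counts: Mapping[str, int],
    mapper: PairHmmMapper,
    init_profile: ErrorProfile | None = None,
    max_iter: int = 5,
    tol: float = 1e-4,
    confident_mapq: int = 20,
    alpha: float = 1.0,
) -> tuple[ErrorProfile, list[float]]:
    """Iteratively estimate the per-cycle substitution profile.

    Each round maps all reads with the current profile, then sets
    e_j = (mismatches at cycle j + alpha) / (aligned bases at cycle j +
    4*alpha) over confidently mapped (MAPQ >= confident_mapq), gapless
    alignments. Stops when max_j |delta e_j| < tol or after ``max_iter``
    rounds. Returns the final profile and the per-round total mapped
    log-likelihood (count-weighted). If a round finds no confident reads
    the incoming profile is returned with its warning flag set.
    """
    lmax = max((len(s) for s in seq_counts), default=0)
    if init_profile is None:
        init_profile = ErrorProfile.uniform(lmax, 0.02)
    profile = init_profile
    ll_history: list[float] = []
    for it in range(max_iter):
        mm = np.zeros(profile.sub.size)
        nn = np.zeros(profile.sub.size)
        total_ll = 0.0
        n_confident = 0
        for seq, cnt in seq_counts.items():
            res = mapper.map_sequence(seq, profile)
            if res is None:
                continue
            total_ll += cnt * res.loglik
            if res.is_discarded or res.mapq < confident_mapq or not res.gapless:
                continue
            n_confident += cnt
            L = len(seq)
            nn[:L] += cnt
            for c in res.mismatch_cycles:
                mm[c] += cnt
        ll_history.append(total_ll)
        if n_confident == 0:
            return (
                ErrorProfile(
                    init_profile.sub.copy(),
                    init_profile.gap_open,
                    init_profile.gap_extend,
                    iteration=it + 1,
                    warning=True,
                ),
                ll_history,
            )
        new_sub = profile.sub.copy()
        seen = nn > 0
        new_sub[seen] = (mm[seen] + alpha) / (nn[seen] + 4.0 * alpha)
        new_sub = np.clip(new_sub, 0.0, 0.75)
        delta = float(np.max(np.abs(new_sub[seen] - profile.sub[seen]))) if seen.any() else 0.0
        profile = ErrorProfile(
            new_sub,
            profile.gap_open,
            profile.gap_extend,
            iteration=it + 1,
        )
        if delta < tol:
            break
    return profile, ll_history


def sam_header(genome: Mapping[str, str]) -> dict:
    contigs = sorted(genome)
    return {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": len(genome[c])} for c in contigs],
        "PG": [{"ID": "srnapipe", "PN": "srnapipe"}],
    }


def map_reads(
    reads: Iterable[ShortRead],
    mapper: PairHmmMapper,
    profile: ErrorProfile,
    sam_path,
    cache: dict[str, MappedRead | None] | None = None,
) -> dict[str, int]:
    """Map reads and write a SAM file; returns a tally.

    Retained placements become mapped records (1-based SAM coordinates,
    MAPQ as computed, NM edit distance, ZP posterior tag). Reads whose
    best placement falls below the MAPQ threshold are written as unmapped
    records carrying a ZD:1 tag (discarded, not silently dropped), as are
    reads with no candidate location at all (ZD:2).
    """
    if cache is None:
        cache = {}
    header = sam_header(mapper.genome)
    tally = {"mapped": 0, "discarded": 0, "unmapped": 0}
    tid = {c: i for i, c in enumerate(sorted(mapper.genome))}
    with pysam.AlignmentFile(str(sam_path), "wh", header=header) as out:
        for read in reads:
            seq = read.seq.upper()
            if seq in cache:
                res = cache[seq]
            else:
                res = mapper.map_sequence(seq, profile)
                cache[seq] = res
            a = pysam.AlignedSegment(out.header)
            a.query_name = read.read_id
            if res is None:
                a.query_sequence = read.seq
                a.query_qualities = pysam.qualitystring_to_array(read.qual)
                a.flag = 4
                a.set_tag("ZD", 2)
                tally["unmapped"] += 1
            else:
                if res.strand == "-":
                    a.query_sequence = revcomp(read.seq)
                    a.query_qualities = pysam.qualitystring_to_array(read.qual[::-1])
                else:
                    a.query_sequence = read.seq
                    a.query_qualities = pysam.qualitystring_to_array(read.qual)
                a.set_tag("ZP", round(res.posterior, 6))
                a.set_tag("NM", res.n_mismatch + sum(
                    r for op, r in res.cigar if op != 0
                ))
                if res.is_discarded:
                    a.flag = 4
                    a.set_tag("ZD", 1)
                    a.set_tag("ZQ", res.mapq)
                    tally["discarded"] += 1
                else:
                    a.flag = 16 if res.strand == "-" else 0
                    a.reference_id = tid[res.contig]
                    a.reference_start = res.start
                    a.mapping_quality = res.mapq
                    a.cigartuples = res.cigar
                    tally["mapped"] += 1
            out.write(a)
    return tally
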