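"""Pair-HMM alignment core and Phred-scaled mapping quality.

The mapper scores a read against a candidate genome window with a 3-state
pair HMM (match/mismatch M, read-insertion X, genome-deletion Y). The
model is local with respect to the genome (the alignment may start at any
window position, cost-free, and unaligned flanking genome is ignored) and
global with respect to the read (every read base is consumed). Emission
at M for read cycle j is (1 - e_j) on base equality and e_j/3 otherwise,
where e_j is the per-cycle substitution probability of the error profile;
X emits a read base uniformly (1/4); Y consumes a genome base silently.
Transitions: M->X = M->Y = gap_open, X->X = Y->Y = gap_extend,
M->M = 1 - 2*gap_open, X->M = Y->M = 1 - gap_extend.

The forward algorithm sums probability over all alignments (the read's
likelihood at that location); Viterbi recovers the single best alignment
for reporting. The posterior that the best location is correct, under a
uniform prior over discovered candidate locations, is converted to a
Phred-scaled MAPQ = round(-10*log10(1 - posterior)); MAPQ 10 corresponds
to a 90% chance the placement is correct and is the default discard
threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

_NEG = -1.0e300

# base encoding: A,C,G,T -> 0..3, anything else (N) -> 4 (matches nothing)
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i


def encode_seq(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class ErrorProfile:
    """Per-cycle substitution probabilities plus gap parameters.

    ``sub[j]`` is the probability that cycle j (0-based read coordinate)
    reports the wrong base. The profile is strand-agnostic: on the reverse
    strand the per-cycle vector is applied in reversed order along the
    genome. ``iteration`` counts refinement rounds of the iterative
    estimator; ``warning`` flags an estimation round that found no
    confidently mapped reads.
    """

    sub: np.ndarray
    gap_open: float = 0.001
    gap_extend: float = 0.1
    iteration: int = 0
    warning: bool = False

    def __post_init__(self) -> None:
        self.sub = np.asarray(self.sub, dtype=float)
        if np.any(self.sub < 0) or np.any(self.sub > 0.75):
            raise ValueError("per-cycle error probabilities must lie in [0, 0.75]")
        if not (0.0 <= self.gap_open <= 0.3):
            raise ValueError("gap_open must lie in [0, 0.3]")
        if not (0.0 <= self.gap_extend < 1.0):
            raise ValueError("gap_extend must lie in [0, 1)")

    @classmethod
    def uniform(cls, length: int, e: float = 0.02, **kw) -> "ErrorProfile":
        return cls(np.full(length, e), **kw)

    def log_terms(self, length: int, reverse: bool = False):
        """Per-cycle log emission terms (match, mismatch) for a read of
        ``length`` cycles, optionally reversed for '-' strand alignment."""
        if length > self.sub.size:
            raise ValueError(
                f"profile covers {self.sub.size} cycles; read has {length}"
            )
        e = self.sub[:length]
        if reverse:
            e = e[::-1]
        with np.errstate(divide="ignore"):
            lmatch = np.log1p(-e)
            lmis = np.where(e > 0, np.log(np.maximum(e, 1e-300) / 3.0), _NEG)
        return np.ascontiguousarray(lmatch), np.ascontiguousarray(lmis)


@njit(cache=True, inline="always")
def _lse2(a, b):
    if a < b:
        a, b = b, a
    if b <= _NEG / 2:
        return a
    return a + math.log1p(math.exp(b - a))


@njit(cache=True)
def forward_loglik(read, win, lmatch, lmis, gap_open, gap_extend):
    """Forward-algorithm log P(read | window, profile).

    Free start/end offsets within the window carry no cost; the alignment
    begins in M and ends in M or X after consuming the whole read.
    Computed in log space; safe for reads up to a few hundred cycles.
    """
    L = read.size
    W = win.size
    if gap_open > 0.0:
        t_mm = math.log(1.0 - 2.0 * gap_open)
        t_gap = math.log(gap_open)
    else:
        t_mm = 0.0
        t_gap = _NEG
    if gap_extend > 0.0:
        t_ee = math.log(gap_extend)
    else:
        t_ee = _NEG
    t_em = math.log(1.0 - gap_extend)
    lx_emit = math.log(0.25)

    fm = np.full((L + 1, W + 1), _NEG)
    fx = np.full((L + 1, W + 1), _NEG)
    fy = np.full((L + 1, W + 1), _NEG)

    for i in range(1, L + 1):
        ri = read[i - 1]
        for g in range(0, W + 1):
            if g >= 1:
                gi = win[g - 1]
                if ri == gi and ri < 4:
                    em = lmatch[i - 1]
                else:
                    em = lmis[i - 1]
                if i == 1:
                    best = em  # free start in M
                else:
                    acc = _lse2(fm[i - 1, g - 1] + t_mm, fx[i - 1, g - 1] + t_em)
                    acc = _lse2(acc, fy[i - 1, g - 1] + t_em)
                    best = em + acc
                fm[i, g] = best
            # X: consumes read base i, no genome base
            if i >= 2:
                accx = _lse2(fm[i - 1, g] + t_gap, fx[i - 1, g] + t_ee)
                fx[i, g] = lx_emit + accx
            # Y: consumes genome base g after read base i
            if g >= 1 and i < L:
                accy = _lse2(fm[i, g - 1] + t_gap, fy[i, g - 1] + t_ee)
                fy[i, g] = accy

    total = _NEG
    for g in range(0, W + 1):
        total = _lse2(total, fm[L, g])
        total = _lse2(total, fx[L, g])
    return total


@njit(cache=True)
def viterbi(read, win, lmatch, lmis, gap_open, gap_extend):
    """Best single alignment: returns (score, g_start, g_end, ops).

    ops is an int8 array over alignment columns: 0 = M (read+genome),
    1 = I (read only), 2 = D (genome only). g_start/g_end are 0-based
    half-open window coordinates of the aligned genome segment.
    """
    L = read.size
    W = win.size
    if gap_open > 0.0:
        t_mm = math.log(1.0 - 2.0 * gap_open)
        t_gap = math.log(gap_open)
    else:
        t_mm = 0.0
        t_gap = _NEG
    if gap_extend > 0.0:
        t_ee = math.log(gap_extend)
    else:
        t_ee = _NEG
    t_em = math.log(1.0 - gap_extend)
    lx_emit = math.log(0.25)

    vm = np.full((L + 1, W + 1), _NEG)
    vx = np.full((L + 1, W + 1), _NEG)
    vy = np.full((L + 1, W + 1), _NEG)
    # backpointers: 0 from M, 1 from X, 2 from Y, 3 start
    bm = np.zeros((L + 1, W + 1), dtype=np.int8)
    bx = np.zeros((L + 1, W + 1), dtype=np.int8)
    by = np.zeros((L + 1, W + 1), dtype=np.int8)

    for i in range(1, L + 1):
        ri = read[i - 1]
        for g in range(0, W + 1):
            if g >= 1:
                gi = win[g - 1]
                if ri == gi and ri < 4:
                    em = lmatch[i - 1]
                else:
                    em = lmis[i - 1]
                if i == 1:
                    vm[i, g] = em
                    bm[i, g] = 3
                else:
                    a = vm[i - 1, g - 1] + t_mm
                    b = vx[i - 1, g - 1] + t_em
                    c = vy[i - 1, g - 1] + t_em
                    if a >= b and a >= c:
                        vm[i, g] = em + a
                        bm[i, g] = 0
                    elif b >= c:
                        vm[i, g] = em + b
                        bm[i, g] = 1
                    else:
                        vm[i, g] = em + c
                        bm[i, g] = 2
            if i >= 2:
                a = vm[i - 1, g] + t_gap
                b = vx[i - 1, g] + t_ee
                if a >= b:
                    vx[i, g] = lx_emit + a
                    bx[i, g] = 0
                else:
                    vx[i, g] = lx_emit + b
                    bx[i, g] = 1
            if g >= 1 and i < L:
                a = vm[i, g - 1] + t_gap
                b = vy[i, g - 1] + t_ee
                if a >= b:
                    vy[i, g] = a
                    by[i, g] = 0
                else:
                    vy[i, g] = b
                    by[i, g] = 2

    best = _NEG
    best_g = 0
    best_state = 0
    for g in range(0, W + 1):
        if vm[L, g] > best:
            best = vm[L, g]
            best_g = g
            best_state = 0
        if vx[L, g] > best:
            best = vx[L, g]
            best_g = g
            best_state = 1

    # traceback
    ops = np.empty(2 * L + W + 1, dtype=np.int8)
    nops = 0
    i = L
    g = best_g
    state = best_state
    g_end = best_g
    while True:
        if state == 0:  # M
            ops[nops] = 0
            nops += 1
            prev = bm[i, g]
            i -= 1
            g -= 1
            if prev == 3:
                break
            state = prev
        elif state == 1:  # X / insertion
            ops[nops] = 1
            nops += 1
            prev = bx[i, g]
            i -= 1
            state = prev
        else:  # Y / deletion
            ops[nops] = 2
            nops += 1
            prev = by[i, g]
            g -= 1
            state = prev
    g_start = g
    return best, g_start, g_end, ops[:nops][::-1].copy()


def compute_mapq(
    logliks,
    keys=None,
    mapq_cap: int = 60,
):
    """Maximum-posterior placement and Phred-scaled mapping quality.

    ``logliks`` are the forward log-likelihoods of the candidate
    locations; ``keys`` (sortable, e.g. (contig, start, strand)) break
    likelihood ties deterministically in favor of the lowest coordinate.
    Returns (best_index, posterior, mapq). The posterior is
    L_best / sum_i L_i under a uniform location prior; MAPQ =
    round-half-up(-10*log10(1 - posterior)), capped at ``mapq_cap``.
    """
    ll = np.asarray(logliks, dtype=float)
    if ll.size == 0:
        raise ValueError("compute_mapq requires at least one candidate")
    if keys is None:
        keys = list(range(ll.size))
    best = 0
    for i in range(1, ll.size):
        if ll[i] > ll[best] or (ll[i] == ll[best] and keys[i] < keys[best]):
            best = i
    if not np.isfinite(ll[best]) or ll[best] <= _NEG / 2:
        return best, 0.0, 0
    rel = ll - ll[best]
    denom = np.logaddexp.reduce(np.clip(rel, -745.0, 0.0))
    posterior = float(math.exp(-denom))
    one_minus = -math.expm1(-denom)  # 1 - posterior, accurate near 1
    if one_minus <= 10.0 ** (-(mapq_cap + 0.5) / 10.0):
        mapq = mapq_cap
    else:
        mapq = int(math.floor(-10.0 * math.log10(one_minus) + 0.5))
        mapq = min(mapq, mapq_cap)
    return best, posterior, mapq
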