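import itertools
import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnapipe.phmm import (
    ErrorProfile,
    compute_mapq,
    encode_seq,
    forward_loglik,
    viterbi,
)
from tests.conftest import pair_hmm_enumeration_loglik


def fwd(read, win, errs, gap_open=0.0, gap_extend=0.1):
    prof = ErrorProfile(np.asarray(errs, float), gap_open=gap_open,
                        gap_extend=gap_extend)
    lm, lx = prof.log_terms(len(read))
    return forward_loglik(
        encode_seq(read), encode_seq(win), lm, lx, gap_open, gap_extend
    )


class TestForward:
    def test_noiseless_perfect_match_has_probability_one(self):
        assert fwd("ACGTAC", "TTACGTACTT", np.zeros(6)) == pytest.approx(0.0, abs=1e-12)

    def test_gapless_closed_form_single_mismatch(self):
        e = np.full(6, 0.01)
        got = fwd("ACGTAC", "ACCTAC", e)  # mismatch at cycle 3 (1-based)
        want = 5 * math.log(0.99) + math.log(0.01 / 3)
        assert got == pytest.approx(want, abs=1e-12)

    def test_matches_exhaustive_enumeration(self):
        rng = random.Random(42)
        for _ in range(60):
            L = rng.randint(3, 8)
            W = rng.randint(L, 20)
            read = [rng.randrange(4) for _ in range(L)]
            win = [rng.randrange(4) for _ in range(W)]
            errs = tuple(rng.uniform(0.001, 0.2) for _ in range(L))
            go = rng.uniform(0.005, 0.1)
            ge = rng.uniform(0.05, 0.3)
            prof = ErrorProfile(np.array(errs), gap_open=go, gap_extend=ge)
            lm, lx = prof.log_terms(L)
            got = forward_loglik(
                np.array(read, np.uint8), np.array(win, np.uint8), lm, lx, go, ge
            )
            want = pair_hmm_enumeration_loglik(tuple(read), tuple(win), errs, go, ge)
            assert got == pytest.approx(want, abs=1e-9)

    def test_literal_path_enumeration_tiny(self):
        # third, fully literal oracle: generate every op string explicitly
        read, win = (0, 1, 2), (0, 1, 3, 2)
        errs = (0.05, 0.1, 0.02)
        go, ge = 0.08, 0.2
        total = 0.0
        L, W = len(read), len(win)
        for n_ins in range(0, L):
            for n_del in range(0, W + 1):
                n_m = L - n_ins
                if n_m < 1:
                    continue
                cols = n_m + n_ins + n_del
                for ops in itertools.product("MID", repeat=cols):
                    if ops.count("M") != n_m or ops.count("I") != n_ins:
                        continue
                    if ops[0] != "M" or ops[-1] == "D":
                        continue
                    # no direct insertion<->deletion transitions in the model
                    if any(
                        a != b and {a, b} == {"I", "D"} for a, b in zip(ops, ops[1:])
                    ):
                        continue
                    ok = True
                    consumed_g = sum(1 for o in ops if o in "MD")
                    for g0 in range(W - consumed_g + 1):
                        p = 1.0
                        i, g, prev = 0, g0, None
                        for o in ops:
                            if o == "M":
                                t = (
                                    1.0
                                    if prev is None
                                    else {"M": 1 - 2 * go, "I": 1 - ge, "D": 1 - ge}[prev]
                                )
                                em = (
                                    (1 - errs[i])
                                    if read[i] == win[g]
                                    else errs[i] / 3
                                )
                                p *= t * em
                                i += 1
                                g += 1
                            elif o == "I":
                                t = go if prev == "M" else ge
                                p *= t * 0.25
                                i += 1
                            else:
                                t = go if prev == "M" else ge
                                p *= t
                                g += 1
                            prev = o
                        total += p
        got = fwd("ACG", "ACTG", errs, gap_open=go, gap_extend=ge)
        assert got == pytest.approx(math.log(total), abs=1e-9)

    def test_profile_shorter_than_read_raises(self):
        prof = ErrorProfile(np.zeros(3))
        with pytest.raises(ValueError):
            prof.log_terms(5)


class TestViterbi:
    def test_recovers_exact_placement(self):
        prof = ErrorProfile(np.full(6, 0.01), gap_open=0.001)
        lm, lx = prof.log_terms(6)
        _, g0, g1, ops = viterbi(
            encode_seq("ACGTAC"), encode_seq("TTACGTACTT"), lm, lx, 0.001, 0.1
        )
        assert (g0, g1) == (2, 8)
        assert list(ops) == [0] * 6

    def test_deletion_recovered(self):
        # read skips two genome bases in the middle
        prof = ErrorProfile(np.full(8, 0.01), gap_open=0.01)
        lm, lx = prof.log_terms(8)
        read = "ACGTTGCA"
        win = "ACGTGGTGCA"  # read = window minus the middle "GG"
        _, g0, g1, ops = viterbi(
            encode_seq(read), encode_seq(win), lm, lx, 0.01, 0.1
        )
        assert list(ops) == [0, 0, 0, 0, 2, 2, 0, 0, 0, 0]
        assert (g0, g1) == (0, 10)

    def test_ops_consume_read_exactly(self):
        rng = random.Random(3)
        for _ in range(20):
            L = rng.randint(3, 10)
            W = rng.randint(L, 25)
            read = "".join(rng.choice("ACGT") for _ in range(L))
            win = "".join(rng.choice("ACGT") for _ in range(W))
            prof = ErrorProfile(np.full(L, 0.05), gap_open=0.02)
            lm, lx = prof.log_terms(L)
            _, g0, g1, ops = viterbi(
                encode_seq(read), encode_seq(win), lm, lx, 0.02, 0.1
            )
            ops = list(ops)
            assert ops.count(0) + ops.count(1) == L
            assert ops.count(0) + ops.count(2) == g1 - g0


class TestComputeMapq:
    def test_ninety_percent_posterior_is_mapq_ten(self):
        best, post, mapq = compute_mapq([math.log(0.9), math.log(0.1)])
        assert post == pytest.approx(0.9)
        assert mapq == 10

    def test_two_identical_candidates_mapq_three(self):
        best, post, mapq = compute_mapq([-4.2, -4.2], keys=[(("c", 7)), ("c", 3)])
        assert post == pytest.approx(0.5)
        assert mapq == 3
        assert best == 1  # lowest coordinate wins the tie

    def test_single_candidate_capped(self):
        _, post, mapq = compute_mapq([-11.0], mapq_cap=60)
        assert post == 1.0
        assert mapq == 60

    def test_no_candidates_raises(self):
        with pytest.raises(ValueError):
            compute_mapq([])

    @given(
        st.lists(st.floats(min_value=-50, max_value=0), min_size=1, max_size=8),
        st.floats(min_value=-50, max_value=0),
    )
    @settings(max_examples=200, deadline=None)
    def test_extra_candidate_never_increases_best_posterior(self, lls, extra):
        from scipy.special import logsumexp

        best, p1, _ = compute_mapq(lls)
        # posterior of the ORIGINAL best location after adding a competitor
        p_after = math.exp(lls[best] - logsumexp(lls + [extra]))
        assert p_after <= p1 + 1e-12


class TestErrorProfileType:
    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            ErrorProfile(np.array([0.9]))
        with pytest.raises(ValueError):
            ErrorProfile(np.array([0.01]), gap_open=0.4)

    def test_reverse_log_terms_flip_cycles(self):
        prof = ErrorProfile(np.array([0.1, 0.2, 0.3]))
        lm_f, _ = prof.log_terms(3)
        lm_r, _ = prof.log_terms(3, reverse=True)
        assert lm_f[0] == lm_r[2]
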