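import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile(
    "deterministic", derandomize=True, deadline=None, database=None
)
settings.load_profile("deterministic")

from srnapipe.simdata import ReferenceBundle, SimulationConfig, simulate_screen


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A reduced screen: 30 miRNA loci, depth 100, 40 kb genome."""
    return SimulationConfig(
        seed=5,
        n_mirna=30,
        n_contaminant_loci=8,
        genome_length=40_000,
        mean_depth=100.0,
    )


@pytest.fixture(scope="session")
def small_sim(small_config, tmp_path_factory):
    return simulate_screen(small_config, tmp_path_factory.mktemp("sim"))


@pytest.fixture()
def flat_bundle():
    """A degenerate bundle for count-model moment checks: many identical
    features (no genome/annotation needed by draw_counts)."""

    def make(n: int, base_mean: float, log2fc: float = 0.0) -> ReferenceBundle:
        truth = pd.DataFrame(
            {
                "base_mean": np.full(n, base_mean),
                "true_log2FC": np.full(n, log2fc),
                "klass": ["miRNA"] * n,
            },
            index=pd.Index([f"f{i}" for i in range(n)], name="feature_id"),
        )
        ann = pd.DataFrame(
            columns=["contig", "start", "end", "strand", "feature_id", "klass"]
        )
        return ReferenceBundle({}, ann, truth, [])

    return make


def pair_hmm_enumeration_loglik(read, win, errs, gap_open, gap_extend):
    """Independent oracle: exhaustive sum over all alignments of the
    3-state pair HMM, computed in probability space by memoized recursion
    (local in genome, global in read; start in M; end in M or X)."""
    import math
    from functools import lru_cache

    L, W = len(read), len(win)
    t_mm = 1 - 2 * gap_open
    t_em = 1 - gap_extend

    @lru_cache(maxsize=None)
    def rest(i, g, state):
        if i == L:
            return 1.0
        tot = 0.0
        if g < W:
            em = (1 - errs[i]) if read[i] == win[g] else errs[i] / 3
            t = t_mm if state == "M" else t_em
            tot += t * em * rest(i + 1, g + 1, "M")
        if state in ("M", "X"):
            t = gap_open if state == "M" else gap_extend
            tot += t * 0.25 * rest(i + 1, g, "X")
        if g < W and state in ("M", "Y"):
            t = gap_open if state == "M" else gap_extend
            tot += t * rest(i, g + 1, "Y")
        return tot

    total = 0.0
    for g0 in range(W):
        em = (1 - errs[0]) if read[0] == win[g0] else errs[0] / 3
        total += em * rest(1, g0 + 1, "M")
    return math.log(total) if total > 0 else float("-inf")


def conditional_nb_pmf_oracle(s: int, phi: float) -> np.ndarray:
    """Independent oracle for the exact test's conditional law: normalize
    products of scipy NB pmfs over all splits of the total s."""
    from scipy import stats

    x = np.arange(s + 1)
    if phi == 0.0:
        w = stats.poisson.pmf(x, 10.0) * stats.poisson.pmf(s - x, 10.0)
    else:
        r = 1.0 / phi
        m = 10.0  # any mean: the conditional does not depend on it
        p = r / (r + m)
        w = stats.nbinom.pmf(x, r, p) * stats.nbinom.pmf(s - x, r, p)
    return w / w.sum()
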