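"""Exact negative-binomial two-group test without replicates.

Given two libraries (control, test) of per-feature counts, the procedure
is: (1) equalize library sizes by scaling counts to the geometric-mean
library size and rounding ("pseudo-counts"); (2) estimate a single common
dispersion phi by conditional maximum likelihood, treating the two
libraries as replicates of one group (the device for having no biological
replicates — conditioning on each feature's total removes the mean
parameter, and any true fold change inflates phi, making the test
conservative); (3) for each feature, an exact two-sided test conditional
on the feature's total under NB(mean m, dispersion phi) i.i.d. marginals
(phi = 0 reduces to Binomial(s, 1/2)); (4) Benjamini-Hochberg adjustment
and calls at FDR < 5%.

Under the NB model the conditional law of (a | a + b = s) is negative
hypergeometric with shape r = 1/phi on both sides; the two-sided p-value
is the sum of conditional masses not exceeding the observed outcome's
mass (the exact-test convention for this family).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

_TIE_SLACK = 1e-12  # floating-point tie tolerance in the mass-comparison rule


@dataclass
class DispersionEstimate:
    phi: float
    method: str
    n_features_used: int


def equalize_libraries(
    counts: pd.DataFrame, lib_sizes: pd.Series | None = None
) -> tuple[pd.DataFrame, float]:
    """Scale both libraries to the geometric-mean size N* = sqrt(N1*N2).

    pseudo[i, l] = round(count[i, l] * N*/N_l); rounding keeps the exact
    test's integer conditioning. Returns (pseudo counts, N*).
    """
    if counts.shape[1] != 2:
        raise ValueError("equalize_libraries expects exactly two libraries")
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0)
    lib_sizes = lib_sizes.loc[counts.columns].astype(float)
    if (lib_sizes <= 0).any():
        raise ValueError("zero library size")
    n_star = float(np.sqrt(lib_sizes.iloc[0] * lib_sizes.iloc[1]))
    pseudo = counts.astype(float).mul(n_star / lib_sizes, axis=1)
    pseudo = np.floor(pseudo + 0.5).astype(int)
    return pseudo, n_star


def _cond_loglik(y1: np.ndarray, y2: np.ndarray, phi: float) -> float:
    """Summed log P(y1 | y1 + y2) over features, common dispersion phi."""
    s = y1 + y2
    if phi <= 0.0:
        return float(
            np.sum(
                gammaln(s + 1) - gammaln(y1 + 1) - gammaln(y2 + 1) - s * math.log(2.0)
            )
        )
    r = 1.0 / phi
    return float(
        np.sum(
            gammaln(y1 + r)
            - gammaln(y1 + 1)
            + gammaln(y2 + r)
            - gammaln(y2 + 1)
            - 2 * gammaln(r)
            - (gammaln(s + 2 * r) - gammaln(s + 1) - gammaln(2 * r))
        )
    )


def estimate_common_dispersion(
    pseudo: pd.DataFrame,
    phi_max: float = 10.0,
    tol: float = 1e-6,
) -> DispersionEstimate:
    """Pseudo-replicate-pooled conditional ML estimate of the common
    dispersion on [0, phi_max]; features with total 0 are excluded."""
    if pseudo.shape[1] != 2:
        raise ValueError("expected exactly two libraries")
    y = pseudo.to_numpy(dtype=float)
    keep = y.sum(axis=1) > 0
    if not keep.any():
        raise ValueError("all feature totals are zero")
    y1, y2 = y[keep, 0], y[keep, 1]

    res = minimize_scalar(
        lambda phi: -_cond_loglik(y1, y2, phi),
        bounds=(1e-8, phi_max),
        method="bounded",
        options={"xatol": tol},
    )
    phi_hat = float(res.x)
    # the boundary phi = 0 (Poisson) is a valid maximizer
    if _cond_loglik(y1, y2, 0.0) >= -res.fun:
        phi_hat = 0.0
    return DispersionEstimate(
        phi=phi_hat, method="pseudo-replicate-pooled", n_features_used=int(keep.sum())
    )


def _cond_log_pmf(s: int, phi: float) -> np.ndarray:
    """log P(a = x | a + b = s) for x = 0..s under i.i.d. NB marginals."""
    x = np.arange(s + 1, dtype=float)
    if phi <= 0.0:
        return gammaln(s + 1) - gammaln(x + 1) - gammaln(s - x + 1) - s * math.log(2.0)
    r = 1.0 / phi
    lp = (
        gammaln(x + r)
        - gammaln(x + 1)
        + gammaln(s - x + r)
        - gammaln(s - x + 1)
        - 2 * gammaln(r)
        - (gammaln(s + 2 * r) - gammaln(s + 1) - gammaln(2 * r))
    )
    return lp - logsumexp(lp)  # renormalize away rounding in the constant


def exact_test(count_a: int, count_b: int, phi: float) -> float:
    """Two-sided exact p-value for equal means, conditional on the total.

    p = sum of conditional masses over outcomes whose mass is <= the
    observed outcome's mass (with a 1e-12 relative slack for float ties);
    p in (0, 1].
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if phi < 0:
        raise ValueError("dispersion must be >= 0")
    s = int(count_a) + int(count_b)
    if s == 0:
        return 1.0
    lp = _cond_log_pmf(s, phi)
    obs = lp[int(count_a)]
    mask = lp <= obs + math.log1p(_TIE_SLACK)
    return float(min(1.0, math.exp(logsumexp(lp[mask]))))


def adjust_bh(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def classify_calls(qvals, log2fc, fdr: float = 0.05) -> np.ndarray:
    """down/up/ns calls: significant iff q < fdr (strict), signed by log2FC."""
    q = np.asarray(qvals, dtype=float)
    lfc = np.asarray(log2fc, dtype=float)
    return np.where(
        (q < fdr) & (lfc < 0), "down", np.where((q < fdr) & (lfc > 0), "up", "ns")
    )


def run_exact_test(
    counts: pd.DataFrame,
    control: str,
    test: str,
    lib_sizes: pd.Series | None = None,
    fdr: float = 0.05,
    phi: float | None = None,
) -> tuple[pd.DataFrame, DispersionEstimate]:
    """Full differential-expression table for one control/test comparison.

    Features with pseudo-count total 0 are excluded from testing. log2FC =
    log2((pseudo_test + 0.5) / (pseudo_control + 0.5)) (the 0.5 offset is
    reporting-only). call = down/up when q < fdr (strict), else ns. The
    table is sorted by q then feature_id.
    """
    pair = counts[[control, test]]
    sizes = None if lib_sizes is None else lib_sizes[[control, test]]
    pseudo, _ = equalize_libraries(pair, sizes)
    if phi is None:
        disp = estimate_common_dispersion(pseudo)
    else:
        disp = DispersionEstimate(phi=phi, method="fixed", n_features_used=len(pseudo))

    keep = pseudo.sum(axis=1) > 0
    sub = pseudo.loc[keep]
    pvals = np.array(
        [
            exact_test(int(a), int(b), disp.phi)
            for a, b in zip(sub[control], sub[test])
        ]
    )
    qvals = adjust_bh(pvals)
    log2fc = np.log2((sub[test] + 0.5) / (sub[control] + 0.5))
    call = classify_calls(qvals, log2fc, fdr)
    out = pd.DataFrame(
        {
            "feature_id": sub.index,
            "count_control": pair.loc[keep, control].to_numpy(),
            "count_test": pair.loc[keep, test].to_numpy(),
            "pseudo_control": sub[control].to_numpy(),
            "pseudo_test": sub[test].to_numpy(),
            "log2FC": log2fc.to_numpy(),
            "p": pvals,
            "q": qvals,
            "call": call,
        }
    ).sort_values(["q", "feature_id"], kind="stable").reset_index(drop=True)
    return out, disp


def plot_fold_changes(results: pd.DataFrame, path) -> None:
    """Bar plot of per-miRNA log2 fold changes, significant calls starred."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = results.sort_values("log2FC").reset_index(drop=True)
    sig = df["call"] != "ns"
    fig, ax = plt.subplots(figsize=(max(6, len(df) * 0.08), 4))
    ax.bar(np.arange(len(df)), df["log2FC"], color=np.where(sig, "black", "0.6"))
    for i in np.flatnonzero(sig.to_numpy()):
        y = df.loc[i, "log2FC"]
        ax.text(i, y + (0.1 if y >= 0 else -0.25), "*", ha="center", fontsize=8)
    ax.set_ylabel("log2 fold change (test / control)")
    ax.set_xlabel("miRNA (ranked)")
    ax.axhline(0.0, color="k", lw=0.5)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def summarize_calls(results: pd.DataFrame) -> dict[str, int]:
    return {
        "n_tested": len(results),
        "n_down": int((results["call"] == "down").sum()),
        "n_up": int((results["call"] == "up").sum()),
        "n_ns": int((results["call"] == "ns").sum()),
    }
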