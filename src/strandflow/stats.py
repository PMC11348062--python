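"""Statistical comparisons for per-order tables, counts and speeds.

Two-sided throughout.  The chi-square test of independence (no continuity
correction) compares positivity across order bins, followed by pairwise
2x2 comparisons of each order against the leader with Bonferroni
adjustment.  Division counts are compared with the exact conditional
(binomial) test of two Poisson means; speed distributions with the
Mann-Whitney rank test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = [
    "chi2_independence",
    "pairwise_vs_leader",
    "poisson_means_test",
    "mann_whitney",
    "stars",
    "comparison_report",
]


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    return t


def chi2_independence(table):
    """Pearson chi-square test of independence, (r-1)(c-1) df, no
    continuity correction.  Returns (statistic, p_value, dof)."""
    t = _as_table(table)
    res = sps.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue), int(res.dof)


def pairwise_vs_leader(table):
    """2x2 chi-square of every non-leader order against the leader row,
    Bonferroni-adjusted (times the number of comparisons, capped at 1).

    Returns a list of dicts with raw and adjusted p per comparison.
    """
    t = _as_table(table)
    n_cmp = t.shape[0] - 1
    out = []
    for i in range(1, t.shape[0]):
        sub = t[[0, i]]
        if np.all(sub[0] * sub[1].sum() == sub[1] * sub[0].sum()):
            stat, p = 0.0, 1.0      # identical composition
        else:
            res = sps.chi2_contingency(sub, correction=False)
            stat, p = float(res.statistic), float(res.pvalue)
        out.append({
            "row": i, "statistic": stat, "p_raw": p,
            "p_adjusted": min(p * n_cmp, 1.0),
        })
    return out


def poisson_means_test(k1: int, exposure1: float, k2: int,
                       exposure2: float, mid_p: bool = False) -> float:
    """Exact conditional comparison of two Poisson means.

    Given the total k1 + k2, k1 is binomial with success probability
    exposure1 / (exposure1 + exposure2) under the null of equal rates;
    the two-sided p sums the probabilities of all outcomes no more
    probable than the observed one.  ``mid_p`` counts the observed
    outcome's probability at half weight.
    """
    if exposure1 <= 0 or exposure2 <= 0:
        raise ValueError("exposures must be positive")
    if k1 < 0 or k2 < 0:
        raise ValueError("counts must be non-negative")
    n = k1 + k2
    if n == 0:
        return 1.0
    pr = exposure1 / (exposure1 + exposure2)
    pmf = sps.binom.pmf(np.arange(n + 1), n, pr)
    p_obs = pmf[k1]
    tol = 1e-12 * max(p_obs, 1e-300)
    if mid_p:
        p = pmf[pmf < p_obs - tol].sum() + 0.5 * pmf[
            np.abs(pmf - p_obs) <= tol].sum()
    else:
        p = pmf[pmf <= p_obs + tol].sum()
    return float(min(p, 1.0))


def mann_whitney(sample_a, sample_b):
    """Two-sided Mann-Whitney rank test.

    Exact enumeration for small tie-free samples (combined n below 20),
    otherwise the tie-corrected normal approximation.  Returns (U, p).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if a.size + b.size < 20 and not ties:
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="exact")
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def stars(p: float) -> str:
    """Significance stars at the 0.05 / 0.01 / 0.001 / 0.0001 levels."""
    for thresh, mark in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"),
                         (5e-2, "*")):
        if p < thresh:
            return mark
    return "n.s."


def comparison_report(name: str, statistic: float, p_raw: float,
                      n, p_adjusted: float | None = None) -> dict:
    """One JSON-serializable record per comparison."""
    p_final = p_adjusted if p_adjusted is not None else p_raw
    return {
        "test": name, "statistic": statistic, "p_raw": p_raw,
        "p_adjusted": p_adjusted, "n": n, "stars": stars(p_final),
    }
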