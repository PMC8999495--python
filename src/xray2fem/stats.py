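"""Nonparametric comparison suite for per-model stress summaries.

The study design compares stress summaries across the three fracture
grades within a fixation system (Kruskal-Wallis with eta-squared effect
size and Bonferroni-corrected pairwise rank tests) and between the two
systems within a grade (Mann-Whitney U with a Z-score).

Conventions
-----------
* Ranks use midranks for ties throughout.
* Mann-Whitney reports ``U = min(U_a, U_b)``.  The two-tailed p is exact
  (full enumeration of the null rank distribution) when the combined
  sample size is at most 12 and the data are tie-free, otherwise the
  normal approximation with tie-corrected variance and a 0.5 continuity
  correction is used.  The Z-score always comes from the corrected normal
  deviate, signed by the rank-mean comparison (positive when the first
  sample ranks higher).
* Kruskal-Wallis H carries the standard tie correction; p is the
  chi-square tail with k-1 degrees of freedom; the effect size is
  ``eta^2 = (H - k + 1) / (n - k)``, floored at zero.
* Pairwise comparisons are Mann-Whitney tests flagged significant at the
  Bonferroni-adjusted level ``alpha / n_pairs``.
* Shapiro-Wilk normality is delegated to :func:`scipy.stats.shapiro`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import chi2, norm, rankdata, shapiro

__all__ = [
    "MannWhitneyResult",
    "KruskalWallisResult",
    "PairwiseResult",
    "mann_whitney_u",
    "kruskal_wallis",
    "pairwise_bonferroni",
    "normality_check",
]

EXACT_MAX_N = 12  # combined size up to which the exact null is enumerated


@dataclass(frozen=True)
class MannWhitneyResult:
    U: float  # min(U_a, U_b)
    U_a: float
    U_b: float
    z: float
    p: float
    method: str  # "exact" | "normal"
    n_a: int
    n_b: int


@dataclass(frozen=True)
class KruskalWallisResult:
    H: float
    df: int
    p: float
    eta_squared: float
    n: int
    k: int


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple
    U: float
    p: float
    threshold: float
    significant: bool


def _tie_term(all_values: np.ndarray) -> float:
    """sum(t^3 - t) over tie groups."""
    _, counts = np.unique(all_values, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def _exact_u_distribution(n_a: int, n_b: int) -> np.ndarray:
    """Null counts of U_a over all C(n_a+n_b, n_a) rank labelings.

    Dynamic programme over the number of group-a elements and the running
    U value; equivalent to brute-force enumeration but O(n_a n_b^2).
    """
    n = n_a + n_b
    max_u = n_a * n_b
    # counts[j, u]: arrangements of the first i ranks with j in group a and U=u
    counts = np.zeros((n_a + 1, max_u + 1), dtype=float)
    counts[0, 0] = 1.0
    for i in range(1, n + 1):
        new = np.zeros_like(counts)
        for j in range(min(i, n_a) + 1):
            # rank i goes to group b: U gains nothing
            new[j] += counts[j]
            # rank i goes to group a: beats the (i-1) - (j-1) b's before it
            if j >= 1:
                gain = (i - 1) - (j - 1)
                if gain <= max_u:
                    new[j, gain:] += counts[j - 1, : max_u + 1 - gain]
        counts = new
    return counts[n_a]


def mann_whitney_u(
    sample_a, sample_b, method: str = "auto"
) -> MannWhitneyResult:
    """Two-sample Mann-Whitney U test, two-tailed.

    method: "auto" (exact when tie-free and n_a+n_b <= 12), "exact",
    "normal".
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    R_a = ranks[:n_a].sum()
    U_a = R_a - n_a * (n_a + 1) / 2
    U_b = n_a * n_b - U_a
    U = min(U_a, U_b)

    has_ties = np.unique(pooled).size < pooled.size
    if method == "auto":
        method = "exact" if (not has_ties and n_a + n_b <= EXACT_MAX_N) else "normal"
    if method == "exact" and has_ties:
        raise ValueError("exact enumeration assumes tie-free data")

    # normal deviate with tie-corrected variance and continuity correction;
    # always reported as the Z-score, signed by the rank-mean comparison
    n = n_a + n_b
    mu = n_a * n_b / 2
    var = n_a * n_b / 12 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
    d = U_a - mu
    if var <= 0 or abs(d) <= 0.5:
        z = 0.0
    else:
        z = np.sign(d) * (abs(d) - 0.5) / np.sqrt(var)

    if method == "exact":
        dist = _exact_u_distribution(n_a, n_b)
        total = comb(n_a + n_b, n_a)
        lo = dist[: int(U) + 1].sum()  # P(U_a <= U)
        hi = dist[int(np.ceil(n_a * n_b - U)) :].sum()  # P(U_a >= n_a n_b - U)
        p = min(1.0, (lo + hi) / total)
    else:
        p = min(1.0, 2 * norm.sf(abs(z))) if var > 0 else 1.0

    return MannWhitneyResult(
        U=float(U), U_a=float(U_a), U_b=float(U_b), z=float(z), p=float(p),
        method=method, n_a=n_a, n_b=n_b,
    )


def kruskal_wallis(groups) -> KruskalWallisResult:
    """Kruskal-Wallis rank test over k independent samples."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    k = len(groups)
    sizes = np.array([g.size for g in groups])
    n = int(sizes.sum())
    pooled = np.concatenate(groups)
    ranks = rankdata(pooled)

    H = 0.0
    start = 0
    for g, sz in zip(groups, sizes):
        R = ranks[start : start + sz].sum()
        H += R * R / sz
        start += sz
    H = 12 / (n * (n + 1)) * H - 3 * (n + 1)

    correction = 1 - _tie_term(pooled) / (n**3 - n)
    if correction <= 0:  # all observations identical
        H, p = 0.0, 1.0
    else:
        H = H / correction
        p = float(chi2.sf(H, k - 1))

    eta2 = max(0.0, (H - k + 1) / (n - k)) if n > k else 0.0
    return KruskalWallisResult(H=float(H), df=k - 1, p=p, eta_squared=eta2, n=n, k=k)


def pairwise_bonferroni(
    groups, labels=None, alpha: float = 0.05, method: str = "auto"
) -> list[PairwiseResult]:
    """All unordered pairwise Mann-Whitney tests, Bonferroni-adjusted.

    A pair is flagged significant when its raw two-tailed p is at or below
    ``alpha / n_pairs``.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    labels = list(labels) if labels is not None else list(range(len(groups)))
    pairs = list(combinations(range(len(groups)), 2))
    threshold = alpha / len(pairs)
    out = []
    for i, j in pairs:
        res = mann_whitney_u(groups[i], groups[j], method=method)
        out.append(
            PairwiseResult(
                pair=(labels[i], labels[j]),
                U=res.U,
                p=res.p,
                threshold=threshold,
                significant=res.p <= threshold,
            )
        )
    return out


def normality_check(sample) -> tuple[float, float]:
    """Shapiro-Wilk W and p for 3 <= n <= 5000."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 observations")
    if x.size > 5000:
        raise ValueError("Shapiro-Wilk is unreliable above n = 5000")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance sample: W is undefined")
    w, p = shapiro(x)
    return float(w), float(p)
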