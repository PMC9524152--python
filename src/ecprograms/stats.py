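"""Statistical primitives used throughout the pipeline.

Every test here is small enough to verify against brute-force enumeration:
the two-sided hypergeometric overlap test (gene-set overlaps), the
Mann-Whitney U test (patient-level comparisons), the Wilcoxon signed-rank
test (paired panel scores), and Benjamini-Hochberg / Bonferroni adjustment.

Conventions
-----------
* Two-sided hypergeometric p = min(1, 2 * min(lower tail, upper tail)).
* Mann-Whitney U uses midranks; exact two-sided p by enumeration of all
  group labelings when the pooled sample size is <= 12 and there are no
  ties, otherwise a normal approximation with tie-corrected variance and
  continuity correction.
* Wilcoxon signed-rank drops zero differences; exact enumeration of all
  sign assignments for <= 12 nonzero pairs, otherwise normal approximation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "AdjustedPValues",
    "hypergeometric_overlap_test",
    "hypergeom_two_sided_p",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "adjust_pvalues",
]

MWU_EXACT_POOLED_N = 12
WILCOXON_EXACT_PAIRS = 12


@dataclass
class TestResult:
    """Outcome of a single hypothesis test."""

    statistic: float
    p_value: float
    method: str
    n1: int
    n2: int
    #: set when a degenerate input forced a conventional p-value (e.g. all
    #: paired differences zero, or zero rank variance under complete ties)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


@dataclass
class AdjustedPValues:
    """Raw and multiplicity-adjusted p-values for one family of tests."""

    raw: np.ndarray
    adjusted: np.ndarray
    procedure: str
    fdr_level: float = 0.1

    @property
    def significant(self) -> np.ndarray:
        """Rejections at ``fdr_level`` (BH) or ``fdr_level`` (Bonferroni)."""
        return self.adjusted <= self.fdr_level


def hypergeometric_overlap_test(set_a, set_b, universe) -> TestResult:
    """Two-sided hypergeometric test for the overlap of two gene sets.

    With ``N = |universe|``, ``K = |set_a|``, ``n = |set_b|`` and observed
    overlap ``k``, the two-sided p-value doubles the smaller tail of
    Hypergeom(N, K, n) at k and caps at 1.
    """
    universe = {str(g).upper() for g in universe}
    if not universe:
        raise ValueError("universe is empty")
    a = {str(g).upper() for g in set_a}
    b = {str(g).upper() for g in set_b}
    if not a or not b:
        raise ValueError("gene sets must be nonempty")
    for name, s in (("set_a", a), ("set_b", b)):
        missing = s - universe
        if missing:
            raise ValueError(
                f"{name} contains genes absent from the universe: "
                f"{sorted(missing)[:5]}"
            )
    N, K, n = len(universe), len(a), len(b)
    k = len(a & b)
    p = hypergeom_two_sided_p(N, K, n, k)
    return TestResult(float(k), float(p), "hypergeometric_two_sided", K, n)


def hypergeom_two_sided_p(N, K, n, k):
    """Two-sided hypergeometric p for counts (vectorizable over arrays)."""
    lower = sps.hypergeom.cdf(k, N, K, n)
    upper = sps.hypergeom.sf(np.asarray(k) - 1, N, K, n)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def _mwu_u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for the first sample, with midrank tie handling."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact enumeration of all ``C(n1+n2, n1)`` group labelings when the
    pooled size is at most 12 and the data are tie-free; otherwise a
    normal approximation with tie-corrected variance and continuity
    correction. Complete ties (zero rank variance) return p = 1.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be nonempty")
    u = _mwu_u_statistic(x, y)
    pooled = np.concatenate([x, y])
    n = n1 + n2
    has_ties = len(np.unique(pooled)) < n
    mean_u = n1 * n2 / 2.0

    if n <= MWU_EXACT_POOLED_N and not has_ties:
        ranks = sps.rankdata(pooled)
        dev = abs(u - mean_u)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), n1):
            r1 = ranks[list(combo)].sum()
            u_perm = r1 - n1 * (n1 + 1) / 2.0
            if abs(u_perm - mean_u) >= dev - 1e-12:
                count += 1
            total += 1
        return TestResult(u, count / total, "mann_whitney_u_two_sided", n1, n2)

    # tie-corrected normal approximation
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        return TestResult(u, 1.0, "mann_whitney_u_two_sided", n1, n2, degenerate=True)
    # continuity correction toward the mean
    z = (u - mean_u - 0.5 * np.sign(u - mean_u)) / np.sqrt(var_u) if u != mean_u else 0.0
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(u, p, "mann_whitney_u_two_sided", n1, n2)


def wilcoxon_signed_rank(before, after) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on index-paired samples.

    Differences ``after - before`` equal to zero are dropped (Wilcoxon's
    convention); if all differences are zero the test is degenerate and
    returns p = 1 with ``degenerate=True``.
    """
    before = np.asarray(before, dtype=float).ravel()
    after = np.asarray(after, dtype=float).ravel()
    if len(before) != len(after):
        raise ValueError(f"length mismatch: {len(before)} vs {len(after)}")
    if len(before) == 0:
        raise ValueError("paired samples must be nonempty")
    d = after - before
    d = d[d != 0]
    m = len(d)
    n_pairs = len(before)
    if m == 0:
        warnings.warn("all paired differences are zero; returning p = 1")
        return TestResult(
            0.0, 1.0, "wilcoxon_signed_rank_two_sided", n_pairs, n_pairs, degenerate=True
        )
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    if m <= WILCOXON_EXACT_PAIRS:
        # enumerate all 2^m sign assignments on the observed (mid)ranks
        lower = upper = 0
        n_assign = 2**m
        for bits in range(n_assign):
            w = 0.0
            for i in range(m):
                if bits >> i & 1:
                    w += ranks[i]
            if w <= w_plus + 1e-12:
                lower += 1
            if w >= w_plus - 1e-12:
                upper += 1
        p = min(1.0, 2.0 * min(lower, upper) / n_assign)
        return TestResult(w_plus, p, "wilcoxon_signed_rank_two_sided", n_pairs, n_pairs)

    mean_w = ranks.sum() / 2.0
    var_w = float((ranks**2).sum()) / 4.0
    if var_w <= 0:  # pragma: no cover - m>0 implies positive ranks
        return TestResult(w_plus, 1.0, "wilcoxon_signed_rank_two_sided", n_pairs, n_pairs, True)
    z = (w_plus - mean_w - 0.5 * np.sign(w_plus - mean_w)) / np.sqrt(var_w) if w_plus != mean_w else 0.0
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(w_plus, p, "wilcoxon_signed_rank_two_sided", n_pairs, n_pairs)


def adjust_pvalues(raw, procedure: str = "benjamini_hochberg", fdr_level: float = 0.1) -> AdjustedPValues:
    """Multiple-testing adjustment.

    ``benjamini_hochberg``: step-up adjusted values ``min_{j>=i} p_(j) m/j``
    capped at 1. ``bonferroni``: ``min(1, m p)``.
    """
    raw = np.asarray(raw, dtype=float).ravel()
    if raw.size and (raw.min() < 0 or raw.max() > 1):
        raise ValueError("raw p-values must lie in [0, 1]")
    m = len(raw)
    if procedure == "bonferroni":
        adjusted = np.minimum(1.0, m * raw)
    elif procedure == "benjamini_hochberg":
        order = np.argsort(raw, kind="mergesort")
        ranked = raw[order] * m / np.arange(1, m + 1)
        # step-up: running minimum from the largest rank downwards
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        adjusted = np.empty(m)
        adjusted[order] = np.minimum(1.0, ranked)
    else:
        raise ValueError(f"unknown procedure {procedure!r}")
    return AdjustedPValues(raw, adjusted, procedure, fdr_level)
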