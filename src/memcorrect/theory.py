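"""Closed-form statistics of exact regions (MEMs) in noisy reads.

An *exact region* is a maximal run of error-free bases in a read of length
``n`` with i.i.d. per-base error rate ``p``. All error types are treated as
substitutions here — with insertions or deletions present the true exact
regions are slightly longer than these formulas predict, so the closed forms
are conservative (they underestimate MEM sizes and coverage).

These quantities drive two decisions in the corrector: the minimum seed
length ``l`` (via the probability that a read still contains a seed of that
size) and the plausibility filter on local mappings (via the expected
fraction of a read covered by exact regions of size >= l).
"""

from __future__ import annotations

import math


def _check_p(p: float) -> None:
    if not 0.0 < p < 1.0:
        raise ValueError(f"error rate p must be in (0,1), got {p}")


def coverage_term(k: int, p: float) -> float:
    """Expected fraction of a read covered by exact regions of size exactly k.

    The product of the per-region coverage k/n, the expected region count np,
    and the geometric size probability (1-p)^k p; the read length cancels.
    """
    _check_p(p)
    if k < 0:
        raise ValueError("k must be >= 0")
    return k * (1.0 - p) ** k * p * p


def expected_coverage(p: float, m: int) -> float:
    """Expected fraction of read bases inside exact regions of size >= m.

    Computed by the finite complement form (1-p) - sum_{k<m} k(1-p)^k p^2;
    equals 1-p for m in {0,1} since every correct base lies in a region of
    size >= 1.
    """
    _check_p(p)
    if m < 0:
        raise ValueError("m must be >= 0")
    return (1.0 - p) - sum(coverage_term(k, p) for k in range(m))


def longest_exact_region(n: int, p: float) -> float:
    """Expected length of the longest exact region in a read of length n.

    The root of np(1-p)^m = 1, i.e. -log_{1-p}(np); only meaningful when at
    least one error-free region is expected (np > 1).
    """
    _check_p(p)
    if n * p <= 1:
        raise ValueError("longest-region approximation requires np > 1")
    return -math.log(n * p) / math.log(1.0 - p)


def prob_exact_region(n: int, p: float, m: int) -> float:
    """Probability that a read of length n has an exact region of size >= m.

    Gumbel tail approximation around the expected longest region:
    1 - exp(-np(1-p)^(m+1)). Accurate for large n and p.
    """
    _check_p(p)
    if m < 0:
        raise ValueError("m must be >= 0")
    return 1.0 - math.exp(-n * p * (1.0 - p) ** (m + 1))


def prob_two_regions(n: int, p: float, m: int) -> float:
    """A priori probability of at least two exact regions of size > m.

    A seed of size >= m splits the read at a uniformly distributed point n';
    averaging the conditional two-sided probability Q over n' in {0..n/2}
    (doubled by symmetry) gives the estimate. Increasingly rough as n shrinks.
    """
    _check_p(p)
    total = 0.0
    for n_prime in range(0, n // 2 + 1):
        p_left = prob_exact_region(n_prime, p, m) if n_prime > 0 else 0.0
        p_right = prob_exact_region(n - n_prime, p, m) if n - n_prime > 0 else 0.0
        total += 1.0 - (1.0 - p_left) * (1.0 - p_right)
    return min(1.0, 2.0 * total / n)


def recommend_seed_length(n: int, p: float, target_prob: float) -> int:
    """Largest m such that a read of length n still has a seed of size >= m
    with probability at least target_prob; 0 if no m qualifies."""
    if not 0.0 < target_prob < 1.0:
        raise ValueError("target_prob must be in (0,1)")
    _check_p(p)
    if prob_exact_region(n, p, 0) < target_prob:
        return 0
    lo, hi = 0, n
    while lo < hi:  # invariant: P(lo) >= target, P(hi+1..) unknown/failing
        mid = (lo + hi + 1) // 2
        if prob_exact_region(n, p, mid) >= target_prob:
            lo = mid
        else:
            hi = mid - 1
    return lo


def theory_table(n: int, p: float, m_values: list[int]) -> list[dict]:
    """Tabulate expected coverage and seed probability over m for one (n, p)."""
    return [
        {
            "m": m,
            "expected_coverage": expected_coverage(p, m),
            "prob_exact_region": prob_exact_region(n, p, m),
        }
        for m in m_values
    ]
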