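"""Tie-aware Mann–Whitney U and exact Wilcoxon signed-rank tests.

Both tests are implemented from first principles so the inferential core of
the pipeline depends on no statistics library.

Mann–Whitney: U1 counts, over all (a, b) cross-group pairs, the pairs with
a > b plus half the ties; U2 = n1*n2 - U1.  The reported statistic is
Umin = min(U1, U2).  The normal approximation standardises Umin with the
tie-corrected variance

    Var(U) = (n1*n2 / 12) * [(n + 1) - sum(t^3 - t) / (n * (n - 1))]

where n = n1 + n2 and t ranges over tie-group sizes in the pooled sample.
No continuity correction is applied.

Wilcoxon signed-rank: zero differences are dropped (Wilcoxon's original
treatment), the absolute differences are midranked, and S = min(W+, W-).
For small samples the two-sided p-value is exact: all 2^n equally likely
sign assignments are enumerated (via the generating function of the
rank-sum distribution, which is an exact, lossless form of that
enumeration) and p = Pr(min(W+, W-) <= observed S).  Above the cutoff a
tie-corrected normal approximation is used and labelled as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

__all__ = [
    "MannWhitneyResult", "SignedRankResult",
    "rank_with_ties", "mann_whitney", "signed_rank_exact",
]


def _check_finite(values: Sequence[float], what: str) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{what} contains a non-finite value: {v!r}")


def rank_with_ties(values: Sequence[float]) -> list[float]:
    """Midranks 1..n; tied values share the mean of the ranks they span."""
    if len(values) == 0:
        raise ValueError("cannot rank an empty list")
    _check_finite(values, "rank input")
    n = len(values)
    order = sorted(range(n), key=lambda i: values[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and values[order[j + 1]] == values[order[i]]:
            j += 1
        midrank = (i + j + 2) / 2  # mean of 1-based ranks i+1 .. j+1
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        i = j + 1
    return ranks


def _tie_group_sizes(values: Sequence[float]) -> list[int]:
    counts: dict[float, int] = {}
    for v in values:
        counts[v] = counts.get(v, 0) + 1
    return [c for _, c in sorted(counts.items()) if c > 1]


def _normal_sf(z: float) -> float:
    """Upper tail of the standard normal, via the complementary error function."""
    return 0.5 * math.erfc(z / math.sqrt(2.0))


@dataclass(frozen=True)
class MannWhitneyResult:
    u1: float
    u2: float
    u_min: float
    z: float
    p_two_sided: float
    n1: int
    n2: int
    tie_groups: tuple[int, ...] = field(default_factory=tuple)

    def as_dict(self) -> dict:
        return {
            "test": "mann_whitney_u",
            "u1": self.u1, "u2": self.u2, "u_min": self.u_min,
            "z": self.z, "p_two_sided": self.p_two_sided,
            "n1": self.n1, "n2": self.n2,
            "tie_groups": list(self.tie_groups),
        }


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test of *group_a* versus *group_b*."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    _check_finite(group_a, "group_a")
    _check_finite(group_b, "group_b")
    n1, n2 = len(group_a), len(group_b)
    # Rank-sum form; identical to the all-pairs count but O(n log n).
    pooled = list(group_a) + list(group_b)
    ranks = rank_with_ties(pooled)
    r1 = sum(ranks[:n1])
    u1 = r1 - n1 * (n1 + 1) / 2
    u2 = n1 * n2 - u1
    u_min = min(u1, u2)

    n = n1 + n2
    ties = _tie_group_sizes(pooled)
    if n > 1:
        tie_term = sum(t**3 - t for t in ties) / (n * (n - 1))
        var_u = (n1 * n2 / 12) * ((n + 1) - tie_term)
    else:
        var_u = 0.0
    mean_u = n1 * n2 / 2
    if var_u <= 0:
        z = 0.0
        p = 1.0
    else:
        z = (u_min - mean_u) / math.sqrt(var_u)
        p = min(1.0, 2.0 * _normal_sf(abs(z)))
    return MannWhitneyResult(u1, u2, u_min, z, p, n1, n2, tuple(ties))


@dataclass(frozen=True)
class SignedRankResult:
    w_plus: float
    w_minus: float
    s: float
    n_used: int
    p_two_sided: float
    method: str
    n_zero_dropped: int = 0

    def as_dict(self) -> dict:
        return {
            "test": "wilcoxon_signed_rank",
            "w_plus": self.w_plus, "w_minus": self.w_minus, "s": self.s,
            "n_used": self.n_used, "p_two_sided": self.p_two_sided,
            "method": self.method, "n_zero_dropped": self.n_zero_dropped,
        }


def _exact_min_tail_p(doubled_ranks: list[int], doubled_s: int) -> float:
    """Pr(min(W+, W-) <= s) over all 2^n sign assignments.

    *doubled_ranks* are the midranks times two (integers even with .5 ties);
    *doubled_s* is the observed statistic on the same scale.  The count of
    assignments with each W+ value is the coefficient vector of
    prod_i (1 + x^{r_i}), computed by dynamic programming — an exact,
    lossless encoding of full sign enumeration.
    """
    total = sum(doubled_ranks)
    counts = [0] * (total + 1)
    counts[0] = 1
    for r in doubled_ranks:
        for s in range(total, r - 1, -1):
            counts[s] += counts[s - r]
    n_assign = 1 << len(doubled_ranks)
    lo = sum(c for s, c in enumerate(counts) if s <= doubled_s)
    hi = sum(c for s, c in enumerate(counts) if s >= total - doubled_s)
    both = 0
    if total - doubled_s <= doubled_s:  # the two tail regions overlap
        both = sum(c for s, c in enumerate(counts)
                   if total - doubled_s <= s <= doubled_s)
    return (lo + hi - both) / n_assign


def signed_rank_exact(differences: Sequence[float], exact_cutoff: int = 20) -> SignedRankResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Exact enumeration for up to *exact_cutoff* nonzero differences; a
    tie-corrected normal approximation (no continuity correction) beyond.
    """
    if len(differences) == 0:
        raise ValueError("difference list is empty")
    _check_finite(differences, "differences")
    nonzero = [d for d in differences if d != 0.0]
    n_dropped = len(differences) - len(nonzero)
    if not nonzero:
        raise ValueError("no informative pairs: all differences are zero")
    n = len(nonzero)
    abs_ranks = rank_with_ties([abs(d) for d in nonzero])
    w_plus = sum(r for d, r in zip(nonzero, abs_ranks) if d > 0)
    w_minus = sum(r for d, r in zip(nonzero, abs_ranks) if d < 0)
    s = min(w_plus, w_minus)

    if n <= exact_cutoff:
        doubled = [round(2 * r) for r in abs_ranks]
        p = _exact_min_tail_p(doubled, round(2 * s))
        method = "exact_enumeration"
    else:
        mean_w = n * (n + 1) / 4
        ties = _tie_group_sizes([abs(d) for d in nonzero])
        var_w = n * (n + 1) * (2 * n + 1) / 24 - sum(t**3 - t for t in ties) / 48
        if var_w <= 0:
            p = 1.0
        else:
            z = (s - mean_w) / math.sqrt(var_w)
            p = min(1.0, 2.0 * _normal_sf(abs(z)))
        method = "normal_approximation"
    return SignedRankResult(w_plus, w_minus, s, n, p, method, n_dropped)
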