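"""Rank and count statistics used throughout the pipeline.

The Kruskal–Wallis H statistic is computed from midranks without tie
correction by default, because that is the form whose values are quoted in
the accompanying field study; tie correction is available and documented.
p-values come from the chi-square upper tail (the usual large-sample
approximation) or, for small two-group problems, from exhaustive
permutation of the group assignment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import special
from scipy.stats import rankdata

from .errors import InsufficientDataError

__all__ = [
    "RankTestResult",
    "DescriptiveStats",
    "kruskal_wallis",
    "chi2_sf",
    "percent_change",
    "describe",
]

# exhaustive permutation is refused above this many distinct assignments
_MAX_EXACT_ASSIGNMENTS = 500_000


@dataclass(frozen=True)
class RankTestResult:
    """Outcome of a Kruskal–Wallis rank test."""

    H: float
    df: int
    p: float
    group_ns: tuple[int, ...]
    tie_corrected: bool
    p_method: str = "chi2"

    def to_record(self) -> dict:
        """One-row tidy record (statistic, df, p, method, options)."""
        return {
            "statistic": self.H,
            "df": self.df,
            "p": self.p,
            "method": "kruskal_wallis",
            "tie_corrected": self.tie_corrected,
            "p_method": self.p_method,
            "group_ns": "/".join(str(n) for n in self.group_ns),
        }


@dataclass(frozen=True)
class DescriptiveStats:
    mean: float
    sd: float | None
    n: int


def _h_from_ranks(ranks: np.ndarray, sizes: Sequence[int]) -> float:
    """H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1) over the given group split."""
    N = ranks.size
    h = 0.0
    start = 0
    for n in sizes:
        h += ranks[start : start + n].sum() ** 2 / n
        start += n
    return 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)


def _tie_factor(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    N = pooled.size
    return 1.0 - (counts**3 - counts).sum() / (N**3 - N)


def kruskal_wallis(
    groups: Sequence[Iterable[float]],
    tie_correction: bool = False,
    p_method: str = "chi2",
    rank_method: str = "average",
) -> RankTestResult:
    """Kruskal–Wallis rank test across two or more groups.

    Parameters
    ----------
    groups
        Two or more non-empty collections of real values.
    tie_correction
        Divide H by ``1 - sum(t^3 - t)/(N^3 - N)`` over tie-group sizes t.
        Off by default (the uncorrected statistic is the one the field
        study reports).
    p_method
        ``"chi2"`` (default): upper tail of chi-square with ``k-1`` df.
        ``"permutation"``: exhaustive enumeration of all distinct
        assignments of the pooled ranks to groups; exact, available only
        when the assignment count is modest.
    rank_method
        Passed to :func:`scipy.stats.rankdata`; ``"average"`` gives
        midranks, ``"ordinal"`` breaks ties by input order (some desktop
        statistics packages rank this way inside permutation tests).
    """
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for i, a in enumerate(arrays):
        if a.size == 0:
            raise ValueError(f"group {i} is empty")
    sizes = tuple(a.size for a in arrays)
    N = sum(sizes)
    if N < 3:
        raise InsufficientDataError("need a total of at least 3 observations")

    pooled = np.concatenate(arrays)
    ranks = rankdata(pooled, method=rank_method)
    H = _h_from_ranks(ranks, sizes)
    if tie_correction:
        corr = _tie_factor(pooled)
        if corr <= 0:  # all values identical
            return RankTestResult(0.0, len(sizes) - 1, 1.0, sizes, True, p_method)
        H /= corr
    H = max(H, 0.0)
    df = len(sizes) - 1

    if p_method == "chi2":
        p = chi2_sf(H, df)
    elif p_method == "permutation":
        p = _permutation_p(ranks, sizes, H, tie_correction, pooled)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    return RankTestResult(float(H), df, float(p), sizes, tie_correction, p_method)


def _permutation_p(
    ranks: np.ndarray,
    sizes: tuple[int, ...],
    h_obs: float,
    tie_correction: bool,
    pooled: np.ndarray,
) -> float:
    """Exact p: fraction of rank assignments with H >= observed H.

    Enumerates every distinct split of the pooled ranks into groups of the
    given sizes (multinomial coefficient many). The tie-correction factor
    is a constant across permutations, so it cancels from the comparison.
    """
    n_assign = math.factorial(sum(sizes))
    for n in sizes:
        n_assign //= math.factorial(n)
    if n_assign > _MAX_EXACT_ASSIGNMENTS:
        raise ValueError(
            f"{n_assign} assignments exceed the exhaustive-permutation limit; "
            "use p_method='chi2'"
        )
    corr = _tie_factor(pooled) if tie_correction else 1.0
    h_ref = h_obs * corr  # compare on the uncorrected scale

    N = ranks.size
    count = 0
    total = 0
    for split in _assignments(tuple(range(N)), sizes):
        h = _h_from_ranks(ranks[np.fromiter(split, int, N)], sizes)
        total += 1
        if h >= h_ref - 1e-9:
            count += 1
    return count / total


def _assignments(indices: tuple[int, ...], sizes: Sequence[int]):
    """Yield index orderings realizing every distinct group split."""
    if len(sizes) == 1:
        yield indices
        return
    first, rest = sizes[0], sizes[1:]
    for chosen in itertools.combinations(indices, first):
        chosen_set = set(chosen)
        remaining = tuple(i for i in indices if i not in chosen_set)
        for tail in _assignments(remaining, rest):
            yield chosen + tail


def chi2_sf(x: float, df: int) -> float:
    """Upper-tail probability of the chi-square distribution.

    Computed as the regularized upper incomplete gamma Q(df/2, x/2).
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if x < 0:
        raise ValueError("x must be >= 0")
    return float(special.chdtrc(df, x))


def percent_change(before: float, after: float) -> int:
    """Relative decrease from *before* to *after*, nearest integer percent."""
    if before <= 0:
        raise ValueError("'before' must be positive")
    return round(100.0 * (before - after) / before)


def describe(values: Iterable[float]) -> DescriptiveStats:
    """Arithmetic mean and sample SD (n-1 denominator); SD is None at n=1."""
    a = np.asarray(list(values), dtype=float)
    if a.size == 0:
        raise ValueError("empty input")
    sd = float(np.std(a, ddof=1)) if a.size > 1 else None
    return DescriptiveStats(float(np.mean(a)), sd, int(a.size))
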