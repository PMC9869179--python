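"""Overlap profiles, consensus-signature derivation, and rank-sum testing.

The expected overlap under independence for a membership pattern P over
sets S_1..S_L within a universe of size N is::

    N * prod_{i in P} (|S_i| / N) * prod_{j not in P} (1 - |S_j| / N)

which is the minimal independence null; the real sampling scheme of the
source data is unknown, so this is a documented modeling choice, not an
inference about it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.stats

from .types import SignatureSet

logger = logging.getLogger(__name__)

__all__ = [
    "OverlapProfile",
    "RankSumResult",
    "overlap_profile",
    "derive_consensus",
    "ranksum_test",
    "compare_tss_distance",
]

EXACT_MAX_N = 12  # exact rank-sum enumeration only for small untied samples


@dataclass
class OverlapProfile:
    """Observed vs expected gene counts per exact set-membership pattern."""

    observed: dict[frozenset, int]
    expected: dict[frozenset, float]
    universe_size: int
    set_names: tuple[str, ...]

    def deviation(self, pattern: frozenset) -> float:
        return self.observed.get(pattern, 0) - self.expected[pattern]

    def by_cardinality(self) -> dict[int, tuple[int, float]]:
        """Aggregate (observed, expected) over patterns of equal size."""
        out: dict[int, tuple[int, float]] = {}
        for pattern, exp in self.expected.items():
            m = len(pattern)
            obs, e = out.get(m, (0, 0.0))
            out[m] = (obs + self.observed.get(pattern, 0), e + exp)
        return out


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann-Whitney U of the first sample
    p_value: float
    method: str  # "exact" or "normal_approx"


def overlap_profile(
    sets: Mapping[str, set], universe: set
) -> OverlapProfile:
    """Count genes per exact membership pattern, with independence expectations.

    The observed counts over non-empty patterns sum to the union size; the
    expected counts over all 2^L patterns (including the empty pattern) sum
    to the universe size exactly.
    """
    names = tuple(sets.keys())
    for name in names:
        if not sets[name] <= universe:
            extra = sorted(sets[name] - universe)[:5]
            raise ValueError(f"set {name!r} not contained in universe (e.g. {extra})")
    n_universe = len(universe)

    observed: dict[frozenset, int] = {}
    for g in set().union(*sets.values()) if sets else set():
        pattern = frozenset(name for name in names if g in sets[name])
        observed[pattern] = observed.get(pattern, 0) + 1

    probs = {name: len(sets[name]) / n_universe for name in names}
    expected: dict[frozenset, float] = {}
    for bits in range(2 ** len(names)):
        pattern = frozenset(n for i, n in enumerate(names) if bits >> i & 1)
        e = float(n_universe)
        for name in names:
            e *= probs[name] if name in pattern else (1.0 - probs[name])
        expected[pattern] = e
    return OverlapProfile(observed, expected, n_universe, names)


def derive_consensus(
    sets: Mapping[str, set], min_lines: int | None = None
) -> SignatureSet:
    """Genes present in at least ``min_lines`` of the per-line sets.

    Defaults to requiring membership in every set.  The result is ordered
    lexicographically and carries per-line provenance flags.
    """
    names = list(sets.keys())
    if min_lines is None:
        min_lines = len(names)
    if not (1 <= min_lines <= len(names)):
        raise ValueError(
            f"min_lines must lie in [1, {len(names)}], got {min_lines}"
        )
    counts: dict[str, int] = {}
    for s in sets.values():
        for g in s:
            counts[g] = counts.get(g, 0) + 1
    genes = tuple(sorted(g for g, c in counts.items() if c >= min_lines))
    provenance = {g: {name: g in sets[name] for name in names} for g in genes}
    logger.info(
        "derive_consensus: %d genes present in >= %d of %d sets",
        len(genes), min_lines, len(names),
    )
    return SignatureSet(genes=genes, provenance=provenance)


def ranksum_test(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two_sided",
) -> RankSumResult:
    """Wilcoxon/Mann-Whitney rank-sum test.

    Uses exact enumeration of the permutation null when the pooled sample
    has at most 12 untied observations; otherwise the normal approximation
    with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    alt_map = {"two_sided": "two-sided", "greater": "greater", "less": "less"}
    if alternative not in alt_map:
        raise ValueError(f"alternative must be one of {sorted(alt_map)}")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    if pooled.size <= EXACT_MAX_N and not has_ties:
        method, scipy_method = "exact", "exact"
    else:
        method, scipy_method = "normal_approx", "asymptotic"
    res = scipy.stats.mannwhitneyu(
        x, y, alternative=alt_map[alternative], method=scipy_method,
        use_continuity=True,
    )
    p = float(min(res.pvalue, 1.0))
    return RankSumResult(statistic=float(res.statistic), p_value=p, method=method)


def _as_distances(assignments: Sequence) -> np.ndarray:
    return np.array(
        [a.distance if hasattr(a, "distance") else float(a) for a in assignments],
        dtype=float,
    )


def compare_tss_distance(
    consensus_assignments: Sequence,
    other_assignments: Sequence,
) -> tuple[float, float, RankSumResult]:
    """Median TSS distances plus a one-sided (consensus < other) rank-sum.

    Accepts :class:`~hifmeta.targets.TargetAssignment` lists or bare
    distance lists.
    """
    if len(consensus_assignments) == 0 or len(other_assignments) == 0:
        raise ValueError("both distance lists must be non-empty")
    dist_c = _as_distances(consensus_assignments)
    dist_o = _as_distances(other_assignments)
    med_c = float(np.median(dist_c))
    med_o = float(np.median(dist_o))
    result = ranksum_test(dist_c, dist_o, alternative="less")
    logger.info(
        "compare_tss_distance: consensus median %.1f vs other median %.1f (p=%.3g)",
        med_c, med_o, result.p_value,
    )
    return med_c, med_o, result
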