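"""Resampling and exact-test machinery.

This module is the statistical kernel of the package: rank-sum and exact
contingency tests, size-preserving interval shuffling on a chromosome,
feature-overlap counting, and empirical p-value conventions shared by the
higher-level analyses.

Empirical p-values use the add-one ("Phipson-Smyth") convention,
``p = (#{null at least as extreme} + 1) / (n + 1)``, so that a finite
resample never reports p = 0. All randomness flows from a single integer
seed through :func:`numpy.random.default_rng`.
"""

from __future__ import annotations

import dataclasses
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ShuffleResult",
    "PermutationResult",
    "mann_whitney_u",
    "fisher_exact_2x2",
    "shuffle_intervals",
    "interval_overlap_count",
    "shuffle_overlap_test",
    "label_permutation_test",
]

#: n_x * n_y at or below which a tie-free Mann-Whitney test is computed by
#: exact enumeration of rank assignments.
EXACT_MW_LIMIT = 400

_STATISTICS = {
    "diff_of_medians": np.median,
    "diff_of_means": np.mean,
}


@dataclass
class ShuffleResult:
    """Outcome of a size-preserving interval shuffle test."""

    observed: int
    null_sample: np.ndarray
    expected: float
    p_depletion: float
    p_enrichment: float
    n_shuffles: int
    seed: int

    def to_record(self) -> dict:
        return {
            "observed": self.observed,
            "expected": self.expected,
            "p_depletion": self.p_depletion,
            "p_enrichment": self.p_enrichment,
            "n_shuffles": self.n_shuffles,
            "seed": self.seed,
        }


@dataclass
class PermutationResult:
    """Outcome of a label-permutation test."""

    statistic_observed: float
    null_sample: np.ndarray
    p: float
    tail: str
    n_perm: int
    seed: int

    def to_record(self) -> dict:
        return {
            "statistic_observed": self.statistic_observed,
            "p": self.p,
            "tail": self.tail,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def mann_whitney_u(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U test between two samples.

    U is computed from midranks. The p-value is exact (full enumeration of
    rank assignments) when the samples are tie-free and
    ``n_x * n_y <= 400``; otherwise a normal approximation with tie and
    continuity corrections is used.

    Returns ``(U, p)`` where U counts pairs in which an ``x`` observation
    exceeds a ``y`` observation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u requires two non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and x.size * y.size <= EXACT_MW_LIMIT:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def fisher_exact_2x2(table, alternative: str = "two-sided") -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table.

    ``table`` is anything exposing counts ``a, b, c, d`` (attributes or a
    2x2 nested sequence). The two-sided p sums hypergeometric probabilities
    of all tables with the observed margins whose probability does not
    exceed the observed table's probability, within a 1e-12 relative slack
    to keep mirror-symmetric tables on the inclusive side of floating-point
    rounding.

    A zero margin makes the odds ratio undefined: ``(nan, 1.0)`` is
    returned.
    """
    a, b, c, d = _table_counts(table)
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    n = a + b + c + d
    if min(row1, row2, col1, col2) == 0:
        return math.nan, 1.0
    if b == 0 or c == 0:
        odds_ratio = math.inf
    else:
        odds_ratio = (a * d) / (b * c)
    kmin = max(0, col1 - row2)
    kmax = min(row1, col1)
    support = np.arange(kmin, kmax + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[a - kmin]
    if alternative == "two-sided":
        p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    elif alternative == "greater":
        p = float(pmf[support >= a].sum())
    elif alternative == "less":
        p = float(pmf[support <= a].sum())
    else:
        raise ValueError(f"unknown alternative: {alternative!r}")
    return odds_ratio, min(p, 1.0)


def _table_counts(table) -> tuple[int, int, int, int]:
    if hasattr(table, "a"):
        counts = (table.a, table.b, table.c, table.d)
    else:
        (a, b), (c, d) = table
        counts = (a, b, c, d)
    counts = tuple(int(v) for v in counts)
    if any(v < 0 for v in counts):
        raise ValueError("contingency counts must be non-negative")
    return counts


def shuffle_intervals(intervals: Sequence, chrom_length: int, rng) -> list:
    """Place each interval independently and uniformly on the chromosome.

    Interval lengths are preserved exactly; shuffled intervals may overlap
    one another. ``rng`` is a :class:`numpy.random.Generator`.
    """
    if not intervals:
        return []
    lengths = np.array([iv.end - iv.start for iv in intervals], dtype=np.int64)
    if (lengths > chrom_length).any():
        raise ValueError("interval longer than the chromosome")
    starts = rng.integers(0, chrom_length - lengths + 1)
    out = []
    for iv, s, ln in zip(intervals, starts, lengths):
        out.append(_relocate(iv, int(s), int(s + ln)))
    return out


def _relocate(iv, start: int, end: int):
    if dataclasses.is_dataclass(iv):
        return dataclasses.replace(iv, start=start, end=end)
    return type(iv)(iv.chrom, start, end)


def _merge_arrays(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Merge overlapping/book-ended intervals given as parallel arrays."""
    if starts.size == 0:
        return starts, ends
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    merged_s = [starts[0]]
    merged_e = [ends[0]]
    for s, e in zip(starts[1:], ends[1:]):
        if s <= merged_e[-1]:
            if e > merged_e[-1]:
                merged_e[-1] = e
        else:
            merged_s.append(s)
            merged_e.append(e)
    return np.asarray(merged_s), np.asarray(merged_e)


def _count_overlapping_features(
    dom_starts: np.ndarray,
    dom_ends: np.ndarray,
    feat_starts: np.ndarray,
    feat_ends: np.ndarray,
) -> int:
    """Count features overlapping >= 1 base of a merged, sorted domain set."""
    if dom_starts.size == 0 or feat_starts.size == 0:
        return 0
    idx = np.searchsorted(dom_ends, feat_starts, side="right")
    in_range = idx < dom_starts.size
    hits = np.zeros(feat_starts.size, dtype=bool)
    hits[in_range] = dom_starts[idx[in_range]] < feat_ends[in_range]
    return int(hits.sum())


def interval_overlap_count(domains: Iterable, features: Iterable) -> int:
    """Number of features overlapping >= 1 base of >= 1 domain.

    Each feature is counted at most once. Coordinates are 0-based
    half-open, so a feature abutting a domain end does not overlap it.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for d in domains:
        by_chrom[d.chrom].append((d.start, d.end))
    merged = {}
    for chrom, pairs in by_chrom.items():
        arr = np.asarray(pairs, dtype=np.int64)
        merged[chrom] = _merge_arrays(arr[:, 0], arr[:, 1])
    count = 0
    feats: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for f in features:
        feats[f.chrom].append((f.start, f.end))
    for chrom, pairs in feats.items():
        if chrom not in merged:
            continue
        arr = np.asarray(pairs, dtype=np.int64)
        count += _count_overlapping_features(*merged[chrom], arr[:, 0], arr[:, 1])
    return count


def _sample_starts(
    lengths: np.ndarray,
    chrom_length: int,
    rng,
    allow_overlap: bool,
    max_tries: int = 1000,
) -> np.ndarray:
    if allow_overlap:
        return rng.integers(0, chrom_length - lengths + 1)
    # Rejection sampling for the strict non-overlapping mode.
    for _ in range(max_tries):
        starts = rng.integers(0, chrom_length - lengths + 1)
        order = np.argsort(starts)
        s, e = starts[order], starts[order] + lengths[order]
        if (s[1:] >= e[:-1]).all():
            return starts
    raise RuntimeError(
        "could not place non-overlapping shuffled intervals "
        f"within {max_tries} tries"
    )


def shuffle_overlap_test(
    domains: Sequence,
    features: Sequence,
    chrom_length: int,
    n_shuffles: int = 2000,
    seed: int = 0,
    allow_overlap: bool = True,
) -> ShuffleResult:
    """Empirical overlap test by size-preserving domain shuffling.

    The observed statistic is the number of ``features`` overlapping the
    real ``domains``. The null sample repositions the domains uniformly on
    one chromosome (lengths preserved; features stay fixed) ``n_shuffles``
    times. ``p_depletion = (#{null <= observed} + 1) / (n_shuffles + 1)``
    and symmetrically for enrichment. Domains and features must live on a
    single shared chromosome, mirroring a shuffle restricted to the
    chromosome under study.

    With ``allow_overlap=False`` shuffled domains are re-drawn until
    mutually disjoint (capped rejection sampling) for sensitivity analysis.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    chroms = {d.chrom for d in domains} | {f.chrom for f in features}
    if len(chroms) > 1:
        raise ValueError(f"shuffle test is confined to one chromosome, got {sorted(chroms)}")
    observed = interval_overlap_count(domains, features)
    lengths = np.array([d.end - d.start for d in domains], dtype=np.int64)
    if (lengths > chrom_length).any():
        raise ValueError("interval longer than the chromosome")
    feat = np.array([(f.start, f.end) for f in features], dtype=np.int64).reshape(-1, 2)
    feat_starts, feat_ends = feat[:, 0], feat[:, 1]
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles, dtype=np.int64)
    for i in range(n_shuffles):
        if lengths.size == 0:
            null[i] = 0
            continue
        starts = _sample_starts(lengths, chrom_length, rng, allow_overlap)
        ds, de = _merge_arrays(starts, starts + lengths)
        null[i] = _count_overlapping_features(ds, de, feat_starts, feat_ends)
    p_dep = (int((null <= observed).sum()) + 1) / (n_shuffles + 1)
    p_enr = (int((null >= observed).sum()) + 1) / (n_shuffles + 1)
    return ShuffleResult(
        observed=observed,
        null_sample=null,
        expected=float(null.mean()),
        p_depletion=float(p_dep),
        p_enrichment=float(p_enr),
        n_shuffles=n_shuffles,
        seed=seed,
    )


def label_permutation_test(
    values: Sequence[float],
    labels: Sequence,
    statistic: str = "diff_of_medians",
    n_perm: int = 2000,
    seed: int = 0,
    tail: str = "two-sided",
) -> PermutationResult:
    """Two-group permutation test on a named statistic.

    The statistic is ``stat(group_first) - stat(group_second)`` where the
    two groups are the sorted unique label levels. The null is built by
    shuffling labels over values; p-values follow the add-one convention.
    """
    if statistic not in _STATISTICS:
        raise ValueError(
            f"unknown statistic {statistic!r}; choose from {sorted(_STATISTICS)}"
        )
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if tail not in {"greater", "less", "two-sided"}:
        raise ValueError(f"unknown tail: {tail!r}")
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if levels.size != 2:
        raise ValueError(f"need exactly two label levels, got {levels.size}")
    mask = labels == levels[0]
    if mask.sum() == 0 or (~mask).sum() == 0:
        raise ValueError("both groups must be non-empty")
    func = _STATISTICS[statistic]
    observed = float(func(values[mask]) - func(values[~mask]))
    n0 = int(mask.sum())
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=float)
    for i in range(n_perm):
        perm = rng.permutation(values.size)
        null[i] = func(values[perm[:n0]]) - func(values[perm[n0:]])
    p_greater = (int((null >= observed).sum()) + 1) / (n_perm + 1)
    p_less = (int((null <= observed).sum()) + 1) / (n_perm + 1)
    if tail == "greater":
        p = p_greater
    elif tail == "less":
        p = p_less
    else:
        p = min(1.0, 2.0 * min(p_greater, p_less))
    return PermutationResult(
        statistic_observed=observed,
        null_sample=null,
        p=float(p),
        tail=tail,
        n_perm=n_perm,
        seed=seed,
    )
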