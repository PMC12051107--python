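"""BED-style interval sets: unique intersect, per-chromosome shuffle, overlap summaries.

Coordinates are 0-based half-open (BED convention); "overlap" always means
at least one shared base pair, matching ``bedtools intersect -u``.  The
shuffle null randomises interval positions uniformly within their own
chromosome, preserving lengths and (optionally) pairwise disjointness,
matching ``bedtools shuffle -chrom -noOverlapping``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from .errors import PackingError, ParameterError

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "OverlapSummary",
    "ShuffleNull",
    "intersect_unique",
    "shuffle_per_chromosome",
    "overlap_summary",
    "shuffle_null_summary",
]


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    score: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"require 0 <= start < end, got {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class IntervalSet:
    """Intervals plus their chromosome-sizes context."""

    intervals: list[GenomicInterval]
    genome: dict[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.genome.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        for iv in self.intervals:
            if iv.chrom not in self.genome:
                raise ParameterError(f"interval chromosome {iv.chrom!r} absent from genome context")
            if iv.end > self.genome[iv.chrom]:
                raise ValueError(f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome length")

    def __len__(self) -> int:
        return len(self.intervals)

    def sorted(self) -> "IntervalSet":
        return IntervalSet(
            intervals=sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)),
            genome=dict(self.genome),
        )

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


@dataclass(frozen=True)
class OverlapSummary:
    """Bidirectional overlap counts between two interval sets."""

    n_a: int
    n_b: int
    n_a_in_b: int
    n_b_in_a: int
    pct_a_in_b: float
    pct_b_in_a: float
    peaks_per_zone: float | None  # n_a_in_b / n_b_in_a; None when undefined


@dataclass(frozen=True)
class ShuffleNull:
    """Observed overlap count against its per-chromosome shuffle null."""

    observed: int
    null_counts: tuple[int, ...]
    fold_change: float | None  # observed / mean(null); None when null mean is 0

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_counts)) if self.null_counts else float("nan")


def _trees(s: IntervalSet) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in s.intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def _shared_genome(a: IntervalSet, b: IntervalSet) -> None:
    if a.genome != b.genome:
        raise ParameterError("interval sets must share the same genome context")


def intersect_unique(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Rows of ``a`` that overlap at least one interval of ``b`` by ≥ 1 bp.

    Each qualifying row of ``a`` is reported exactly once (duplicate rows
    count individually); output sorted by (chrom, start, end).
    """
    _shared_genome(a, b)
    trees = _trees(b)
    hits = [
        iv
        for iv in a.intervals
        if iv.chrom in trees and trees[iv.chrom].overlaps(iv.start, iv.end)
    ]
    return IntervalSet(intervals=hits, genome=dict(a.genome)).sorted()


def shuffle_per_chromosome(
    s: IntervalSet,
    seed: int,
    no_overlap: bool = True,
    max_tries: int = 10_000,
) -> IntervalSet:
    """Relocate every interval uniformly at random within its own chromosome.

    Lengths and chromosome assignment are preserved.  With ``no_overlap``
    the placed intervals are pairwise disjoint, enforced by rejection
    sampling (up to ``max_tries`` draws per interval, placement order
    randomised to reduce packing bias).  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    placed: list[GenomicInterval] = []
    for chrom, ivs in sorted(s.by_chrom().items()):
        chrom_len = s.genome[chrom]
        if sum(len(iv) for iv in ivs) > chrom_len:
            raise PackingError(chrom, f"total interval length exceeds chromosome {chrom!r}")
        occupied = IntervalTree()
        for iv in (ivs[i] for i in rng.permutation(len(ivs))):
            span = chrom_len - len(iv)
            for _ in range(max_tries):
                start = int(rng.integers(0, span + 1))
                if not no_overlap or not occupied.overlaps(start, start + len(iv)):
                    break
            else:
                raise PackingError(chrom)
            if no_overlap:
                occupied.addi(start, start + len(iv))
            placed.append(GenomicInterval(chrom, start, start + len(iv), score=iv.score))
    return IntervalSet(intervals=placed, genome=dict(s.genome)).sorted()


def overlap_summary(a: IntervalSet, b: IntervalSet) -> OverlapSummary:
    """Counts and percentages of a-in-b and b-in-a overlap, plus peaks/zone.

    ``peaks_per_zone`` is the number of a-intervals landing in b divided by
    the number of b-intervals hit — e.g. dense-DNA peaks per initiation
    zone — and is ``None`` when no b-interval is hit.
    """
    _shared_genome(a, b)
    n_a_in_b = len(intersect_unique(a, b))
    n_b_in_a = len(intersect_unique(b, a))
    return OverlapSummary(
        n_a=len(a),
        n_b=len(b),
        n_a_in_b=n_a_in_b,
        n_b_in_a=n_b_in_a,
        pct_a_in_b=100.0 * n_a_in_b / len(a) if len(a) else 0.0,
        pct_b_in_a=100.0 * n_b_in_a / len(b) if len(b) else 0.0,
        peaks_per_zone=n_a_in_b / n_b_in_a if n_b_in_a else None,
    )


def shuffle_null_summary(a: IntervalSet, b: IntervalSet, n_shuffles: int, seed: int) -> ShuffleNull:
    """Empirical null of the a-in-b overlap count under shuffling of ``a``."""
    _shared_genome(a, b)
    if n_shuffles < 1:
        raise ParameterError("n_shuffles must be >= 1")
    observed = len(intersect_unique(a, b))
    child_seeds = np.random.SeedSequence(seed).generate_state(n_shuffles) >> 1  # keep < 2**31
    null = tuple(
        len(intersect_unique(shuffle_per_chromosome(a, int(cs)), b)) for cs in child_seeds
    )
    mean_null = float(np.mean(null))
    return ShuffleNull(
        observed=observed,
        null_counts=null,
        fold_change=observed / mean_null if mean_null > 0 else None,
    )
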