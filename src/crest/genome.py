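"""Genomic data model and interval/coverage algebra.

Coordinates are 0-based, half-open throughout (BED/bedGraph native): an
interval ``[start, end)`` covers the bases ``start .. end-1``.  Interval sets
are kept sorted per chromosome; merging produces non-overlapping,
non-abutting intervals, which is the precondition for base-pair counting.

The algebra here (merge, base intersection/union, overlap selection,
per-interval signal) is the primitive everything downstream is built on, so
it is implemented directly on numpy arrays and checked against a naive
per-base oracle in the test suite.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "GenomeModel",
    "GenomicInterval",
    "IntervalSet",
    "CoverageTrack",
    "GeneAnnotation",
    "merge_intervals",
    "intersect_bases",
    "union_bases",
    "overlapping_subset",
    "subtract_intervals",
    "nearest_tss",
    "signal_in_interval",
]


class GenomeModel:
    """Chromosome names and lengths; the coordinate frame of a run.

    Every interval and coverage step elsewhere in the pipeline must reference
    a chromosome registered here, with coordinates within its length.
    """

    def __init__(self, chromosomes: Mapping[str, int]):
        if not chromosomes:
            raise ValueError("genome must define at least one chromosome")
        lengths = {}
        for name, length in chromosomes.items():
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
            if name in lengths:
                raise ValueError(f"duplicate chromosome name {name!r}")
            lengths[str(name)] = length
        self._lengths = lengths

    @property
    def chromosomes(self) -> dict[str, int]:
        return dict(self._lengths)

    @property
    def names(self) -> list[str]:
        return list(self._lengths)

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def length_of(self, name: str) -> int:
        try:
            return self._lengths[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def total_length(self) -> int:
        return sum(self._lengths.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeModel) and self._lengths == other._lengths

    def __repr__(self) -> str:
        return f"GenomeModel({self._lengths!r})"


@dataclass(frozen=True)
class GenomicInterval:
    """One half-open interval, optionally named and scored (BED semantics)."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty or inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene locus anchor: a TSS on a strand, used to assign enhancers to genes."""

    gene_id: str
    chrom: str
    tss: int
    strand: str = "+"

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene_id}")


class IntervalSet:
    """A collection of genomic intervals, sorted per chromosome.

    Construction sorts by (chromosome, start, end) and, when a genome is
    supplied, validates that every interval fits its chromosome.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval] = (),
        genome: Optional[GenomeModel] = None,
    ):
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        if genome is not None:
            for iv in ivs:
                if iv.chrom not in genome:
                    raise ValueError(f"unknown chromosome {iv.chrom!r}")
                if iv.end > genome.length_of(iv.chrom):
                    raise ValueError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                        f"chromosome length {genome.length_of(iv.chrom)}"
                    )
        self._intervals: list[GenomicInterval] = ivs
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for iv in ivs:
            self._arrays.setdefault(iv.chrom, None)  # type: ignore[arg-type]
        for chrom in self._arrays:
            sub = [iv for iv in ivs if iv.chrom == chrom]
            self._arrays[chrom] = (
                np.array([iv.start for iv in sub], dtype=np.int64),
                np.array([iv.end for iv in sub], dtype=np.int64),
            )

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self):
        return iter(self._intervals)

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self._intervals == other._intervals

    @property
    def intervals(self) -> list[GenomicInterval]:
        return list(self._intervals)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._arrays)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(starts, ends) for one chromosome; empty arrays if absent."""
        if chrom not in self._arrays:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty
        return self._arrays[chrom]

    # -- algebra ------------------------------------------------------------
    def merge(self, min_gap: int = 0) -> "IntervalSet":
        return merge_intervals(self, min_gap)

    def total_bases(self) -> int:
        """Number of distinct covered bases (overlaps counted once)."""
        total = 0
        for chrom in self._arrays:
            starts, ends = _merge_arrays(*self._arrays[chrom], 0)
            total += int((ends - starts).sum())
        return total


def _merge_arrays(
    starts: np.ndarray, ends: np.ndarray, min_gap: int
) -> tuple[np.ndarray, np.ndarray]:
    """Merge sorted interval arrays; gaps <= min_gap are closed."""
    if starts.size == 0:
        return starts, ends
    cummax = np.maximum.accumulate(ends)
    # a new block starts where the current start exceeds the previous
    # running end by more than min_gap
    new_block = np.empty(starts.size, dtype=bool)
    new_block[0] = True
    new_block[1:] = starts[1:] > cummax[:-1] + min_gap
    idx = np.flatnonzero(new_block)
    out_starts = starts[idx]
    out_ends = np.empty(idx.size, dtype=np.int64)
    out_ends[:-1] = cummax[idx[1:] - 1]
    out_ends[-1] = cummax[-1]
    return out_starts, out_ends


def _set_from_arrays(per_chrom: dict[str, tuple[np.ndarray, np.ndarray]]) -> IntervalSet:
    ivs = []
    for chrom, (starts, ends) in per_chrom.items():
        ivs.extend(
            GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends)
        )
    return IntervalSet(ivs)


def merge_intervals(a: IntervalSet, min_gap: int = 0) -> IntervalSet:
    """Merge intervals separated by at most ``min_gap`` bases.

    ``min_gap=0`` merges overlapping and abutting intervals only; names and
    scores do not survive merging.
    """
    if min_gap < 0:
        raise ValueError("min_gap must be non-negative")
    return _set_from_arrays(
        {chrom: _merge_arrays(*a.arrays(chrom), min_gap) for chrom in a.chromosomes}
    )


def _intersect_arrays(
    a_starts: np.ndarray, a_ends: np.ndarray, b_starts: np.ndarray, b_ends: np.ndarray
) -> int:
    """Total overlapping bases between two merged, sorted interval arrays."""
    if a_starts.size == 0 or b_starts.size == 0:
        return 0
    # for each interval of a, find the b intervals it can overlap
    lo = np.searchsorted(b_ends, a_starts, side="right")
    hi = np.searchsorted(b_starts, a_ends, side="left")
    total = 0
    for s, e, i, j in zip(a_starts, a_ends, lo, hi):
        if j > i:
            total += int(
                np.clip(np.minimum(b_ends[i:j], e) - np.maximum(b_starts[i:j], s), 0, None).sum()
            )
    return total


def intersect_bases(a: IntervalSet, b: IntervalSet) -> int:
    """Bases covered by both sets; symmetric, fragmentation-invariant."""
    am, bm = a.merge(), b.merge()
    return sum(
        _intersect_arrays(*am.arrays(chrom), *bm.arrays(chrom))
        for chrom in am.chromosomes
    )


def union_bases(a: IntervalSet, b: IntervalSet) -> int:
    """Bases covered by either set."""
    return a.total_bases() + b.total_bases() - intersect_bases(a, b)


def overlapping_subset(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Intervals of ``a`` that share at least one base with ``b``.

    Whole intervals are retained, never clipped: downstream stages classify
    whole peaks, not overlap fragments.
    """
    bm = b.merge()
    keep = []
    for iv in a:
        b_starts, b_ends = bm.arrays(iv.chrom)
        if b_starts.size == 0:
            continue
        i = np.searchsorted(b_ends, iv.start, side="right")
        if i < b_starts.size and b_starts[i] < iv.end:
            keep.append(iv)
    return IntervalSet(keep)


def subtract_intervals(a: IntervalSet, exclusion: IntervalSet) -> IntervalSet:
    """Remove every base of ``exclusion`` from ``a`` (blacklist filtering).

    Intervals are clipped around excluded regions; names/scores of clipped
    fragments are preserved from the source interval.
    """
    exm = exclusion.merge()
    out = []
    for iv in a:
        ex_starts, ex_ends = exm.arrays(iv.chrom)
        if ex_starts.size == 0:
            out.append(iv)
            continue
        i = np.searchsorted(ex_ends, iv.start, side="right")
        j = np.searchsorted(ex_starts, iv.end, side="left")
        cursor = iv.start
        for k in range(i, j):
            if ex_starts[k] > cursor:
                out.append(
                    GenomicInterval(iv.chrom, cursor, int(ex_starts[k]), iv.name, iv.score)
                )
            cursor = max(cursor, int(ex_ends[k]))
        if cursor < iv.end:
            out.append(GenomicInterval(iv.chrom, cursor, iv.end, iv.name, iv.score))
    return IntervalSet(out)


def nearest_tss(
    interval: GenomicInterval,
    genes: Sequence[GeneAnnotation],
    max_distance: int,
) -> Optional[str]:
    """Gene whose TSS is nearest to the interval, or None beyond ``max_distance``.

    Distance is 0 when the TSS falls inside the interval, otherwise the number
    of bases from the nearest covered base to the TSS.  Ties are broken by the
    lexicographically smaller gene id, which makes the assignment
    deterministic.
    """
    best: tuple[int, str] | None = None
    for g in genes:
        if g.chrom != interval.chrom:
            continue
        if interval.start <= g.tss < interval.end:
            d = 0
        elif g.tss < interval.start:
            d = interval.start - g.tss
        else:
            d = g.tss - interval.end + 1
        if d > max_distance:
            continue
        key = (d, g.gene_id)
        if best is None or key < best:
            best = key
    return None if best is None else best[1]


class CoverageTrack:
    """Stepwise genomic signal with bedGraph semantics.

    Steps are non-overlapping, sorted, non-negative.  Total signal is
    sum(value * width); zero-valued gaps are implicit.
    """

    def __init__(self, steps: Iterable[tuple[str, int, int, float]] = ()):
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in steps:
            if start < 0 or start >= end:
                raise ValueError(f"bad step {chrom}:{start}-{end}")
            if value < 0 or not np.isfinite(value):
                raise ValueError(f"step value must be finite and >= 0, got {value}")
            per_chrom.setdefault(chrom, []).append((int(start), int(end), float(value)))
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, items in per_chrom.items():
            items.sort()
            starts = np.array([s for s, _, _ in items], dtype=np.int64)
            ends = np.array([e for _, e, _ in items], dtype=np.int64)
            values = np.array([v for _, _, v in items], dtype=np.float64)
            if np.any(starts[1:] < ends[:-1]):
                bad = int(np.flatnonzero(starts[1:] < ends[:-1])[0])
                raise ValueError(
                    f"overlapping steps on {chrom} near position {int(starts[bad + 1])}"
                )
            self._arrays[chrom] = (starts, ends, values)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._arrays)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if chrom not in self._arrays:
            empty_i = np.empty(0, dtype=np.int64)
            return empty_i, empty_i.copy(), np.empty(0, dtype=np.float64)
        return self._arrays[chrom]

    def steps(self):
        """Iterate (chrom, start, end, value) in sorted order."""
        for chrom in self.chromosomes:
            starts, ends, values = self._arrays[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)

    def __len__(self) -> int:
        return sum(v[0].size for v in self._arrays.values())

    def total_signal(self) -> float:
        return float(
            sum(((e - s) * v).sum() for s, e, v in self._arrays.values())
        )

    def scaled(self, factor: float) -> "CoverageTrack":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        out = CoverageTrack()
        out._arrays = {
            chrom: (s.copy(), e.copy(), v * factor)
            for chrom, (s, e, v) in self._arrays.items()
        }
        return out


def signal_in_interval(track: CoverageTrack, interval: GenomicInterval) -> float:
    """Sum of step value x overlap width over the interval; additive over partitions."""
    starts, ends, values = track.arrays(interval.chrom)
    if starts.size == 0:
        return 0.0
    i = np.searchsorted(ends, interval.start, side="right")
    j = np.searchsorted(starts, interval.end, side="left")
    if j <= i:
        return 0.0
    widths = np.clip(
        np.minimum(ends[i:j], interval.end) - np.maximum(starts[i:j], interval.start),
        0,
        None,
    )
    return float((widths * values[i:j]).sum())
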