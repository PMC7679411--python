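"""Calling TF-dependent enhancers from paired control/knockdown H3K27ac signal.

An enhancer (an H3K27ac peak overlapping a TF binding peak) is called
TF-dependent when the log2 ratio of knockdown to control acetylation signal,
stabilized by a pseudocount, falls strictly below a threshold (default -0.5).
Genes from the contrast classification become direct targets when a
dependent enhancer is assigned to their TSS (nearest-TSS within a window)
and the TF binds within that window.

Tracks must be normalized to a common total before signals are compared;
``normalize_track`` rescales a track the way depth normalization by total
mapped reads does.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .contrasts import GeneClassification
from .genome import (
    CoverageTrack,
    GeneAnnotation,
    GenomicInterval,
    IntervalSet,
    nearest_tss,
    overlapping_subset,
    signal_in_interval,
)

__all__ = [
    "DependencyCall",
    "EnhancerCallResult",
    "DirectTargetCall",
    "GroupComparison",
    "normalize_track",
    "merge_tracks_mean",
    "dependency_log2_ratio",
    "classify_dependency",
    "call_enhancers",
    "call_direct_targets",
    "mann_whitney",
]


@dataclass(frozen=True)
class DependencyCall:
    """One TF-bound H3K27ac peak with its paired signals and dependency label."""

    peak: GenomicInterval
    control_signal: float
    kd_signal: float
    log2_ratio: float
    is_dependent: bool


@dataclass
class EnhancerCallResult:
    """All dependency calls of a run plus the dependent fraction."""

    calls: list[DependencyCall]
    pseudocount: float
    threshold: float

    @property
    def n_dependent(self) -> int:
        return sum(c.is_dependent for c in self.calls)

    @property
    def dependent_fraction(self) -> float:
        return self.n_dependent / len(self.calls) if self.calls else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (
                    c.peak.chrom,
                    c.peak.start,
                    c.peak.end,
                    c.control_signal,
                    c.kd_signal,
                    c.log2_ratio,
                    c.is_dependent,
                )
                for c in self.calls
            ],
            columns=[
                "chrom",
                "start",
                "end",
                "control_signal",
                "kd_signal",
                "log2_ratio",
                "dependent",
            ],
        )


@dataclass
class DirectTargetCall:
    """Direct-target status of one classified gene."""

    gene_id: str
    gene_class: str  # canonical | specific
    supporting_peaks: list[DependencyCall]
    tf_bound: bool
    is_direct: bool

    @property
    def n_dependent_peaks(self) -> int:
        return sum(c.is_dependent for c in self.supporting_peaks)


@dataclass(frozen=True)
class GroupComparison:
    """Two-group rank comparison (Mann–Whitney U, two-tailed)."""

    group_a: str
    group_b: str
    u_statistic: float
    p_value: float
    n_a: int
    n_b: int


def normalize_track(track: CoverageTrack, target_total: float) -> CoverageTrack:
    """Rescale all step values so the track's total signal equals ``target_total``."""
    if target_total <= 0:
        raise ValueError("target_total must be positive")
    total = track.total_signal()
    if total == 0:
        raise ValueError("cannot normalize a track with zero total signal")
    return track.scaled(target_total / total)


def merge_tracks_mean(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Mean of several coverage tracks, evaluated piecewise.

    Step boundaries are unioned per chromosome; a track contributes 0 where
    it has no step, so the result is the per-base mean of the inputs.
    """
    if not tracks:
        raise ValueError("at least one track is required")
    chroms = sorted({c for t in tracks for c in t.chromosomes})
    steps = []
    for chrom in chroms:
        bounds = np.unique(
            np.concatenate(
                [np.concatenate(t.arrays(chrom)[:2]) for t in tracks]
            )
        )
        seg_starts, seg_ends = bounds[:-1], bounds[1:]
        acc = np.zeros(seg_starts.size, dtype=float)
        for t in tracks:
            starts, ends, values = t.arrays(chrom)
            if starts.size == 0:
                continue
            idx = np.searchsorted(starts, seg_starts, side="right") - 1
            valid = idx >= 0
            valid[valid] &= seg_ends[valid] <= ends[idx[valid]]
            acc[valid] += values[idx[valid]]
        mean = acc / len(tracks)
        nz = mean > 0
        steps.extend(
            (chrom, int(s), int(e), float(v))
            for s, e, v in zip(seg_starts[nz], seg_ends[nz], mean[nz])
        )
    return CoverageTrack(steps)


def dependency_log2_ratio(
    control_signal: float, kd_signal: float, pseudocount: float = 1.0
) -> float:
    """log2((kd + pc) / (control + pc)); defined even at zero coverage."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if control_signal < 0 or kd_signal < 0:
        raise ValueError("signals must be non-negative")
    return math.log2((kd_signal + pseudocount) / (control_signal + pseudocount))


def classify_dependency(ratio: float, threshold: float = -0.5) -> bool:
    """Dependent iff the log2 ratio is strictly below the threshold."""
    return ratio < threshold


def call_enhancers(
    h3k27ac_peaks: IntervalSet,
    tf_peaks: IntervalSet,
    control_track: CoverageTrack,
    kd_track: CoverageTrack,
    pseudocount: float = 1.0,
    threshold: float = -0.5,
) -> EnhancerCallResult:
    """Classify TF-overlapping H3K27ac peaks as dependent or independent.

    Only H3K27ac peaks sharing at least one base with a TF peak are
    quantified; each retained peak gets its control and knockdown signal from
    the tracks, the pseudocount-stabilized log2 ratio, and the strict
    threshold call.  The tracks must carry the same total signal (relative
    difference <= 1e-6), i.e. be depth-normalized to a common target.
    """
    tc, tk = control_track.total_signal(), kd_track.total_signal()
    if tc <= 0 or tk <= 0:
        raise ValueError("tracks must have positive total signal")
    if abs(tc - tk) > 1e-6 * max(tc, tk):
        raise ValueError(
            f"tracks are not normalized to the same total ({tc:g} vs {tk:g}); "
            "apply normalize_track first"
        )
    retained = overlapping_subset(h3k27ac_peaks, tf_peaks)
    calls = []
    for peak in retained:
        c = signal_in_interval(control_track, peak)
        k = signal_in_interval(kd_track, peak)
        ratio = dependency_log2_ratio(c, k, pseudocount)
        calls.append(
            DependencyCall(
                peak=peak,
                control_signal=c,
                kd_signal=k,
                log2_ratio=ratio,
                is_dependent=classify_dependency(ratio, threshold),
            )
        )
    return EnhancerCallResult(calls=calls, pseudocount=pseudocount, threshold=threshold)


def call_direct_targets(
    genes: Sequence[GeneAnnotation],
    gene_classes: GeneClassification,
    calls: Sequence[DependencyCall],
    tf_peaks: IntervalSet,
    window: int = 100_000,
) -> list[DirectTargetCall]:
    """Direct-target calls for every classified gene.

    Each enhancer call is assigned to its nearest TSS within ``window`` (one
    gene per peak); a gene is direct when at least one assigned peak is
    dependent *and* a TF peak lies within the window of its TSS.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    by_gene: dict[str, GeneAnnotation] = {g.gene_id: g for g in genes}
    classified = sorted(gene_classes.common_downstream)
    missing = [g for g in classified if g not in by_gene]
    if missing:
        raise KeyError(f"classified gene(s) absent from annotation: {missing}")

    tf_merged = tf_peaks.merge()
    assigned: dict[str, list[DependencyCall]] = {g: [] for g in classified}
    for call in calls:
        gene = nearest_tss(call.peak, genes, window)
        if gene is not None and gene in assigned:
            assigned[gene].append(call)

    out = []
    for gene_id in classified:
        ann = by_gene[gene_id]
        tf_starts, tf_ends = tf_merged.arrays(ann.chrom)
        tf_bound = bool(
            np.any(
                (tf_starts <= ann.tss + window) & (tf_ends - 1 >= ann.tss - window)
            )
        )
        supporting = assigned[gene_id]
        is_direct = tf_bound and any(c.is_dependent for c in supporting)
        out.append(
            DirectTargetCall(
                gene_id=gene_id,
                gene_class=gene_classes.class_of(gene_id) or "none",
                supporting_peaks=supporting,
                tf_bound=tf_bound,
                is_direct=is_direct,
            )
        )
    return out


def mann_whitney(
    values_a: Sequence[float],
    values_b: Sequence[float],
    label_a: str = "A",
    label_b: str = "B",
) -> GroupComparison:
    """Two-tailed Mann–Whitney test.

    The U statistic is the rank-sum form for the first group with mid-ranks
    for ties.  The p-value is exact (full enumeration of the U null) when the
    pooled size is at most 16 and no ties are present; otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if a.size + b.size <= 16 and no_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return GroupComparison(
        group_a=label_a,
        group_b=label_b,
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=int(a.size),
        n_b=int(b.size),
    )
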