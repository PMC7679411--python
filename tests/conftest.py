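"""Shared fixtures and the naive per-base oracle used against the interval algebra."""

from __future__ import annotations

import numpy as np
import pytest

from crest.genome import (
    CoverageTrack,
    GenomeModel,
    GenomicInterval,
    IntervalSet,
)
from crest.simulate import SimulationConfig


# ---------------------------------------------------------------------------
# per-base oracle: boolean membership arrays on a tiny genome
# ---------------------------------------------------------------------------

def bases_of(iset: IntervalSet, genome: GenomeModel) -> dict[str, np.ndarray]:
    cov = {c: np.zeros(L, dtype=bool) for c, L in genome.chromosomes.items()}
    for iv in iset:
        cov[iv.chrom][iv.start : iv.end] = True
    return cov


def oracle_intersect(a, b, genome) -> int:
    ca, cb = bases_of(a, genome), bases_of(b, genome)
    return int(sum((ca[c] & cb[c]).sum() for c in ca))


def oracle_union(a, b, genome) -> int:
    ca, cb = bases_of(a, genome), bases_of(b, genome)
    return int(sum((ca[c] | cb[c]).sum() for c in ca))


def oracle_merge(a: IntervalSet, genome: GenomeModel, min_gap: int = 0) -> IntervalSet:
    """Merge by painting bases then closing gaps <= min_gap, then reading runs."""
    out = []
    for chrom, cov in bases_of(a, genome).items():
        cov = cov.copy()
        # close gaps of at most min_gap between covered runs, then read runs
        idx = np.flatnonzero(cov)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > 1)
        for bi in breaks:
            gap = idx[bi + 1] - idx[bi] - 1
            if gap <= min_gap:
                cov[idx[bi] + 1 : idx[bi + 1]] = True
        idx = np.flatnonzero(cov)
        starts = [int(idx[0])] + [int(idx[i + 1]) for i in np.flatnonzero(np.diff(idx) > 1)]
        ends = [int(idx[i]) + 1 for i in np.flatnonzero(np.diff(idx) > 1)] + [int(idx[-1]) + 1]
        out.extend(GenomicInterval(chrom, s, e) for s, e in zip(starts, ends))
    return IntervalSet(out)


def oracle_overlapping_subset(a, b, genome) -> IntervalSet:
    cb = bases_of(b, genome)
    keep = [iv for iv in a if cb[iv.chrom][iv.start : iv.end].any()]
    return IntervalSet(keep)


def oracle_signal(track: CoverageTrack, interval: GenomicInterval, genome) -> float:
    vals = {c: np.zeros(L, dtype=float) for c, L in genome.chromosomes.items()}
    for chrom, s, e, v in track.steps():
        vals[chrom][s:e] = v
    return float(vals[interval.chrom][interval.start : interval.end].sum())


def random_interval_set(rng, genome, max_intervals=50) -> IntervalSet:
    ivs = []
    for _ in range(int(rng.integers(0, max_intervals + 1))):
        chrom = str(rng.choice(genome.names))
        L = genome.length_of(chrom)
        start = int(rng.integers(0, L - 1))
        end = int(rng.integers(start + 1, min(L, start + 1 + L // 4) + 1))
        ivs.append(GenomicInterval(chrom, start, end))
    return IntervalSet(ivs, genome)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def toy_genome() -> GenomeModel:
    return GenomeModel({"chr1": 10_000, "chr2": 5_000})


@pytest.fixture
def small_sim_config() -> SimulationConfig:
    """Scaled-down study design for fast end-to-end tests."""
    return SimulationConfig(
        seed=13,
        n_genes=300,
        n_canonical=20,
        n_specific=10,
        n_enhancers=40,
        n_direct_canonical=15,
        n_direct_specific=6,
        dependent_fraction=27 / 40,
        n_h3k27ac_only=5,
        n_tf_only=5,
        n_null_genes_annotated=20,
        cohort_size=60,
        n_correlated_candidates=5,
        n_cohort_null_genes=10,
    )
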