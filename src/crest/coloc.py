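"""Base-pair Jaccard colocalization of candidate cofactor peak sets.

The reference set is the TF's binding peaks that carry the active-enhancer
mark (H3K27ac).  Each candidate factor's peak set is scored by the genomic
Jaccard index — overlapping bases over union bases of the merged sets — and
ranked.  Significance comes from a Monte-Carlo null that repositions every
query interval uniformly at random within its own chromosome, preserving
lengths and chromosome assignment, with the add-one estimator
p = (k + 1) / (n_perm + 1) so p never reaches zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .genome import (
    GenomeModel,
    GenomicInterval,
    IntervalSet,
    _merge_arrays,
    intersect_bases,
    overlapping_subset,
    subtract_intervals,
    union_bases,
)

__all__ = [
    "JaccardResult",
    "reference_set",
    "jaccard_index",
    "permutation_null",
    "rank_cofactors",
]


@dataclass(frozen=True)
class JaccardResult:
    factor: str
    jaccard: float
    perm_p: Optional[float]
    rank: int


def reference_set(tf_peaks: IntervalSet, h3k27ac_peaks: IntervalSet) -> IntervalSet:
    """TF peaks that overlap the enhancer mark — the colocalization reference."""
    return overlapping_subset(tf_peaks, h3k27ac_peaks)


def jaccard_index(a: IntervalSet, b: IntervalSet) -> float:
    """Base-pair Jaccard of two interval sets; symmetric, in [0, 1]."""
    union = union_bases(a, b)
    if union == 0:
        raise ValueError("Jaccard undefined: both sets are empty")
    return intersect_bases(a, b) / union


def _merged_arrays(iset: IntervalSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    m = iset.merge()
    return {c: m.arrays(c) for c in m.chromosomes}


def _jaccard_merged(
    q: dict[str, tuple[np.ndarray, np.ndarray]],
    r: dict[str, tuple[np.ndarray, np.ndarray]],
    r_bases: int,
) -> float:
    """Jaccard between pre-merged per-chromosome arrays (two-pointer sweep)."""
    inter = 0
    q_bases = 0
    for chrom, (qs, qe) in q.items():
        q_bases += int((qe - qs).sum())
        if chrom not in r:
            continue
        rs, re = r[chrom]
        i = j = 0
        while i < qs.size and j < rs.size:
            lo = max(qs[i], rs[j])
            hi = min(qe[i], re[j])
            if hi > lo:
                inter += int(hi - lo)
            if qe[i] <= re[j]:
                i += 1
            else:
                j += 1
    union = q_bases + r_bases - inter
    return inter / union if union else 0.0


def permutation_null(
    query: IntervalSet,
    reference: IntervalSet,
    genome: GenomeModel,
    n_perm: int = 999,
    seed: int = 0,
    exclusion: Optional[IntervalSet] = None,
) -> float:
    """Monte-Carlo p-value for the observed Jaccard of query vs reference.

    Each permutation repositions every query interval uniformly within its
    own chromosome (lengths preserved, start drawn so the interval fits).
    p = (k + 1) / (n_perm + 1), where k counts permutations whose Jaccard is
    >= the observed value.  When an exclusion set is given it is subtracted
    from the query, the reference, and every permuted set.
    """
    if n_perm < 19:
        raise ValueError("n_perm must be at least 19")
    if exclusion is not None:
        query = subtract_intervals(query, exclusion)
        reference = subtract_intervals(reference, exclusion)
    lengths_by_chrom: dict[str, np.ndarray] = {}
    for iv in query:
        L = genome.length_of(iv.chrom)
        if len(iv) > L:
            raise ValueError(
                f"interval of length {len(iv)} cannot fit chromosome {iv.chrom}"
            )
        lengths_by_chrom.setdefault(iv.chrom, [])
        lengths_by_chrom[iv.chrom].append(len(iv))
    lengths_by_chrom = {
        c: np.asarray(v, dtype=np.int64) for c, v in lengths_by_chrom.items()
    }
    ref_arrays = _merged_arrays(reference)
    ref_bases = reference.total_bases()
    observed = jaccard_index(query, reference)
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(n_perm):
        perm: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, lens in lengths_by_chrom.items():
            L = genome.length_of(chrom)
            starts = rng.integers(0, L - lens + 1)
            ends = starts + lens
            order = np.argsort(starts, kind="stable")
            perm[chrom] = _merge_arrays(starts[order], ends[order], 0)
        if exclusion is not None:
            perm_set = _set_from(perm)
            perm_set = subtract_intervals(perm_set, exclusion)
            perm = _merged_arrays(perm_set)
        if _jaccard_merged(perm, ref_arrays, ref_bases) >= observed:
            k += 1
    return (k + 1) / (n_perm + 1)


def _set_from(per_chrom: dict[str, tuple[np.ndarray, np.ndarray]]) -> IntervalSet:
    ivs = []
    for chrom, (starts, ends) in per_chrom.items():
        ivs.extend(GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends))
    return IntervalSet(ivs)


def rank_cofactors(
    catalog: Mapping[str, IntervalSet],
    reference: IntervalSet,
    genome: GenomeModel,
    n_perm: int = 999,
    seed: int = 0,
    exclusion: Optional[IntervalSet] = None,
) -> list[JaccardResult]:
    """Rank candidate factors by descending Jaccard against the reference.

    Ties break by factor name, and each factor's permutation seed is derived
    from (seed, sorted position) so the ranking is independent of catalog
    insertion order.
    """
    if not catalog:
        raise ValueError("catalog must be non-empty")
    if len(reference) == 0 or reference.total_bases() == 0:
        raise ValueError("reference set is empty")
    if exclusion is not None:
        reference = subtract_intervals(reference, exclusion)
    rows = []
    ss = np.random.SeedSequence(seed)
    child_seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(sorted(catalog), ss.spawn(len(catalog)))
    }
    for name in sorted(catalog):
        iset = catalog[name]
        if exclusion is not None:
            iset = subtract_intervals(iset, exclusion)
        j = jaccard_index(iset, reference)
        p = permutation_null(
            iset,
            reference,
            genome,
            n_perm=n_perm,
            seed=child_seeds[name],
            exclusion=exclusion,
        )
        rows.append((name, j, p))
    rows.sort(key=lambda r: (-r[1], r[0]))
    return [
        JaccardResult(factor=name, jaccard=j, perm_p=p, rank=i + 1)
        for i, (name, j, p) in enumerate(rows)
    ]


def ranking_to_frame(results: list[JaccardResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.factor, r.jaccard, r.perm_p, r.rank) for r in results],
        columns=["factor", "jaccard", "perm_p", "rank"],
    )
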