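"""Seeded generators planting every structure the pipeline is meant to infer.

The generators emulate the study design end to end on a desk-scale synthetic
genome: three knockdown contrasts in constitutively TF-active cell contexts
and two induction contrasts in TF-normal contexts (with planted canonical,
specific and null genes); paired control/knockdown H3K27ac coverage over
TF-bound enhancer peaks with a planted dependent subset; cofactor peak sets
constructed to hit target base-pair Jaccard values against the reference;
and a tumor expression cohort whose signature genes and query gene co-vary
with a latent activity variable.

Every generator records its ground truth in machine-readable tables so that
recovery tests read truth from data, never from hidden coupling, and
identical configuration plus seed reproduces byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .activity import DEFAULT_SIGNATURE
from .contrasts import ContrastTable, KNOCKDOWN, INDUCTION
from .genome import (
    CoverageTrack,
    GeneAnnotation,
    GenomeModel,
    GenomicInterval,
    IntervalSet,
)

KD_CONTEXTS = ("A549", "H460", "H2023")
IND_CONTEXTS = ("ABC1", "HCC4006")

SLOT = 10_000          # bp per layout slot
NOTCH3_SLOT = 30_000   # the exemplar gene gets room for a distal enhancer
BIN = 10               # bp per coverage bin

__all__ = [
    "SimulationConfig",
    "SimulatedContrasts",
    "SimulatedEpigenome",
    "make_contrasts",
    "make_epigenome",
    "make_cofactor_catalog",
    "make_null_factor",
    "make_cohort",
    "simulate_bundle",
]


@dataclass
class SimulationConfig:
    """All knobs of the synthetic study, with the study's conditions as defaults."""

    seed: int = 0

    # contrast design
    n_genes: int = 10_000
    n_canonical: int = 87
    n_specific: int = 36
    kd_effect: float = 2.0        # |log2fc| of responsive genes
    effect_sd: float = 0.4
    alpha: float = 0.05
    flip_fraction: float = 0.0    # fraction of genes with one corrupted call

    # epigenome design
    n_enhancers: int = 200
    dependent_fraction: float = 2.0 / 3.0
    kd_signal_ratio: float = 0.4  # true kd/control signal at dependent enhancers
    peak_rate: float = 0.1        # per-base control coverage inside peaks
    background_rate: float = 0.02
    min_peak_width: int = 500
    max_peak_width: int = 2000
    coverage_noise: bool = True   # Poisson read noise; off = exact rates
    n_direct_canonical: int = 77
    n_direct_specific: int = 21
    n_h3k27ac_only: int = 20
    n_tf_only: int = 20
    n_null_genes_annotated: int = 100

    # cofactor catalog (target base-pair Jaccard per factor)
    cofactor_jaccards: dict[str, float] = field(
        default_factory=lambda: {"GATA3": 0.6, "MAFK": 0.4, "PBX3": 0.2, "CEBPB": 0.05}
    )

    # tumor cohort
    cohort_size: int = 503
    signature_effect: float = 1.0
    query_effect: float = 1.0
    noise_sd: float = 1.0
    n_correlated_candidates: int = 13
    n_cohort_null_genes: int = 50

    def __post_init__(self):
        if self.n_canonical + self.n_specific > self.n_genes:
            raise ValueError("planted gene counts exceed total gene count")
        if not 0 <= self.dependent_fraction <= 1:
            raise ValueError("dependent_fraction must be in [0, 1]")
        if not 0 <= self.flip_fraction < 1:
            raise ValueError("flip_fraction must be in [0, 1)")
        for name, j in self.cofactor_jaccards.items():
            if not 0 <= j <= 1:
                raise ValueError(f"target jaccard for {name} must be in [0, 1]")


def gene_universe(config: SimulationConfig) -> dict[str, list[str]]:
    """Deterministic gene id lists for the three planted classes.

    The first canonical ids reuse the six signature gene names and the first
    specific id is the exemplar NOTCH3, so that the cohort and epigenome
    generators can share the naming.
    """
    canonical = list(DEFAULT_SIGNATURE[: config.n_canonical])
    canonical += [f"CANON{i:03d}" for i in range(len(canonical) + 1, config.n_canonical + 1)]
    specific = ["NOTCH3"][: config.n_specific]
    specific += [f"SPEC{i:03d}" for i in range(2, config.n_specific + 1)]
    n_null = config.n_genes - config.n_canonical - config.n_specific
    null = [f"NULL{i:05d}" for i in range(1, n_null + 1)]
    return {"canonical": canonical, "specific": specific, "null": null}


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

@dataclass
class SimulatedContrasts:
    kd_tables: list[ContrastTable]
    ind_tables: list[ContrastTable]
    truth: pd.DataFrame   # gene_id, true_class
    flips: pd.DataFrame   # gene_id, context


def _responsive_p(rng: np.random.Generator, n: int, alpha: float) -> np.ndarray:
    p = rng.beta(0.1, 20.0, size=n)
    high = p >= alpha
    p[high] = rng.uniform(0.0, alpha, size=int(high.sum()))
    return p


def _null_p(rng: np.random.Generator, n: int, alpha: float) -> np.ndarray:
    return alpha + (1.0 - alpha) * rng.uniform(0.0, 1.0, size=n)


def make_contrasts(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> SimulatedContrasts:
    """Three knockdown and two induction contrast tables with planted classes.

    Canonical genes are significantly down in every knockdown table and up in
    at least one induction table (roughly half respond in both normal
    contexts, the rest in one); specific genes are down in every knockdown
    table and unresponsive to induction; null genes are unresponsive
    everywhere.  ``flip_fraction`` corrupts that fraction of genes by
    toggling the gene's call in one uniformly chosen table.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ids = gene_universe(config)
    genes = ids["canonical"] + ids["specific"] + ids["null"]
    n = len(genes)
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "true_class": (
                ["canonical"] * len(ids["canonical"])
                + ["specific"] * len(ids["specific"])
                + ["null"] * len(ids["null"])
            ),
        }
    )

    is_common = np.zeros(n, dtype=bool)
    is_common[: config.n_canonical + config.n_specific] = True
    # induction membership of canonical genes: both / first / second context
    ind_member = np.zeros((n, len(IND_CONTEXTS)), dtype=bool)
    choice = rng.choice(3, size=config.n_canonical, p=[0.5, 0.25, 0.25])
    ind_member[: config.n_canonical, 0] = (choice == 0) | (choice == 1)
    ind_member[: config.n_canonical, 1] = (choice == 0) | (choice == 2)

    responsive_by_table: list[np.ndarray] = [is_common.copy() for _ in KD_CONTEXTS]
    responsive_by_table += [ind_member[:, j].copy() for j in range(len(IND_CONTEXTS))]
    contexts = list(KD_CONTEXTS) + list(IND_CONTEXTS)

    flips_rows = []
    if config.flip_fraction > 0:
        n_flip = int(round(config.flip_fraction * n))
        victims = rng.choice(n, size=n_flip, replace=False)
        tables = rng.integers(0, len(contexts), size=n_flip)
        for gi, ti in zip(victims, tables):
            responsive_by_table[ti][gi] = ~responsive_by_table[ti][gi]
            flips_rows.append((genes[gi], contexts[ti]))
    flips = pd.DataFrame(flips_rows, columns=["gene_id", "context"])

    def build(context: str, kind: str, resp: np.ndarray) -> ContrastTable:
        sign = -1.0 if kind == KNOCKDOWN else 1.0
        p = _null_p(rng, n, config.alpha)
        p[resp] = _responsive_p(rng, int(resp.sum()), config.alpha)
        lfc = rng.normal(0.0, 0.3, size=n)
        magnitudes = np.clip(
            np.abs(rng.normal(config.kd_effect, config.effect_sd, size=int(resp.sum()))),
            0.25,
            None,
        )
        lfc[resp] = sign * magnitudes
        df = pd.DataFrame({"log2fc": lfc, "p_adj": p}, index=pd.Index(genes, name="gene_id"))
        return ContrastTable(context=context, kind=kind, data=df)

    kd_tables = [
        build(ctx, KNOCKDOWN, responsive_by_table[i]) for i, ctx in enumerate(KD_CONTEXTS)
    ]
    ind_tables = [
        build(ctx, INDUCTION, responsive_by_table[len(KD_CONTEXTS) + j])
        for j, ctx in enumerate(IND_CONTEXTS)
    ]
    return SimulatedContrasts(kd_tables, ind_tables, truth, flips)


# ---------------------------------------------------------------------------
# epigenome
# ---------------------------------------------------------------------------

@dataclass
class SimulatedEpigenome:
    genome: GenomeModel
    genes: list[GeneAnnotation]
    tf_peaks: IntervalSet
    h3k27ac_peaks: IntervalSet
    control_track: CoverageTrack
    kd_track: CoverageTrack
    truth: pd.DataFrame  # chrom, start, end, kind, dependent, gene_id
    exemplar_gene: Optional[str]


def _round_bin(x: int) -> int:
    return int(round(x / BIN) * BIN)


def make_epigenome(
    config: SimulationConfig,
    classes: Optional[dict[str, list[str]]] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedEpigenome:
    """Synthetic genome, peaks and paired coverage tracks.

    Two modes share the same slot-based layout (one feature per fixed-size
    slot, which keeps nearest-TSS assignment unambiguous):

    * without ``classes``: ``n_enhancers`` TF-bound H3K27ac peaks on two
      gene-free chromosomes, a ``dependent_fraction`` of them with true
      knockdown/control signal ratio ``kd_signal_ratio`` — the dependency-
      recovery benchmark;
    * with ``classes`` (the contrast generator's canonical/specific/null
      lists): classified genes get TSS slots on chromosome 1;
      ``n_direct_canonical``/``n_direct_specific`` of them get dependent
      TF-bound enhancers a few kb upstream, ten canonical genes get
      TF-bound but independent enhancers, and the exemplar specific gene
      (NOTCH3) gets its dependent enhancer ~10 kb upstream of the TSS.
      Unassigned enhancers and mark-only peaks live on a gene-free
      chromosome 2 so they cannot be attributed to any gene.

    Coverage is Poisson-sampled per 10-bp bin around the true per-base rates
    (``coverage_noise=False`` emits the exact rates).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng

    genes: list[GeneAnnotation] = []
    enh_rows: list[tuple] = []   # chrom, start, end, kind, dependent, gene_id
    tf_ivs: list[GenomicInterval] = []
    mark_ivs: list[GenomicInterval] = []
    exemplar: Optional[str] = None

    def place_enhancer(chrom: str, slot_start: int, dependent: bool, gene_id: str = "",
                       tss_offset: Optional[int] = None, distal: bool = False) -> None:
        """One enhancer inside a slot; optionally anchored upstream of a TSS."""
        width = _round_bin(int(rng.integers(config.min_peak_width, config.max_peak_width + 1)))
        if tss_offset is None:
            lo = slot_start + 2000
            hi = slot_start + SLOT - 2000 - width
            start = _round_bin(int(rng.integers(lo, hi + 1)))
        elif distal:
            # exemplar: enhancer ends ~9.5 kb upstream of the TSS
            end = slot_start + tss_offset - 9500
            start = end - width
            start, end = _round_bin(start), _round_bin(end)
            width = end - start
            mark_ivs.append(GenomicInterval(chrom, start, end, gene_id or None))
            tf_center = (start + end) // 2
            tf_ivs.append(GenomicInterval(chrom, _round_bin(tf_center - 100), _round_bin(tf_center + 100)))
            enh_rows.append((chrom, start, end, "enhancer", dependent, gene_id))
            return
        else:
            gap = _round_bin(int(rng.integers(200, 501)))
            end = slot_start + tss_offset - gap
            start = end - width
        end = start + width
        mark_ivs.append(GenomicInterval(chrom, start, end, gene_id or None))
        tf_center = (start + end) // 2
        tf_ivs.append(GenomicInterval(chrom, _round_bin(tf_center - 100), _round_bin(tf_center + 100)))
        enh_rows.append((chrom, start, end, "enhancer", dependent, gene_id))

    if classes is None:
        # --- dependency-recovery mode: enhancers only -----------------------
        n = config.n_enhancers
        per_chrom = (n + 1) // 2
        chrom_lengths = {"chr1": per_chrom * SLOT, "chr2": (n - per_chrom) * SLOT}
        chrom_lengths = {c: max(L, SLOT) for c, L in chrom_lengths.items() if L > 0}
        n_dep = int(round(config.dependent_fraction * n))
        dep_flags = np.zeros(n, dtype=bool)
        dep_flags[rng.choice(n, size=n_dep, replace=False)] = True
        slot_idx = 0
        for chrom, L in chrom_lengths.items():
            for s in range(0, L, SLOT):
                if slot_idx >= n:
                    break
                place_enhancer(chrom, s, bool(dep_flags[slot_idx]))
                slot_idx += 1
    else:
        canonical = list(classes["canonical"])
        specific = list(classes["specific"])
        null_genes = list(classes.get("null", []))[: config.n_null_genes_annotated]
        if config.n_direct_canonical > len(canonical):
            raise ValueError("n_direct_canonical exceeds canonical gene count")
        if config.n_direct_specific > len(specific):
            raise ValueError("n_direct_specific exceeds specific gene count")

        # which genes get which enhancer type (exemplar always direct)
        exemplar = specific[0] if specific else None
        can_perm = [canonical[i] for i in rng.permutation(len(canonical))]
        direct_can = set(can_perm[: config.n_direct_canonical])
        indep_can = set(can_perm[config.n_direct_canonical:][:10])
        spc_rest = [g for g in specific[1:]]
        spc_perm = [spc_rest[i] for i in rng.permutation(len(spc_rest))]
        direct_spc = set(spc_perm[: max(0, config.n_direct_specific - 1)])
        if exemplar is not None and config.n_direct_specific > 0:
            direct_spc.add(exemplar)

        n_linked = len(direct_can) + len(indep_can) + len(direct_spc)
        n_unlinked = config.n_enhancers - n_linked
        if n_unlinked < 0:
            raise ValueError("n_enhancers smaller than the gene-linked enhancer count")
        n_dep_total = int(round(config.dependent_fraction * config.n_enhancers))
        n_dep_unlinked = n_dep_total - len(direct_can) - len(direct_spc)
        if not 0 <= n_dep_unlinked <= n_unlinked:
            raise ValueError(
                "dependent_fraction incompatible with the planted direct-target counts"
            )

        # chromosome 1: one slot per annotated gene (shuffled order)
        gene_order = canonical + specific + null_genes
        gene_order = [gene_order[i] for i in rng.permutation(len(gene_order))]
        cursor = 0
        for g in gene_order:
            slot = NOTCH3_SLOT if g == exemplar else SLOT
            tss_offset = 25_000 if g == exemplar else 6_000
            tss = cursor + tss_offset
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            genes.append(GeneAnnotation(g, "chr1", tss, strand))
            if g == exemplar and config.n_direct_specific > 0:
                place_enhancer("chr1", cursor, True, g, tss_offset, distal=True)
            elif g in direct_can or g in direct_spc:
                place_enhancer("chr1", cursor, True, g, tss_offset)
            elif g in indep_can:
                place_enhancer("chr1", cursor, False, g, tss_offset)
            cursor += slot
        chr1_len = cursor + SLOT

        # chromosome 2: unlinked enhancers and mark-only / TF-only peaks
        n_slots2 = n_unlinked + config.n_h3k27ac_only + config.n_tf_only
        chr2_len = max(n_slots2 * SLOT + SLOT, SLOT)
        dep_flags = np.zeros(n_unlinked, dtype=bool)
        if n_dep_unlinked > 0:
            dep_flags[rng.choice(n_unlinked, size=n_dep_unlinked, replace=False)] = True
        cursor2 = 0
        for i in range(n_unlinked):
            place_enhancer("chr2", cursor2, bool(dep_flags[i]))
            cursor2 += SLOT
        for _ in range(config.n_h3k27ac_only):
            width = _round_bin(int(rng.integers(config.min_peak_width, config.max_peak_width + 1)))
            start = _round_bin(cursor2 + 2000)
            mark_ivs.append(GenomicInterval("chr2", start, start + width))
            enh_rows.append(("chr2", start, start + width, "mark_only", False, ""))
            cursor2 += SLOT
        for _ in range(config.n_tf_only):
            start = _round_bin(cursor2 + 4000)
            tf_ivs.append(GenomicInterval("chr2", start, start + 200))
            enh_rows.append(("chr2", start, start + 200, "tf_only", False, ""))
            cursor2 += SLOT
        chrom_lengths = {"chr1": chr1_len, "chr2": chr2_len}

    genome = GenomeModel(chrom_lengths)
    truth = pd.DataFrame(
        enh_rows, columns=["chrom", "start", "end", "kind", "dependent", "gene_id"]
    )

    # --- coverage ----------------------------------------------------------
    control_steps: list[tuple[str, int, int, float]] = []
    kd_steps: list[tuple[str, int, int, float]] = []
    for chrom, L in chrom_lengths.items():
        n_bins = L // BIN
        control_rate = np.full(n_bins, config.background_rate)
        kd_rate = np.full(n_bins, config.background_rate)
        sub = truth[(truth["chrom"] == chrom) & (truth["kind"] != "tf_only")]
        for _, row in sub.iterrows():
            b0, b1 = row["start"] // BIN, row["end"] // BIN
            control_rate[b0:b1] = config.peak_rate
            ratio = config.kd_signal_ratio if row["dependent"] else 1.0
            kd_rate[b0:b1] = config.peak_rate * ratio
        for rate, steps in ((control_rate, control_steps), (kd_rate, kd_steps)):
            if config.coverage_noise:
                values = rng.poisson(rate * BIN).astype(float) / BIN
            else:
                values = rate.copy()
            nz = np.flatnonzero(values > 0)
            for b in nz:
                steps.append((chrom, int(b) * BIN, (int(b) + 1) * BIN, float(values[b])))

    return SimulatedEpigenome(
        genome=genome,
        genes=genes,
        tf_peaks=IntervalSet(tf_ivs, genome),
        h3k27ac_peaks=IntervalSet(mark_ivs, genome),
        control_track=CoverageTrack(control_steps),
        kd_track=CoverageTrack(kd_steps),
        truth=truth,
        exemplar_gene=exemplar,
    )


# ---------------------------------------------------------------------------
# cofactor catalog
# ---------------------------------------------------------------------------

def _complement(reference: IntervalSet, genome: GenomeModel) -> list[GenomicInterval]:
    out = []
    merged = reference.merge()
    for chrom, L in genome.chromosomes.items():
        starts, ends = merged.arrays(chrom)
        cursor = 0
        for s, e in zip(starts, ends):
            if s > cursor:
                out.append(GenomicInterval(chrom, cursor, int(s)))
            cursor = int(e)
        if cursor < L:
            out.append(GenomicInterval(chrom, cursor, L))
    return out


def make_cofactor_catalog(
    config: SimulationConfig,
    reference: IntervalSet,
    genome: GenomeModel,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, IntervalSet], pd.DataFrame]:
    """Peak sets with planted base-pair Jaccard against the reference.

    For a target Jaccard j, a factor copies c = 2Bj/(1+j) bases of the
    reference (B = reference bases) and adds B - c disjoint filler bases
    drawn from the reference's complement, so the factor's footprint equals
    the reference's and the realized Jaccard is c/(2B - c) = j up to
    rounding.  Truth records the realized value.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    B = reference.total_bases()
    if B == 0:
        raise ValueError("reference set is empty")
    merged_ref = list(reference.merge())
    free = _complement(reference, genome)
    free_total = sum(len(iv) for iv in free)

    catalog: dict[str, IntervalSet] = {}
    rows = []
    for name in config.cofactor_jaccards:
        j = config.cofactor_jaccards[name]
        c = int(round(2 * B * j / (1 + j)))
        f = B - c
        if f > free_total:
            raise ValueError(f"not enough reference-free space for factor {name}")
        ivs: list[GenomicInterval] = []
        # copy a prefix of the (shuffled) reference until c bases are taken
        order = rng.permutation(len(merged_ref))
        taken = 0
        for idx in order:
            if taken >= c:
                break
            iv = merged_ref[idx]
            keep = min(len(iv), c - taken)
            ivs.append(GenomicInterval(iv.chrom, iv.start, iv.start + keep))
            taken += keep
        # contiguous filler from a random starting point in the complement
        if f > 0:
            start_at = int(rng.integers(0, len(free)))
            remaining = f
            for k in range(len(free)):
                iv = free[(start_at + k) % len(free)]
                if len(iv) <= 2:  # keep a base of slack so filler never abuts reference
                    continue
                take = min(len(iv) - 2, remaining)
                ivs.append(GenomicInterval(iv.chrom, iv.start + 1, iv.start + 1 + take))
                remaining -= take
                if remaining == 0:
                    break
            if remaining > 0:
                raise ValueError(f"not enough filler space for factor {name}")
        iset = IntervalSet(ivs, genome)
        from .coloc import jaccard_index

        realized = jaccard_index(iset, reference)
        catalog[name] = iset
        rows.append((name, j, realized))
    truth = pd.DataFrame(rows, columns=["factor", "target_jaccard", "realized_jaccard"])
    return catalog, truth


def make_null_factor(
    genome: GenomeModel,
    n_intervals: int = 100,
    width: int = 1000,
    rng: Optional[np.random.Generator] = None,
    seed: int = 0,
) -> IntervalSet:
    """A factor with no planted relationship to anything: uniform placement.

    Built by the same repositioning process as the permutation null, so its
    observed Jaccard against any reference is exchangeable with the
    permutation draws.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    chroms = list(genome.chromosomes.items())
    lengths = np.array([L for _, L in chroms], dtype=float)
    probs = lengths / lengths.sum()
    ivs = []
    for _ in range(n_intervals):
        ci = int(rng.choice(len(chroms), p=probs))
        chrom, L = chroms[ci]
        start = int(rng.integers(0, L - width + 1))
        ivs.append(GenomicInterval(chrom, start, start + width))
    return IntervalSet(ivs, genome)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------

def make_cohort(
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Expression cohort driven by a latent activity variable.

    Samples draw activity ~ N(0,1).  Signature genes follow
    a*activity + noise, the query gene (the exemplar NOTCH3) follows
    b*activity + noise, and so do the planted activity-correlated candidate
    genes; the remaining candidates and the null genes are pure noise.

    Returns (matrix, sample_truth, gene_truth).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if config.cohort_size < 10:
        raise ValueError("cohort size must be at least 10")
    ids = gene_universe(config)
    signature = list(DEFAULT_SIGNATURE)
    candidates = ids["specific"]
    null_genes = [f"CNULL{i:04d}" for i in range(1, config.n_cohort_null_genes + 1)]

    n_corr = config.n_correlated_candidates
    if n_corr > len(candidates):
        raise ValueError("n_correlated_candidates exceeds candidate count")
    # the exemplar (first candidate) is always correlated when any are
    others = candidates[1:]
    perm = [others[i] for i in rng.permutation(len(others))]
    correlated = set(candidates[:1][: min(1, n_corr)]) | set(perm[: max(0, n_corr - 1)])

    samples = [f"TCGA{i:04d}" for i in range(1, config.cohort_size + 1)]
    activity = rng.normal(0.0, 1.0, size=config.cohort_size)

    rows = {}
    for g in signature:
        rows[g] = (
            rng.normal(5.0, 1.0)
            + config.signature_effect * activity
            + rng.normal(0.0, config.noise_sd, size=config.cohort_size)
        )
    for g in candidates:
        effect = config.query_effect if g in correlated else 0.0
        rows[g] = (
            rng.normal(5.0, 1.0)
            + effect * activity
            + rng.normal(0.0, config.noise_sd, size=config.cohort_size)
        )
    for g in null_genes:
        rows[g] = rng.normal(5.0, 1.0) + rng.normal(0.0, config.noise_sd, size=config.cohort_size)

    matrix = pd.DataFrame(rows, index=samples).T
    matrix.index.name = "gene_id"
    sample_truth = pd.DataFrame({"sample_id": samples, "activity": activity})
    gene_truth = pd.DataFrame(
        {
            "gene_id": signature + candidates + null_genes,
            "role": (
                ["signature"] * len(signature)
                + ["candidate"] * len(candidates)
                + ["null"] * len(null_genes)
            ),
            "activity_correlated": (
                [True] * len(signature)
                + [g in correlated for g in candidates]
                + [False] * len(null_genes)
            ),
        }
    )
    return matrix, sample_truth, gene_truth


# ---------------------------------------------------------------------------
# bundle writer
# ---------------------------------------------------------------------------

def simulate_bundle(config: SimulationConfig, outdir: Path) -> dict:
    """Generate every input of the end-to-end pipeline into ``outdir``.

    Writes contrast tables, genome/annotation, peak BEDs, coverage
    bedGraphs, cofactor BEDs, the cohort matrix, a signature list, the
    ground-truth tables (under ``ground_truth/``) and a ready-to-run
    ``pipeline.yaml``.  Returns a manifest of the written paths.
    """
    import yaml

    from . import io as cio
    from .coloc import reference_set

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth_dir = outdir / "ground_truth"
    truth_dir.mkdir(exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    rng_contrasts, rng_epi, rng_cof, rng_cohort = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    contrasts = make_contrasts(config, rng_contrasts)
    classes = gene_universe(config)
    epi = make_epigenome(config, classes, rng_epi)
    reference = reference_set(epi.tf_peaks, epi.h3k27ac_peaks)
    catalog, cof_truth = make_cofactor_catalog(config, reference, epi.genome, rng_cof)
    cohort, sample_truth, gene_truth = make_cohort(config, rng_cohort)

    manifest: dict = {"outdir": str(outdir)}
    kd_paths, ind_paths = [], []
    for t in contrasts.kd_tables:
        p = outdir / f"kd_{t.context}.tsv"
        t.to_file(p)
        kd_paths.append(p.name)
    for t in contrasts.ind_tables:
        p = outdir / f"ind_{t.context}.tsv"
        t.to_file(p)
        ind_paths.append(p.name)

    cio.write_genome_table(epi.genome, outdir / "genome.tsv")
    cio.write_gene_annotation(epi.genes, outdir / "genes.tsv")
    cio.write_bed(epi.tf_peaks, outdir / "tf_peaks.bed")
    cio.write_bed(epi.h3k27ac_peaks, outdir / "h3k27ac_peaks.bed")
    cio.write_bedgraph(epi.control_track, outdir / "control.bdg")
    cio.write_bedgraph(epi.kd_track, outdir / "kd.bdg")

    cof_dir = outdir / "cofactors"
    cof_dir.mkdir(exist_ok=True)
    for name, iset in catalog.items():
        cio.write_bed(iset, cof_dir / f"{name}.bed")

    cio.write_expression_matrix(cohort, outdir / "cohort.tsv")
    with open(outdir / "signature.txt", "w") as fh:
        fh.write("\n".join(DEFAULT_SIGNATURE) + "\n")

    contrasts.truth.to_csv(truth_dir / "gene_classes.tsv", sep="\t", index=False)
    contrasts.flips.to_csv(truth_dir / "flips.tsv", sep="\t", index=False)
    epi.truth.to_csv(truth_dir / "enhancers.tsv", sep="\t", index=False)
    cof_truth.to_csv(truth_dir / "cofactors.tsv", sep="\t", index=False, float_format="%.6g")
    sample_truth.to_csv(truth_dir / "cohort_samples.tsv", sep="\t", index=False, float_format="%.10g")
    gene_truth.to_csv(truth_dir / "cohort_genes.tsv", sep="\t", index=False)

    pipeline_cfg = {
        "genome": "genome.tsv",
        "gene_annotation": "genes.tsv",
        "knockdown_contrasts": {
            t.context: p for t, p in zip(contrasts.kd_tables, kd_paths)
        },
        "induction_contrasts": {
            t.context: p for t, p in zip(contrasts.ind_tables, ind_paths)
        },
        "tf_peaks": "tf_peaks.bed",
        "h3k27ac_peaks": "h3k27ac_peaks.bed",
        "control_track": "control.bdg",
        "kd_track": "kd.bdg",
        "cofactors": {name: f"cofactors/{name}.bed" for name in catalog},
        "expression_matrix": "cohort.tsv",
        "signature_genes": list(DEFAULT_SIGNATURE),
        "query_gene": epi.exemplar_gene or "NOTCH3",
        "params": {
            "alpha": config.alpha,
            "dependency_threshold": -0.5,
            "pseudocount": 1.0,
            "window": 100_000,
            "n_groups": 3,
            "n_perm": 999,
            "seed": int(config.seed),
            "correlation_method": "spearman",
            "correlation_threshold": 0.3,
        },
    }
    with open(outdir / "pipeline.yaml", "w") as fh:
        yaml.safe_dump(pipeline_cfg, fh, sort_keys=False)
    manifest["pipeline_config"] = str(outdir / "pipeline.yaml")
    return manifest
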