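"""Readers and writers for the plain-text formats the pipeline consumes.

BED and bedGraph parsing is strict on purpose: malformed coordinates raise
with the offending line number, unknown chromosomes raise with the name, and
overlapping bedGraph steps are rejected rather than summed — silent repair
of upstream peak-caller output hides real errors.

Floats are written with ``repr`` so that round-trips are lossless.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .genome import (
    CoverageTrack,
    GeneAnnotation,
    GenomeModel,
    GenomicInterval,
    IntervalSet,
)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """A malformed line in a text genomic format."""


def _fmt(x: float) -> str:
    r = repr(float(x))
    return r[:-2] if r.endswith(".0") else r


# ---------------------------------------------------------------------------
# genome table
# ---------------------------------------------------------------------------

def read_genome_table(path: PathLike) -> GenomeModel:
    """Two-column TSV: chromosome name, length."""
    chroms: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns")
            try:
                chroms[fields[0]] = int(fields[1])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer length {fields[1]!r}")
    return GenomeModel(chroms)


def write_genome_table(genome: GenomeModel, path: PathLike) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chromosomes.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: PathLike, genome: GenomeModel) -> IntervalSet:
    """Read a 3+ column BED file into a sorted IntervalSet.

    Column 4 (name) and column 5 (score) are captured when present; further
    columns are ignored.  A ``.`` placeholder means absent.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates")
            if start < 0 or start >= end:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval {chrom}:{start}-{end}"
                )
            if chrom not in genome:
                raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if end > genome.length_of(chrom):
                raise ParseError(
                    f"{path}:{lineno}: interval end {end} exceeds length of {chrom}"
                )
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: Optional[float] = None
            if len(fields) > 4 and fields[4] != ".":
                try:
                    score = float(fields[4])
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-numeric score {fields[4]!r}")
            intervals.append(GenomicInterval(chrom, start, end, name, score))
    return IntervalSet(intervals, genome)


def write_bed(intervals: IntervalSet, path: PathLike) -> None:
    """Write BED with as many columns as the set actually uses (3, 4 or 5)."""
    any_name = any(iv.name is not None for iv in intervals)
    any_score = any(iv.score is not None for iv in intervals)
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if any_name or any_score:
                fields.append(iv.name if iv.name is not None else ".")
            if any_score:
                fields.append(_fmt(iv.score) if iv.score is not None else ".")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# bedGraph
# ---------------------------------------------------------------------------

def read_bedgraph(path: PathLike, genome: GenomeModel) -> CoverageTrack:
    """Read a 4-column bedGraph into a CoverageTrack (strict dialect).

    Negative values and overlapping steps are errors.
    """
    steps = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 bedGraph columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: malformed step")
            if start < 0 or start >= end:
                raise ParseError(f"{path}:{lineno}: invalid step {chrom}:{start}-{end}")
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative value {value}")
            if chrom not in genome:
                raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if end > genome.length_of(chrom):
                raise ParseError(f"{path}:{lineno}: step end {end} exceeds length of {chrom}")
            steps.append((chrom, start, end, value))
    try:
        return CoverageTrack(steps)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_bedgraph(track: CoverageTrack, path: PathLike) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.steps():
            fh.write(f"{chrom}\t{start}\t{end}\t{_fmt(value)}\n")


# ---------------------------------------------------------------------------
# gene annotation
# ---------------------------------------------------------------------------

def read_gene_annotation(path: PathLike, genome: GenomeModel) -> list[GeneAnnotation]:
    """Read gene loci from a headered TSV or a BED6 file.

    TSV columns: gene_id, chrom, tss, strand (header required).  BED6 input
    derives the TSS from the strand: start for ``+``, end-1 for ``-``.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("gene_id"):
        genes = []
        seen = set()
        with open(path) as fh:
            next(fh)
            for lineno, line in enumerate(fh, 2):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ParseError(f"{path}:{lineno}: expected 4 columns")
                gene_id, chrom, tss, strand = fields[:4]
                if gene_id in seen:
                    raise ParseError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
                seen.add(gene_id)
                if chrom not in genome:
                    raise ParseError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                try:
                    tss_i = int(tss)
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-integer TSS {tss!r}")
                if not 0 <= tss_i < genome.length_of(chrom):
                    raise ParseError(f"{path}:{lineno}: TSS {tss_i} outside {chrom}")
                genes.append(GeneAnnotation(gene_id, chrom, tss_i, strand))
        return genes
    # BED6
    bed = read_bed(path, genome)
    genes = []
    with open(path) as fh:
        strands = {}
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 6:
                strands[(fields[0], int(fields[1]), int(fields[2]))] = fields[5]
    seen = set()
    for iv in bed:
        if iv.name is None:
            raise ParseError(f"{path}: BED gene annotation requires a name column")
        if iv.name in seen:
            raise ParseError(f"{path}: duplicate gene id {iv.name!r}")
        seen.add(iv.name)
        strand = strands.get((iv.chrom, iv.start, iv.end), "+")
        tss = iv.start if strand == "+" else iv.end - 1
        genes.append(GeneAnnotation(iv.name, iv.chrom, tss, strand))
    return genes


def write_gene_annotation(genes: Sequence[GeneAnnotation], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.strand}\n")


# ---------------------------------------------------------------------------
# tabular inputs (contrast tables, expression matrix)
# ---------------------------------------------------------------------------

def read_table(path: PathLike, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def read_expression_matrix(path: PathLike) -> pd.DataFrame:
    """Gene x sample TSV, first column gene_id, header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ParseError(f"{path}: duplicate gene id {dup!r}")
    if df.columns.has_duplicates:
        raise ParseError(f"{path}: duplicate sample ids")
    return df.astype(float)


def write_expression_matrix(matrix: pd.DataFrame, path: PathLike) -> None:
    matrix.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")
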