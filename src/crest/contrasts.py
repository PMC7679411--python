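"""Gene-set algebra over knockdown and induction differential-expression contrasts.

The classification mirrors the two-arm design used to separate canonical from
context-specific transcription-factor targets: genes consistently
*down*-regulated by TF knockdown in every constitutively-active cell context
form the common downstream set; genes *up*-regulated by a chemical inducer in
at least one normal context form the inducible set.  Their intersection is
the canonical class, the set difference the context-specific class.

Significance calls use Benjamini–Hochberg adjusted p-values with a strict
``p_adj < alpha`` cutoff and an enforced fold-change direction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import PathLike, read_table

KNOCKDOWN = "knockdown"
INDUCTION = "induction"

__all__ = [
    "ContrastTable",
    "GeneClassification",
    "bh_adjust",
    "responsive_genes",
    "common_downstream",
    "inducible_union",
    "classify",
    "correlation_filter",
]


@dataclass
class ContrastTable:
    """Per-gene differential statistics for one perturbation in one context.

    ``kind`` decides which direction counts as responsive downstream:
    knockdown -> log2fc < 0, induction -> log2fc > 0.
    """

    context: str
    kind: Literal["knockdown", "induction"]
    data: pd.DataFrame  # index gene_id, columns log2fc, p_adj

    def __post_init__(self):
        if self.kind not in (KNOCKDOWN, INDUCTION):
            raise ValueError(f"perturbation kind must be knockdown/induction, got {self.kind!r}")
        df = self.data
        for col in ("log2fc", "p_adj"):
            if col not in df.columns:
                raise ValueError(f"contrast table missing column {col!r}")
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r} in contrast table {self.context}")
        p = df["p_adj"].to_numpy(dtype=float)
        if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
            raise ValueError(f"p_adj outside [0,1] in contrast table {self.context}")

    @classmethod
    def from_file(cls, path: PathLike, context: str, kind: str) -> "ContrastTable":
        df = read_table(path, ["gene_id", "log2fc", "p_adj"]).set_index("gene_id")
        return cls(context=context, kind=kind, data=df[["log2fc", "p_adj"]])

    def to_file(self, path: PathLike) -> None:
        self.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


@dataclass(frozen=True)
class GeneClassification:
    """Partition of the common downstream set into canonical and specific genes."""

    common_downstream: frozenset[str]
    inducible: frozenset[str]
    canonical: frozenset[str]
    specific: frozenset[str]

    def __post_init__(self):
        if self.canonical | self.specific != self.common_downstream:
            raise ValueError("canonical and specific must partition the common set")
        if self.canonical & self.specific:
            raise ValueError("canonical and specific must be disjoint")

    def class_of(self, gene: str) -> Optional[str]:
        if gene in self.canonical:
            return "canonical"
        if gene in self.specific:
            return "specific"
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, "canonical") for g in sorted(self.canonical)]
        rows += [(g, "specific") for g in sorted(self.specific)]
        return pd.DataFrame(rows, columns=["gene_id", "class"])


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def responsive_genes(table: ContrastTable, alpha: float = 0.05) -> set[str]:
    """Genes significantly changed in the responsive direction.

    Strict inequalities on both conditions: ``p_adj < alpha`` and a fold
    change strictly below (knockdown) or above (induction) zero.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = table.data
    sig = df["p_adj"] < alpha
    if table.kind == KNOCKDOWN:
        direction = df["log2fc"] < 0
    else:
        direction = df["log2fc"] > 0
    return set(df.index[sig & direction])


def _check_kinds(tables: Sequence[ContrastTable], kind: str) -> None:
    if not tables:
        raise ValueError("at least one contrast table is required")
    bad = [t.context for t in tables if t.kind != kind]
    if bad:
        raise ValueError(f"expected only {kind} tables, got other kinds in {bad}")


def common_downstream(kd_tables: Sequence[ContrastTable], alpha: float = 0.05) -> set[str]:
    """Genes downregulated by knockdown in *every* supplied context."""
    _check_kinds(kd_tables, KNOCKDOWN)
    sets = [responsive_genes(t, alpha) for t in kd_tables]
    return set.intersection(*sets)


def inducible_union(ind_tables: Sequence[ContrastTable], alpha: float = 0.05) -> set[str]:
    """Genes upregulated by induction in *at least one* supplied context."""
    _check_kinds(ind_tables, INDUCTION)
    sets = [responsive_genes(t, alpha) for t in ind_tables]
    return set.union(*sets)


def classify(common: set[str], inducible: set[str]) -> GeneClassification:
    """Split the common downstream set by membership in the inducible set."""
    common_f = frozenset(common)
    inducible_f = frozenset(inducible)
    return GeneClassification(
        common_downstream=common_f,
        inducible=inducible_f,
        canonical=common_f & inducible_f,
        specific=common_f - inducible_f,
    )


def correlation_filter(
    candidates: Iterable[str],
    cohort: pd.DataFrame,
    scores: Union[pd.Series, "object"],
    method: Literal["pearson", "spearman"] = "spearman",
    threshold: float = 0.3,
) -> tuple[pd.DataFrame, list[str]]:
    """Keep candidate genes whose cohort expression tracks the activity score.

    Parameters
    ----------
    candidates : gene ids to test.
    cohort : gene x sample expression matrix.
    scores : per-sample activity scores (a Series aligned to cohort samples,
        or an ActivityScores object).
    method : correlation statistic; rank correlation is the default because
        it is robust to the cohort's expression scale.
    threshold : minimum correlation to retain a gene.

    Returns
    -------
    (table, skipped) : table has columns gene_id, correlation, sorted by
        descending correlation, retaining only correlations >= threshold;
        skipped lists genes absent from the cohort or with zero variance.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    score_series = getattr(scores, "scores", scores)
    score_series = score_series.reindex(cohort.columns)
    if score_series.isna().any():
        raise ValueError("activity scores are not aligned to cohort samples")
    if cohort.shape[1] < 3:
        raise ValueError("correlation requires at least 3 samples")
    s = score_series.to_numpy(dtype=float)
    rows = []
    skipped: list[str] = []
    for gene in candidates:
        if gene not in cohort.index:
            skipped.append(gene)
            continue
        x = cohort.loc[gene].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(s) == 0:
            warnings.warn(f"gene {gene!r} has zero variance; skipped from correlation filter")
            skipped.append(gene)
            continue
        if method == "pearson":
            r = float(stats.pearsonr(x, s).statistic)
        else:
            r = float(stats.spearmanr(x, s).statistic)
        rows.append((gene, r))
    table = pd.DataFrame(rows, columns=["gene_id", "correlation"])
    table = table[table["correlation"] >= threshold]
    table = table.sort_values(
        ["correlation", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
    return table, skipped
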