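"""Signature-based TF activity scoring and small-table statistics.

A tumor sample's activity score is the mean of z-scored expression of a small
signature of direct target genes (default: the six-gene NRF2 signature NQO1,
SLC7A11, GCLC, GCLM, TXNRD1, NR0B1).  Samples are then stratified into
quantile groups of the score and a query gene is compared across strata with
one-way ANOVA plus Bonferroni-adjusted pairwise t-tests.  The 2x2 chi-square
and Pearson correlation helpers mirror the clinical association analyses.

Standard deviations use the n-1 denominator throughout (cohort-sample
semantics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_SIGNATURE = ("NQO1", "SLC7A11", "GCLC", "GCLM", "TXNRD1", "NR0B1")

__all__ = [
    "DEFAULT_SIGNATURE",
    "ActivityScores",
    "AnovaResult",
    "zscore_by_gene",
    "activity_score",
    "stratify",
    "anova_oneway",
    "chi_square_2x2",
    "pearson_r",
]


@dataclass
class ActivityScores:
    """Per-sample signature scores, optionally with ordinal strata (1 = lowest)."""

    scores: pd.Series
    strata: Optional[pd.Series] = None

    def __post_init__(self):
        if self.scores.index.has_duplicates:
            raise ValueError("duplicate sample ids in activity scores")
        if self.strata is not None and not self.strata.index.equals(self.scores.index):
            raise ValueError("strata must be indexed like the scores")

    @property
    def n_samples(self) -> int:
        return self.scores.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.scores.index, "score": self.scores.values})
        if self.strata is not None:
            df["stratum"] = self.strata.values
        return df


def zscore_by_gene(matrix: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene row to mean 0, sd 1 (n-1 denominator).

    Zero-variance rows become NaN rather than raising here; downstream
    consumers that actually request such a gene raise with its name.
    """
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("expression matrix contains non-finite values")
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (values - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = np.nan
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)


def activity_score(
    zmatrix: pd.DataFrame, signature: Sequence[str] = DEFAULT_SIGNATURE
) -> ActivityScores:
    """Per-sample mean of the signature genes' z-scores."""
    signature = list(signature)
    if not signature:
        raise ValueError("signature must contain at least one gene")
    missing = [g for g in signature if g not in zmatrix.index]
    if missing:
        raise KeyError(f"signature gene(s) missing from matrix: {missing}")
    sub = zmatrix.loc[signature]
    bad = sub.index[sub.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"zero-variance signature gene {bad[0]!r}")
    return ActivityScores(scores=sub.mean(axis=0))


def stratify(scores: ActivityScores, n_groups: int = 3) -> ActivityScores:
    """Assign quantile-based ordinal strata (1 = lowest activity).

    Samples are ranked by (score, sample id) — the id makes tie handling
    stable — and split into groups whose sizes differ by at most one.
    """
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    n = scores.n_samples
    if n_groups > n:
        raise ValueError(f"n_groups={n_groups} exceeds sample count {n}")
    order = sorted(scores.scores.index, key=lambda s: (scores.scores[s], str(s)))
    strata = pd.Series(0, index=scores.scores.index, dtype=int)
    for label, chunk in enumerate(np.array_split(np.asarray(order, dtype=object), n_groups), 1):
        strata[chunk] = label
    return ActivityScores(scores=scores.scores, strata=strata)


@dataclass
class AnovaResult:
    """Classical one-way ANOVA with Bonferroni-adjusted pairwise t-tests."""

    f_statistic: float
    p_value: float
    pairwise: list[tuple[int, int, float]] = field(default_factory=list)
    group_means: list[float] = field(default_factory=list)
    group_sizes: list[int] = field(default_factory=list)


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Between/within decomposition F-test across >= 2 groups.

    Bonferroni-adjusted two-sample t-test p-values (adjust factor = number of
    pairs) accompany the omnibus test.  Zero within-group variance is a
    degenerate design and raises.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("at least two groups are required")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValueError(f"group {i} has fewer than 2 values")
    pooled_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    if pooled_within == 0:
        raise ValueError("zero within-group variance: ANOVA undefined")
    res = stats.f_oneway(*arrays)
    n_pairs = len(arrays) * (len(arrays) - 1) // 2
    pairwise = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            t = stats.ttest_ind(arrays[i], arrays[j])
            pairwise.append((i, j, float(min(1.0, t.pvalue * n_pairs))))
    return AnovaResult(
        f_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        pairwise=pairwise,
        group_means=[float(g.mean()) for g in arrays],
        group_sizes=[int(g.size) for g in arrays],
    )


def chi_square_2x2(counts, yates: bool = False) -> tuple[float, float]:
    """Chi-square test of independence on a 2x2 count table.

    Uses the closed form N(|ad-bc| - c0)^2 / ((a+b)(c+d)(a+c)(b+d)) with
    c0 = N/2 under the Yates continuity correction, 0 otherwise; p from the
    chi-square distribution with 1 df.
    """
    t = np.asarray(counts, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("counts must be a 2x2 table")
    if np.any(t < 0) or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    a, b, c, d = t.ravel()
    n = t.sum()
    margins = [a + b, c + d, a + c, b + d]
    if any(m == 0 for m in margins):
        raise ValueError("zero marginal total: chi-square undefined")
    correction = n / 2 if yates else 0.0
    num = n * max(0.0, abs(a * d - b * c) - correction) ** 2
    statistic = num / np.prod(margins)
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with two-tailed p (t transform, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("correlation requires at least 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
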