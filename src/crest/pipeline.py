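"""End-to-end orchestration: classification -> enhancers -> targets -> colocalization -> activity.

The pipeline is configured by a single YAML file (paths resolved relative to
the file's own directory) and writes every intermediate table to the output
directory.  Reruns with identical configuration and inputs reproduce
identical output bytes; timestamps live only in ``run.log``.  A stage
failure writes a ``FAILED`` marker naming the stage and re-raises.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml

from . import io as cio
from .activity import activity_score, anova_oneway, stratify, zscore_by_gene
from .coloc import rank_cofactors, ranking_to_frame, reference_set
from .contrasts import (
    ContrastTable,
    classify,
    common_downstream,
    correlation_filter,
    inducible_union,
)
from .enhancers import call_direct_targets, call_enhancers, mann_whitney, normalize_track
from .genome import subtract_intervals

logger = logging.getLogger("crest")

__all__ = ["PipelineConfig", "RunReport", "StageError", "run_end_to_end"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Input paths and parameters of one end-to-end run."""

    genome: Path
    gene_annotation: Path
    knockdown_contrasts: dict[str, Path]
    induction_contrasts: dict[str, Path]
    tf_peaks: Path
    h3k27ac_peaks: Path
    control_track: Path
    kd_track: Path
    cofactors: dict[str, Path]
    expression_matrix: Path
    signature_genes: list[str]
    query_gene: str
    blacklist: Optional[Path] = None

    alpha: float = 0.05
    dependency_threshold: float = -0.5
    pseudocount: float = 1.0
    window: int = 100_000
    n_groups: int = 3
    n_perm: int = 999
    seed: int = 0
    correlation_method: str = "spearman"
    correlation_threshold: float = 0.3
    target_total: float = 1e6

    @classmethod
    def from_yaml(cls, path: Union[str, Path], overrides: Optional[dict] = None) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = path.parent

        def resolve(p):
            return (base / p).resolve() if p is not None else None

        params = dict(raw.get("params", {}))
        if overrides:
            params.update({k: v for k, v in overrides.items() if v is not None})
        signature = raw["signature_genes"]
        if isinstance(signature, str):
            with open(resolve(signature)) as fh:
                signature = [line.strip() for line in fh if line.strip()]
        return cls(
            genome=resolve(raw["genome"]),
            gene_annotation=resolve(raw["gene_annotation"]),
            knockdown_contrasts={k: resolve(v) for k, v in raw["knockdown_contrasts"].items()},
            induction_contrasts={k: resolve(v) for k, v in raw.get("induction_contrasts", {}).items()},
            tf_peaks=resolve(raw["tf_peaks"]),
            h3k27ac_peaks=resolve(raw["h3k27ac_peaks"]),
            control_track=resolve(raw["control_track"]),
            kd_track=resolve(raw["kd_track"]),
            cofactors={k: resolve(v) for k, v in raw.get("cofactors", {}).items()},
            expression_matrix=resolve(raw["expression_matrix"]),
            signature_genes=list(signature),
            query_gene=raw["query_gene"],
            blacklist=resolve(raw.get("blacklist")),
            **params,
        )


@dataclass
class RunReport:
    """Per-stage counts and results; serialized (without timing) to report.json."""

    params: dict = field(default_factory=dict)
    n_common: int = 0
    n_canonical: int = 0
    n_specific: int = 0
    degenerate_no_induction: bool = False
    n_filtered: int = 0
    filter_skipped: list[str] = field(default_factory=list)
    n_enhancer_calls: int = 0
    n_dependent: int = 0
    dependent_fraction: float = float("nan")
    n_direct_canonical: int = 0
    n_direct_specific: int = 0
    direct_contains_query: bool = False
    group_comparison: Optional[dict] = None
    cofactor_ranking: list[dict] = field(default_factory=list)
    anova: Optional[dict] = None
    stage_seconds: dict = field(default_factory=dict)

    def to_json(self, path: Path) -> None:
        payload = asdict(self)
        payload.pop("stage_seconds")  # wall-clock stays in the log only
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _stage(report: RunReport, outdir: Path, name: str):
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            report.stage_seconds[name] = dt
            if exc is not None:
                logger.error("stage %s: FAILED (%s)", name, exc)
                (outdir / "FAILED").write_text(f"{name}: {exc}\n")
                raise StageError(name, exc) from exc
            logger.info("stage %s: done in %.2fs", name, dt)
            return False

    return _Ctx()


def run_end_to_end(config: PipelineConfig, outdir: Union[str, Path]) -> RunReport:
    """Run every stage on the configured inputs, writing all tables to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    failed_marker = outdir / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    report = RunReport(
        params={
            "alpha": config.alpha,
            "dependency_threshold": config.dependency_threshold,
            "pseudocount": config.pseudocount,
            "window": config.window,
            "n_groups": config.n_groups,
            "n_perm": config.n_perm,
            "seed": config.seed,
            "correlation_method": config.correlation_method,
            "correlation_threshold": config.correlation_threshold,
            "target_total": config.target_total,
        }
    )
    logger.info("parameters: %s", report.params)

    try:
        # ------------------------------------------------------------------
        with _stage(report, outdir, "classify-genes"):
            kd = [
                ContrastTable.from_file(p, ctx, "knockdown")
                for ctx, p in config.knockdown_contrasts.items()
            ]
            ind = [
                ContrastTable.from_file(p, ctx, "induction")
                for ctx, p in config.induction_contrasts.items()
            ]
            common = common_downstream(kd, config.alpha)
            if ind:
                inducible = inducible_union(ind, config.alpha)
            else:
                inducible = set()
                report.degenerate_no_induction = True
                logger.warning(
                    "degenerate design: no induction contrasts supplied; "
                    "every common downstream gene will be classified specific"
                )
            classification = classify(common, inducible)
            classification.to_frame().to_csv(
                outdir / "gene_classes.tsv", sep="\t", index=False
            )
            report.n_common = len(classification.common_downstream)
            report.n_canonical = len(classification.canonical)
            report.n_specific = len(classification.specific)
            logger.info(
                "common=%d canonical=%d specific=%d",
                report.n_common,
                report.n_canonical,
                report.n_specific,
            )

        # ------------------------------------------------------------------
        with _stage(report, outdir, "call-enhancers"):
            genome = cio.read_genome_table(config.genome)
            tf_peaks = cio.read_bed(config.tf_peaks, genome)
            h3k27ac = cio.read_bed(config.h3k27ac_peaks, genome)
            if config.blacklist is not None:
                blacklist = cio.read_bed(config.blacklist, genome)
                tf_peaks = subtract_intervals(tf_peaks, blacklist)
                h3k27ac = subtract_intervals(h3k27ac, blacklist)
            control = normalize_track(
                cio.read_bedgraph(config.control_track, genome), config.target_total
            )
            kd_track = normalize_track(
                cio.read_bedgraph(config.kd_track, genome), config.target_total
            )
            enh = call_enhancers(
                h3k27ac,
                tf_peaks,
                control,
                kd_track,
                pseudocount=config.pseudocount,
                threshold=config.dependency_threshold,
            )
            enh.to_frame().to_csv(
                outdir / "enhancer_calls.tsv", sep="\t", index=False, float_format="%.10g"
            )
            report.n_enhancer_calls = len(enh.calls)
            report.n_dependent = enh.n_dependent
            report.dependent_fraction = enh.dependent_fraction
            logger.info(
                "enhancer calls=%d dependent=%d (fraction %.3f)",
                report.n_enhancer_calls,
                report.n_dependent,
                report.dependent_fraction,
            )

        # ------------------------------------------------------------------
        with _stage(report, outdir, "direct-targets"):
            genes = cio.read_gene_annotation(config.gene_annotation, genome)
            targets = call_direct_targets(
                genes, classification, enh.calls, tf_peaks, window=config.window
            )
            pd.DataFrame(
                [
                    (t.gene_id, t.gene_class, t.tf_bound, t.n_dependent_peaks, t.is_direct)
                    for t in targets
                ],
                columns=["gene_id", "class", "tf_bound", "n_dependent_peaks", "is_direct"],
            ).to_csv(outdir / "direct_targets.tsv", sep="\t", index=False)
            report.n_direct_canonical = sum(
                t.is_direct for t in targets if t.gene_class == "canonical"
            )
            report.n_direct_specific = sum(
                t.is_direct for t in targets if t.gene_class == "specific"
            )
            report.direct_contains_query = any(
                t.gene_id == config.query_gene and t.is_direct and t.gene_class == "specific"
                for t in targets
            )
            spec_signals = [
                c.control_signal
                for t in targets
                if t.gene_class == "specific"
                for c in t.supporting_peaks
                if c.is_dependent
            ]
            can_signals = [
                c.control_signal
                for t in targets
                if t.gene_class == "canonical"
                for c in t.supporting_peaks
                if c.is_dependent
            ]
            if spec_signals and can_signals:
                cmp = mann_whitney(spec_signals, can_signals, "specific", "canonical")
                report.group_comparison = {
                    "group_a": cmp.group_a,
                    "group_b": cmp.group_b,
                    "u_statistic": cmp.u_statistic,
                    "p_value": cmp.p_value,
                    "n_a": cmp.n_a,
                    "n_b": cmp.n_b,
                }
            logger.info(
                "direct targets: canonical=%d specific=%d (query %s direct: %s)",
                report.n_direct_canonical,
                report.n_direct_specific,
                config.query_gene,
                report.direct_contains_query,
            )

        # ------------------------------------------------------------------
        with _stage(report, outdir, "coloc"):
            if config.cofactors:
                ref = reference_set(tf_peaks, h3k27ac)
                catalog = {
                    name: cio.read_bed(p, genome) for name, p in config.cofactors.items()
                }
                ranking = rank_cofactors(
                    catalog, ref, genome, n_perm=config.n_perm, seed=config.seed
                )
                ranking_to_frame(ranking).to_csv(
                    outdir / "coloc_ranking.tsv", sep="\t", index=False, float_format="%.10g"
                )
                report.cofactor_ranking = [
                    {"factor": r.factor, "jaccard": r.jaccard, "perm_p": r.perm_p, "rank": r.rank}
                    for r in ranking
                ]
                logger.info(
                    "cofactor ranking: %s",
                    ", ".join(f"{r.rank}.{r.factor}({r.jaccard:.3f})" for r in ranking),
                )

        # ------------------------------------------------------------------
        with _stage(report, outdir, "score-activity"):
            cohort = cio.read_expression_matrix(config.expression_matrix)
            zmat = zscore_by_gene(cohort)
            scores = stratify(
                activity_score(zmat, config.signature_genes), config.n_groups
            )
            scores.to_frame().to_csv(
                outdir / "activity_scores.tsv", sep="\t", index=False, float_format="%.10g"
            )
            if config.query_gene in cohort.index:
                q = cohort.loc[config.query_gene]
                groups = [
                    q[scores.strata[scores.strata == s].index].to_numpy()
                    for s in sorted(scores.strata.unique())
                ]
                res = anova_oneway(groups)
                report.anova = {
                    "query_gene": config.query_gene,
                    "f_statistic": res.f_statistic,
                    "p_value": res.p_value,
                    "group_means": res.group_means,
                    "group_sizes": res.group_sizes,
                    "pairwise_bonferroni": [
                        {"i": i, "j": j, "p": p} for i, j, p in res.pairwise
                    ],
                }
                logger.info(
                    "ANOVA %s across %d strata: F=%.3f p=%.3g",
                    config.query_gene,
                    config.n_groups,
                    res.f_statistic,
                    res.p_value,
                )
            filtered, skipped = correlation_filter(
                sorted(classification.specific),
                cohort,
                scores,
                method=config.correlation_method,
                threshold=config.correlation_threshold,
            )
            filtered.to_csv(
                outdir / "correlation_filter.tsv", sep="\t", index=False, float_format="%.10g"
            )
            report.n_filtered = len(filtered)
            report.filter_skipped = sorted(skipped)
            logger.info(
                "correlation filter retained %d of %d specific genes (%d skipped)",
                report.n_filtered,
                report.n_specific,
                len(skipped),
            )

        report.to_json(outdir / "report.json")
        return report
    finally:
        logger.removeHandler(handler)
        handler.close()
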