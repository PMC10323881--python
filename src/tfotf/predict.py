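"""Join PWM summaries with R-scores and apply the combined cutoffs.

A gene is predicted as a TF target when its R-score and its chosen PWM
summary (k_max1 by default) both exceed their cutoffs — strictly, matching
the "> 0.7" / "> 8" phrasing of every threshold in this method; a switch
flips to ``≥``. Cutoffs may be absolute values or percentiles of the
joined table's own score distribution (linear-interpolation / type-7
percentiles, the numpy default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import chipseq, correlation, io, metrics, pwm

logger = logging.getLogger("tfotf")

PWM_METRICS = ("k_max1", "k_max3", "k_total")


@dataclass(frozen=True)
class PercentileSpec:
    """A cutoff given as a percentile of the observed score distribution."""

    percentile: float

    def __post_init__(self) -> None:
        if not 0 < self.percentile < 100:
            raise ValueError("percentile must be in (0, 100)")


@dataclass
class CutoffSpec:
    """The two-score cutoff rule of the final prediction step."""

    r_cutoff: float | PercentileSpec = 0.7
    pwm_metric: str = "k_max1"
    pwm_cutoff: float | PercentileSpec = 8.0
    inclusive: bool = False  # False = strict ">"

    def __post_init__(self) -> None:
        if self.pwm_metric not in PWM_METRICS:
            raise ValueError(f"pwm_metric must be one of {PWM_METRICS}")


def resolve_cutoff(values, spec) -> float:
    """Absolute specs pass through; percentile specs use type-7 interpolation."""
    if isinstance(spec, PercentileSpec):
        values = np.asarray(list(values), dtype=float)
        if values.size == 0:
            raise ValueError("cannot take a percentile of an empty score list")
        return float(np.percentile(values, spec.percentile, method="linear"))
    return float(spec)


def predict(
    score_summaries: list[pwm.ScoreSummary],
    r_score_records: list[correlation.RScoreRecord],
    cutoffs: CutoffSpec | None = None,
) -> tuple[list[io.PredictionRecord], dict[str, int]]:
    """Join the two score tables on gene id and flag genes passing the cutoffs.

    Genes present in only one input are excluded from the joined table and
    counted in the returned report. Percentile cutoffs are resolved over
    the joined table's own values.
    """
    cutoffs = cutoffs or CutoffSpec()
    by_gene_pwm = {s.gene_id: s for s in score_summaries}
    by_gene_r = {r.gene_id: r for r in r_score_records}
    joined = sorted(set(by_gene_pwm) & set(by_gene_r))
    report = {
        "n_joined": len(joined),
        "n_pwm_only": len(set(by_gene_pwm) - set(by_gene_r)),
        "n_rscore_only": len(set(by_gene_r) - set(by_gene_pwm)),
    }
    if not joined:
        logger.warning("prediction join is empty: no gene has both score types")
        return [], report

    r_values = [by_gene_r[g].r_score for g in joined]
    pwm_values = [getattr(by_gene_pwm[g], cutoffs.pwm_metric) for g in joined]
    r_cut = resolve_cutoff(r_values, cutoffs.r_cutoff)
    pwm_cut = resolve_cutoff(pwm_values, cutoffs.pwm_cutoff)
    passes = (lambda v, c: v >= c) if cutoffs.inclusive else (lambda v, c: v > c)

    records = []
    for gene, r_val, pwm_val in zip(joined, r_values, pwm_values):
        s = by_gene_pwm[gene]
        rec = by_gene_r[gene]
        records.append(
            io.PredictionRecord(
                gene_id=gene,
                r_score=rec.r_score,
                best_group=rec.best_group,
                k_max1=s.k_max1,
                k_max3=s.k_max3,
                k_total=s.k_total,
                pass_r=passes(r_val, r_cut),
                pass_pwm=passes(pwm_val, pwm_cut),
            )
        )
    records.sort(key=lambda r: (not r.pass_all, -r.r_score, r.gene_id))
    return records, report


class StageError(RuntimeError):
    """A pipeline stage failed; ``stage`` names where."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunResult:
    """Everything the end-to-end run produced."""

    predictions: list[io.PredictionRecord]
    score_summaries: list[pwm.ScoreSummary]
    r_scores: list[correlation.RScoreRecord]
    join_report: dict[str, int]
    scoring_failures: list[tuple[str, str]]
    correlation_skips: list[tuple[str, str]]
    evaluation: metrics.EvalMetrics | None = None
    roc: metrics.RocCurve | None = None
    manifest: dict = field(default_factory=dict)

    @property
    def predicted_gene_ids(self) -> set[str]:
        return {r.gene_id for r in self.predictions if r.pass_all}


def run_tfotf(
    genome: io.GenomeSequence,
    annotations: list[io.GeneAnnotation],
    pfm: io.PositionFrequencyMatrix,
    expr: io.ExpressionMatrix,
    tf_gene: str,
    cutoffs: CutoffSpec | None = None,
    upstream_length: int = pwm.DEFAULT_UPSTREAM,
    scan_reverse_strand: bool = True,
    pseudocount: float = 0.8,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    absolute_r: bool = False,
    reference: chipseq.ReferenceTargetSet | None = None,
) -> RunResult:
    """End-to-end target prediction for one TF.

    PFM → PWM, promoter scan of every annotated gene, R-scores of every
    expression gene, join and cutoff. When a reference set is supplied the
    final predictions are also evaluated against it (set metrics + ROC
    sweep over the R-scores). All parameters are echoed into the manifest.
    """
    cutoffs = cutoffs or CutoffSpec()
    try:
        matrix = io.pfm_to_pwm(pfm, pseudocount=pseudocount, background=background)
    except Exception as exc:
        raise StageError("pwm_conversion", exc) from exc
    try:
        summaries, scoring_failures = pwm.score_all_genes(
            matrix, genome, annotations, upstream_length, scan_reverse_strand
        )
    except Exception as exc:
        raise StageError("pwm_scoring", exc) from exc
    try:
        r_records, corr_skips = correlation.r_scores_all(
            expr, tf_gene, absolute=absolute_r
        )
    except Exception as exc:
        raise StageError("expression_correlation", exc) from exc
    try:
        records, join_report = predict(summaries, r_records, cutoffs)
    except Exception as exc:
        raise StageError("prediction", exc) from exc

    evaluation = None
    roc = None
    if reference is not None:
        try:
            universe = {r.gene_id for r in r_records} | {tf_gene}
            ref = chipseq.restrict_to_universe(reference, universe)
            predicted = {r.gene_id for r in records if r.pass_all}
            evaluation = metrics.evaluate_sets(
                metrics.TargetSets(universe, ref.gene_ids, predicted)
            )
            if ref.gene_ids:
                roc = metrics.roc_sweep(r_records, ref.gene_ids, universe)
        except Exception as exc:
            raise StageError("evaluation", exc) from exc

    manifest = {
        "tf_gene": tf_gene,
        "tf_name": pfm.tf_name,
        "upstream_length": upstream_length,
        "scan_reverse_strand": scan_reverse_strand,
        "pseudocount": pseudocount,
        "background": tuple(background),
        "absolute_r": absolute_r,
        "r_cutoff": repr(cutoffs.r_cutoff),
        "pwm_metric": cutoffs.pwm_metric,
        "pwm_cutoff": repr(cutoffs.pwm_cutoff),
        "inclusive": cutoffs.inclusive,
        "n_genes_annotated": len(annotations),
        "n_genes_expression": len(expr.gene_ids),
    }
    return RunResult(
        predictions=records,
        score_summaries=summaries,
        r_scores=r_records,
        join_report=join_report,
        scoring_failures=scoring_failures,
        correlation_skips=corr_skips,
        evaluation=evaluation,
        roc=roc,
        manifest=manifest,
    )
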