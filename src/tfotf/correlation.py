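"""Per-group Pearson correlation and the R-score reduction.

For a TF and a candidate gene, the Pearson correlation of their expression
is computed within each sample group (one group per cancer type) and the
R-score is the maximum across groups — by default the signed maximum; an
absolute mode takes the maximum of |r| for repressive TFs that
anticorrelate with their targets. Groups with fewer than three samples or
with zero variance in either gene have no defined correlation and are
recorded as missing with a reason code rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, LookupError_

MIN_GROUP_SIZE = 3

#: reason codes for groups without a defined correlation
REASON_INSUFFICIENT = "insufficient_samples"
REASON_ZERO_VARIANCE = "zero_variance"


class UndefinedCorrelation(ValueError):
    """Pearson r is undefined for the given vectors."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


@dataclass
class RScoreRecord:
    """Maximum per-group correlation of one candidate gene with the TF."""

    gene_id: str
    r_score: float
    best_group: str
    per_group_r: dict[str, float] = field(default_factory=dict)
    missing_groups: dict[str, str] = field(default_factory=dict)  # group → reason

    @property
    def n_groups_evaluated(self) -> int:
        return len(self.per_group_r)


def pearson_r(x, y) -> float:
    """Product-moment correlation, clamped to [−1, 1] against rounding.

    Raises :class:`UndefinedCorrelation` for fewer than three paired
    observations or zero variance in either vector.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if len(x) < MIN_GROUP_SIZE:
        raise UndefinedCorrelation(REASON_INSUFFICIENT)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelation(REASON_ZERO_VARIANCE)
    dx = x - x.mean()
    dy = y - y.mean()
    r = (dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum())
    return float(np.clip(r, -1.0, 1.0))


def group_correlations(
    expr: ExpressionMatrix, tf_gene: str, target_gene: str
) -> tuple[dict[str, float], dict[str, str]]:
    """Per-group Pearson r of TF vs target; (defined, missing-with-reason)."""
    for g in (tf_gene, target_gene):
        if g not in expr.values.index:
            raise LookupError_(f"gene {g!r} not in expression matrix")
    tf_row = expr.values.loc[tf_gene].to_numpy(dtype=float)
    tg_row = expr.values.loc[target_gene].to_numpy(dtype=float)
    sample_groups = np.array(
        [expr.group_of_sample[s] for s in expr.values.columns]
    )
    defined: dict[str, float] = {}
    missing: dict[str, str] = {}
    for group in expr.groups:
        mask = sample_groups == group
        try:
            defined[group] = pearson_r(tf_row[mask], tg_row[mask])
        except UndefinedCorrelation as exc:
            missing[group] = exc.reason
    return defined, missing


def r_score(
    expr: ExpressionMatrix,
    tf_gene: str,
    target_gene: str,
    absolute: bool = False,
) -> RScoreRecord:
    """Reduce per-group correlations to the maximum (the R-score).

    Signed mode (default) maximises r itself; absolute mode maximises |r|
    while ``per_group_r`` keeps the signed values. Ties break by
    lexicographic group label. Raises :class:`UndefinedCorrelation` when
    no group yields a defined correlation.
    """
    defined, missing = group_correlations(expr, tf_gene, target_gene)
    if not defined:
        raise UndefinedCorrelation("no_defined_group")
    best, score = _best_group(defined, absolute)
    return RScoreRecord(target_gene, score, best, defined, missing)


def _best_group(defined: dict[str, float], absolute: bool) -> tuple[str, float]:
    """Group attaining the (absolute) maximum; ties → lexicographically first."""
    value = lambda g: abs(defined[g]) if absolute else defined[g]
    top = max(value(g) for g in defined)
    best = min(g for g in defined if value(g) == top)
    return best, top


def r_scores_all(
    expr: ExpressionMatrix,
    tf_gene: str,
    candidate_genes=None,
    absolute: bool = False,
) -> tuple[list[RScoreRecord], list[tuple[str, str]]]:
    """R-scores of every candidate gene against the TF.

    The TF itself is excluded (its self-correlation of 1 is degenerate).
    Candidates with no defined group are reported in the second return
    value, not silently dropped. Records are sorted by r_score descending
    (gene_id ascending on ties). Correlations are computed group-block-wise
    with one matrix pass per group rather than per-gene calls.
    """
    if tf_gene not in expr.values.index:
        raise LookupError_(f"TF gene {tf_gene!r} not in expression matrix")
    if candidate_genes is None:
        candidate_genes = expr.gene_ids
    candidates = [g for g in candidate_genes if g != tf_gene]
    unknown = [g for g in candidates if g not in expr.values.index]
    if unknown:
        raise LookupError_(f"unknown candidate genes: {unknown[:5]}")

    sample_groups = np.array([expr.group_of_sample[s] for s in expr.values.columns])
    vals = expr.values.loc[candidates].to_numpy(dtype=float)
    tf_row = expr.values.loc[tf_gene].to_numpy(dtype=float)

    # per_group_r[g][i] = r of candidate i with TF in group g (nan = missing)
    per_group: dict[str, np.ndarray] = {}
    reasons: dict[str, str | None] = {}
    for group in expr.groups:
        mask = sample_groups == group
        n = int(mask.sum())
        if n < MIN_GROUP_SIZE:
            reasons[group] = REASON_INSUFFICIENT
            per_group[group] = np.full(len(candidates), np.nan)
            continue
        x = tf_row[mask]
        if np.ptp(x) == 0:
            reasons[group] = REASON_ZERO_VARIANCE
            per_group[group] = np.full(len(candidates), np.nan)
            continue
        y = vals[:, mask]
        xc = x - x.mean()
        yc = y - y.mean(axis=1, keepdims=True)
        denom = np.sqrt((xc**2).sum() * (yc**2).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.clip((yc @ xc) / denom, -1.0, 1.0)
        r[denom == 0] = np.nan  # zero-variance candidates in this group
        reasons[group] = None
        per_group[group] = r

    records: list[RScoreRecord] = []
    skipped: list[tuple[str, str]] = []
    groups = expr.groups
    for i, gene in enumerate(candidates):
        defined = {
            g: float(per_group[g][i])
            for g in groups
            if not np.isnan(per_group[g][i])
        }
        missing = {
            g: (reasons[g] or REASON_ZERO_VARIANCE)
            for g in groups
            if np.isnan(per_group[g][i])
        }
        if not defined:
            skipped.append((gene, "no_defined_group"))
            continue
        best, score = _best_group(defined, absolute)
        records.append(RScoreRecord(gene, score, best, defined, missing))
    records.sort(key=lambda r: (-r.r_score, r.gene_id))
    return records, skipped
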