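"""Set-cardinality evaluation metrics and the ROC sweep over R-score cutoffs.

With A the gene universe, C the ChIP-seq reference targets and P the
predicted targets:

    sensitivity = |C ∩ P| / |C|
    specificity = (|A| − |C| − |P| + |C ∩ P|) / (|A| − |C|)
    precision   = |C ∩ P| / |P|
    P/C         = |P| / |C|

Ratios with a zero denominator are reported as explicitly undefined
(``None``), never as 0 — the behaviour of precision and P/C at extreme
cutoffs depends on this distinction. The ROC curve sweeps a cutoff t over
the R-scores with P(t) = {genes : r > t}; the AUC is the trapezoidal area
after augmenting the curve with (0,0) and (1,1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .correlation import RScoreRecord


@dataclass
class TargetSets:
    """The universes of the evaluation: all genes A, reference C, predicted P."""

    A: set[str]
    C: set[str]
    P: set[str]

    def __post_init__(self) -> None:
        self.A, self.C, self.P = set(self.A), set(self.C), set(self.P)
        if not self.C <= self.A:
            raise ValueError("C must be a subset of A")
        if not self.P <= self.A:
            raise ValueError("P must be a subset of A")


@dataclass
class EvalMetrics:
    """The four set-cardinality metrics plus the counts they derive from."""

    sensitivity: float | None
    specificity: float | None
    precision: float | None
    p_over_c: float | None
    n_universe: int
    n_reference: int
    n_predicted: int
    n_shared: int

    @property
    def fpr(self) -> float | None:
        return None if self.specificity is None else 1.0 - self.specificity


def evaluate_sets(sets: TargetSets) -> EvalMetrics:
    """Compute sensitivity, specificity, precision and P/C from A, C, P."""
    a, c, p = len(sets.A), len(sets.C), len(sets.P)
    if a == 0:
        raise ValueError("universe A must be non-empty")
    shared = len(sets.C & sets.P)
    sensitivity = shared / c if c > 0 else None
    specificity = (a - c - p + shared) / (a - c) if a > c else None
    precision = shared / p if p > 0 else None
    p_over_c = p / c if c > 0 else None
    return EvalMetrics(
        sensitivity, specificity, precision, p_over_c, a, c, p, shared
    )


@dataclass
class RocCurve:
    """Cutoff sweep: (cutoff, fpr, tpr) triples plus the trapezoidal AUC."""

    cutoffs: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


class UndefinedRoc(ValueError):
    """Raised when the ROC is undefined (empty reference set)."""


def _resolve_cutoff_grid(scores: np.ndarray, cutoffs) -> np.ndarray:
    if isinstance(cutoffs, str):
        if cutoffs != "auto":
            raise ValueError(f"unknown cutoff spec {cutoffs!r}")
        distinct = np.unique(scores)
        grid = np.concatenate([[distinct[0] - 1.0], distinct, [distinct[-1] + 1.0]])
    else:
        grid = np.sort(np.asarray(cutoffs, dtype=float))
    return grid


def predicted_at_cutoff(
    r_scores: list[RScoreRecord], cutoff: float, inclusive: bool = False
) -> set[str]:
    """P(t): genes scoring strictly above the cutoff (``≥`` if inclusive)."""
    if inclusive:
        return {r.gene_id for r in r_scores if r.r_score >= cutoff}
    return {r.gene_id for r in r_scores if r.r_score > cutoff}


def roc_sweep(
    r_scores: list[RScoreRecord],
    C,
    A,
    cutoffs="auto",
    inclusive: bool = False,
) -> RocCurve:
    """ROC curve of the R-score against the reference set C.

    ``"auto"`` uses every distinct observed score plus sentinels below the
    minimum and above the maximum, so the curve spans (0,0) to the
    all-predicted corner. tpr = sensitivity and fpr = 1 − specificity per
    :func:`evaluate_sets`; the AUC is trapezoidal over the curve augmented
    with (0,0) and (1,1).
    """
    A, C = set(A), set(C)
    if not C:
        raise UndefinedRoc("reference set C is empty")
    if not C <= A:
        raise ValueError("C must be a subset of A")
    scored = {r.gene_id for r in r_scores}
    if not scored <= A:
        raise ValueError("every scored gene must be in A")
    values = np.array([r.r_score for r in r_scores])
    grid = _resolve_cutoff_grid(values, cutoffs)
    fprs, tprs = [], []
    for t in grid:
        m = evaluate_sets(TargetSets(A, C, predicted_at_cutoff(r_scores, t, inclusive)))
        tprs.append(m.sensitivity if m.sensitivity is not None else 0.0)
        fprs.append(m.fpr if m.fpr is not None else 0.0)
    fpr = np.asarray(fprs)
    tpr = np.asarray(tprs)
    # integrate in ascending-fpr order with the (0,0)/(1,1) anchors attached
    fpr_aug = np.concatenate([[0.0], fpr[::-1], [1.0]])
    tpr_aug = np.concatenate([[0.0], tpr[::-1], [1.0]])
    order = np.argsort(fpr_aug, kind="mergesort")
    auc = float(np.trapezoid(tpr_aug[order], fpr_aug[order]))
    return RocCurve(grid, fpr, tpr, auc)


def precision_sweep(
    r_scores: list[RScoreRecord],
    C,
    A,
    cutoffs="auto",
    inclusive: bool = False,
) -> list[dict]:
    """Precision and P/C per cutoff; undefined precision stays ``None``."""
    A, C = set(A), set(C)
    if not C:
        raise UndefinedRoc("reference set C is empty")
    values = np.array([r.r_score for r in r_scores])
    grid = _resolve_cutoff_grid(values, cutoffs)
    rows = []
    for t in grid:
        m = evaluate_sets(TargetSets(A, C, predicted_at_cutoff(r_scores, t, inclusive)))
        rows.append(
            {
                "cutoff": float(t),
                "precision": m.precision,
                "p_over_c": m.p_over_c,
                "n_predicted": m.n_predicted,
            }
        )
    return rows
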