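"""Promoter extraction and sliding-window PWM scoring.

The promoter of a gene is the 5000 bp (configurable) upstream of its TSS,
read 5'→3' on the gene's coding orientation. Each length-n window of the
promoter gets a binding score k = Σ_i a(m(x_i), i), where a is the 4×n
scoring matrix with rows A,T,C,G; a promoter is summarised by the highest
window score (k_max1), the sum of the three highest (k_max3), and the sum
of all window scores (k_total). By default both strands are scanned and
pooled into one window list; windows containing N are skipped since the
score is defined only for A,C,G,T.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import (
    GeneAnnotation,
    GenomeSequence,
    LookupError_,
    PwmMatrix,
    PWM_ROW_ORDER,
)

DEFAULT_UPSTREAM = 5000

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: base → PWM row index (A→0, T→1, C→2, G→3); N → -1 marks unscorable.
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(PWM_ROW_ORDER):
    _BASE_CODE[ord(_b)] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PromoterSequence:
    """Upstream sequence of one gene, coding orientation, 5'→3'."""

    gene_id: str
    sequence: str
    requested_length: int
    truncated: bool

    @property
    def actual_length(self) -> int:
        return len(self.sequence)


@dataclass
class ScoreSummary:
    """Per-gene window-score summaries k_max1, k_max3, k_total."""

    gene_id: str
    k_max1: float
    k_max3: float
    k_total: float
    n_windows: int
    n_skipped_windows: int = 0
    no_windows: bool = False  # True when no scorable window existed


def extract_promoter(
    genome: GenomeSequence,
    gene: GeneAnnotation,
    upstream_length: int = DEFAULT_UPSTREAM,
) -> PromoterSequence:
    """Extract the upstream promoter of a gene, strand-aware.

    "+" strand: positions [max(0, tss−L), tss) in forward orientation.
    "−" strand: positions [tss+1, min(chrom_len, tss+1+L)),
    reverse-complemented. ``truncated`` is set when the chromosome edge
    clips the window.
    """
    if upstream_length < 1:
        raise ValueError("upstream_length must be positive")
    chrom_seq = genome[gene.chrom]
    if not 0 <= gene.tss < len(chrom_seq):
        raise LookupError_(
            f"tss {gene.tss} out of range for {gene.chrom} "
            f"(length {len(chrom_seq)})"
        )
    if gene.strand == "+":
        start = max(0, gene.tss - upstream_length)
        seq = chrom_seq[start : gene.tss]
    else:
        start = gene.tss + 1
        seq = reverse_complement(chrom_seq[start : start + upstream_length])
    return PromoterSequence(
        gene.gene_id, seq, upstream_length, truncated=len(seq) < upstream_length
    )


def segment_sequence(sequence: str, n: int) -> list[str]:
    """All contiguous length-n windows, left to right, stride 1."""
    if n < 1:
        raise ValueError("motif length must be >= 1")
    return [sequence[i : i + n] for i in range(len(sequence) - n + 1)]


def score_window(pwm: PwmMatrix, window: str) -> float:
    """Binding score of one window: per-position row lookups, summed."""
    if len(window) != pwm.length:
        raise ValueError(
            f"window length {len(window)} != motif length {pwm.length}"
        )
    codes = _BASE_CODE[np.frombuffer(window.encode("ascii"), dtype=np.uint8)]
    if np.any(codes < 0):
        raise ValueError("window contains a base outside A,C,G,T")
    return float(pwm.entries[codes, np.arange(pwm.length)].sum())


def _window_scores(pwm: PwmMatrix, sequence: str) -> tuple[np.ndarray, int]:
    """Scores of every N-free window of one strand; (scores, n_skipped)."""
    n = pwm.length
    if len(sequence) < n:
        return np.empty(0), 0
    codes = _BASE_CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    wins = np.lib.stride_tricks.sliding_window_view(codes, n)
    valid = ~(wins < 0).any(axis=1)
    n_skipped = int((~valid).sum())
    wins = wins[valid]
    if len(wins) == 0:
        return np.empty(0), n_skipped
    scores = pwm.entries[wins, np.arange(n)].sum(axis=1)
    return scores, n_skipped


def score_promoter(
    pwm: PwmMatrix,
    promoter: PromoterSequence,
    scan_reverse_strand: bool = True,
) -> ScoreSummary:
    """Summarise all window scores of a promoter into k_max1/k_max3/k_total.

    With ``scan_reverse_strand`` (the default) the reverse complement's
    windows are pooled into the same score list. k_max3 is the sum of the
    three largest scores, or of all scores if fewer than three windows
    exist. A promoter with no scorable window scores 0 on all three
    summaries with ``no_windows`` set, so downstream joins stay total.
    """
    scores, skipped = _window_scores(pwm, promoter.sequence)
    if scan_reverse_strand:
        rc_scores, rc_skipped = _window_scores(
            pwm, reverse_complement(promoter.sequence)
        )
        scores = np.concatenate([scores, rc_scores])
        skipped += rc_skipped
    if len(scores) == 0:
        return ScoreSummary(
            promoter.gene_id, 0.0, 0.0, 0.0,
            n_windows=0, n_skipped_windows=skipped, no_windows=True,
        )
    top3 = np.sort(scores)[-3:]
    return ScoreSummary(
        promoter.gene_id,
        k_max1=float(scores.max()),
        k_max3=float(top3.sum()),
        k_total=float(scores.sum()),
        n_windows=int(len(scores)),
        n_skipped_windows=skipped,
    )


def score_all_genes(
    pwm: PwmMatrix,
    genome: GenomeSequence,
    annotations: list[GeneAnnotation],
    upstream_length: int = DEFAULT_UPSTREAM,
    scan_reverse_strand: bool = True,
) -> tuple[list[ScoreSummary], list[tuple[str, str]]]:
    """Score every annotated gene's promoter.

    Returns (summaries in annotation order, failures as (gene_id, reason));
    genes whose promoter extraction fails are reported, never silently
    dropped.
    """
    if not annotations:
        raise ValueError("annotations must be non-empty")
    summaries: list[ScoreSummary] = []
    failures: list[tuple[str, str]] = []
    for gene in annotations:
        try:
            promoter = extract_promoter(genome, gene, upstream_length)
        except (LookupError_, KeyError) as exc:
            failures.append((gene.gene_id, str(exc)))
            continue
        summaries.append(score_promoter(pwm, promoter, scan_reverse_strand))
    return summaries, failures
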