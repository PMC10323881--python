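"""Reference target set construction from ChIP-seq peaks.

Peaks are first filtered on enrichment (fold change strictly > 1.5 and at
least 10 distinct reads by default), then assigned to genes by overlap
with a strand-aware promoter window around each TSS. This
promoter-proximity assignment is a deliberate simplification of full
nearest-feature genome annotation; callers with an externally annotated
gene list can load it directly and skip the assignment step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import GeneAnnotation, PeakRecord

DEFAULT_MIN_FOLD_CHANGE = 1.5
DEFAULT_MIN_READS = 10
DEFAULT_WINDOW_UPSTREAM = 5000
DEFAULT_WINDOW_DOWNSTREAM = 1000


@dataclass
class ReferenceTargetSet:
    """The ChIP-seq-derived gene set C plus bookkeeping counts."""

    tf_name: str
    gene_ids: set[str]
    n_peaks_input: int = 0
    n_peaks_passing: int = 0
    n_peaks_intergenic: int = 0
    skipped_peaks: list[str] = field(default_factory=list)


def filter_peaks(
    peaks: list[PeakRecord],
    min_fold_change: float = DEFAULT_MIN_FOLD_CHANGE,
    min_reads: int = DEFAULT_MIN_READS,
) -> list[PeakRecord]:
    """Keep peaks with fold_change > min_fold_change and read_count ≥ min_reads.

    Strict ``>`` for fold change ("more than 1.5"), inclusive ``≥`` for
    reads ("at least 10"). Order-preserving and idempotent.
    """
    return [
        p
        for p in peaks
        if p.fold_change > min_fold_change and p.read_count >= min_reads
    ]


def promoter_window(
    gene: GeneAnnotation,
    window_upstream: int = DEFAULT_WINDOW_UPSTREAM,
    window_downstream: int = DEFAULT_WINDOW_DOWNSTREAM,
) -> tuple[int, int]:
    """Strand-aware promoter interval around the TSS, 0-based half-open.

    "+" strand: [tss − upstream, tss + downstream). "−" strand mirrors the
    window: [tss + 1 − downstream, tss + 1 + upstream). The left bound is
    clipped at zero.
    """
    if gene.strand == "+":
        start = gene.tss - window_upstream
        end = gene.tss + window_downstream
    else:
        start = gene.tss + 1 - window_downstream
        end = gene.tss + 1 + window_upstream
    return max(0, start), end


def assign_peaks_to_genes(
    peaks: list[PeakRecord],
    annotations: list[GeneAnnotation],
    window_upstream: int = DEFAULT_WINDOW_UPSTREAM,
    window_downstream: int = DEFAULT_WINDOW_DOWNSTREAM,
    tf_name: str = "",
    min_fold_change: float = DEFAULT_MIN_FOLD_CHANGE,
    min_reads: int = DEFAULT_MIN_READS,
) -> ReferenceTargetSet:
    """Build C: genes whose promoter window overlaps a passing peak.

    A gene enters C once regardless of how many peaks hit it; passing
    peaks overlapping no promoter window count as intergenic and are
    discarded; peaks on chromosomes absent from the annotation are
    reported in ``skipped_peaks``.
    """
    if not annotations:
        raise ValueError("annotations must be non-empty")
    passing = filter_peaks(peaks, min_fold_change, min_reads)

    windows_by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gene in annotations:
        s, e = promoter_window(gene, window_upstream, window_downstream)
        windows_by_chrom.setdefault(gene.chrom, []).append((s, e, gene.gene_id))

    hits: set[str] = set()
    n_intergenic = 0
    skipped: list[str] = []
    for peak in passing:
        windows = windows_by_chrom.get(peak.chrom)
        if windows is None:
            skipped.append(f"{peak.chrom}:{peak.start}-{peak.end}")
            continue
        overlapped = {
            gid for s, e, gid in windows if peak.start < e and s < peak.end
        }
        if overlapped:
            hits |= overlapped
        else:
            n_intergenic += 1
    return ReferenceTargetSet(
        tf_name=tf_name,
        gene_ids=hits,
        n_peaks_input=len(peaks),
        n_peaks_passing=len(passing),
        n_peaks_intergenic=n_intergenic,
        skipped_peaks=skipped,
    )


def restrict_to_universe(
    reference: ReferenceTargetSet, universe_gene_ids
) -> ReferenceTargetSet:
    """Intersect C with the gene universe (e.g. the expression dataset)."""
    universe = set(universe_gene_ids)
    return ReferenceTargetSet(
        tf_name=reference.tf_name,
        gene_ids=reference.gene_ids & universe,
        n_peaks_input=reference.n_peaks_input,
        n_peaks_passing=reference.n_peaks_passing,
        n_peaks_intergenic=reference.n_peaks_intergenic,
        skipped_peaks=list(reference.skipped_peaks),
    )
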