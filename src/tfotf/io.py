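"""Readers and writers for every external representation the tool touches.

All downstream modules consume only the in-memory types defined here:
genomes, gene annotations (TSS table), JASPAR position frequency matrices,
expression matrices with a sample→group mapping, and ChIP-seq peak tables.
All genomic coordinates are 0-based half-open throughout the package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from Bio import SeqIO

logger = logging.getLogger("tfotf")

VALID_BASES = frozenset("ACGTN")

#: JASPAR count-matrix row order.
PFM_ROW_ORDER = "ACGT"
#: Row order of the scoring matrix used by the window-scoring module
#: (rows 1..4 = A, T, C, G).
PWM_ROW_ORDER = "ATCG"


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


class LookupError_(KeyError):
    """Raised when a referenced entity (chromosome, gene) is unknown."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class GenomeSequence:
    """Chromosome name → uppercase nucleotide string over {A,C,G,T,N}."""

    chroms: dict[str, str]
    n_substituted: int = 0  # non-ACGTN characters normalized to N at read time

    def __contains__(self, name: str) -> bool:
        return name in self.chroms

    def __getitem__(self, name: str) -> str:
        try:
            return self.chroms[name]
        except KeyError:
            raise LookupError_(f"unknown chromosome {name!r}") from None


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene: id, chromosome, 0-based TSS coordinate, strand."""

    gene_id: str
    chrom: str
    tss: int
    strand: str  # "+" or "-"


@dataclass
class PositionFrequencyMatrix:
    """JASPAR-style count matrix: 4 rows (A,C,G,T) × n motif columns."""

    tf_name: str
    counts: np.ndarray  # shape (4, n), non-negative integers

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        """Most frequent base per column (ties → first of A,C,G,T)."""
        return "".join(PFM_ROW_ORDER[i] for i in self.counts.argmax(axis=0))


@dataclass
class PwmMatrix:
    """Log-odds scoring matrix with rows in A,T,C,G order.

    ``entries[m, j]`` is the score of base ``PWM_ROW_ORDER[m]`` at motif
    position ``j``; a window score is the sum of its per-position entries.
    """

    tf_name: str
    entries: np.ndarray  # shape (4, n), finite reals; rows A,T,C,G

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.ndim != 2 or self.entries.shape[0] != 4:
            raise ValueError("PWM must have exactly 4 rows")
        if self.entries.shape[1] < 1:
            raise ValueError("PWM must have at least 1 column")
        if not np.all(np.isfinite(self.entries)):
            raise ValueError("PWM entries must be finite")

    @property
    def length(self) -> int:
        return self.entries.shape[1]

    def max_score(self) -> float:
        """Best attainable window score: column-wise maxima summed."""
        return float(self.entries.max(axis=0).sum())


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values plus a sample→group mapping."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids
    group_of_sample: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate gene ids: {list(dups)[:5]}")
        missing = [s for s in self.values.columns if s not in self.group_of_sample]
        if missing:
            raise FormatError(f"samples without a group assignment: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        return sorted({self.group_of_sample[s] for s in self.values.columns})

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_of_sample[s] == group]


@dataclass(frozen=True)
class PeakRecord:
    """One ChIP-seq peak with its enrichment statistics."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    fold_change: float
    read_count: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"peak start must be < end, got [{self.start}, {self.end})"
            )
        if not math.isfinite(self.fold_change):
            raise FormatError("peak fold_change must be finite")


@dataclass
class PredictionRecord:
    """Joined PWM + R-score record with pass/fail flags under the cutoffs."""

    gene_id: str
    r_score: float
    best_group: str
    k_max1: float
    k_max3: float
    k_total: float
    pass_r: bool
    pass_pwm: bool

    @property
    def pass_all(self) -> bool:
        return self.pass_r and self.pass_pwm


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_genome_fasta(path) -> GenomeSequence:
    """Load a FASTA genome; sequences uppercased, non-ACGTN mapped to N.

    The first whitespace-delimited token of each header is the chromosome
    name. IUPAC ambiguity codes (and anything else outside A,C,G,T,N)
    are normalized to N; the substitution count is logged and stored.
    """
    chroms: dict[str, str] = {}
    n_sub = 0
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if name in chroms:
            raise FormatError(f"duplicate FASTA header token {name!r}")
        seq = str(record.seq).upper()
        cleaned = "".join(c if c in VALID_BASES else "N" for c in seq)
        n_sub += sum(1 for a, b in zip(seq, cleaned) if a != b)
        if len(cleaned) == 0:
            raise FormatError(f"empty sequence for {name!r}")
        chroms[name] = cleaned
    if not chroms:
        raise FormatError(f"no FASTA records in {path}")
    if n_sub:
        logger.warning("normalized %d non-ACGTN characters to N", n_sub)
    return GenomeSequence(chroms, n_substituted=n_sub)


def read_gene_annotation(path) -> list[GeneAnnotation]:
    """Parse the TSS table: tab-separated gene_id, chrom, tss, strand.

    Lines starting with ``#`` are headers/comments. TSS is a 0-based
    integer coordinate; strand must be ``+`` or ``-``.
    """
    records: list[GeneAnnotation] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"line {lineno}: expected 4 columns, got {len(parts)}")
            gene_id, chrom, tss_s, strand = parts[:4]
            if strand not in ("+", "-"):
                raise FormatError(f"line {lineno}: invalid strand {strand!r}")
            try:
                tss = int(tss_s)
            except ValueError:
                raise FormatError(f"line {lineno}: non-integer tss {tss_s!r}") from None
            if tss < 0:
                raise FormatError(f"line {lineno}: negative tss {tss}")
            if gene_id in seen:
                raise FormatError(f"line {lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            records.append(GeneAnnotation(gene_id, chrom, tss, strand))
    return records


def read_jaspar_pfm(path) -> list[PositionFrequencyMatrix]:
    """Parse JASPAR 2016+ PFM text; multiple records per file allowed.

    Counts are stored in A,C,G,T row order as in the file. Ragged rows or
    a missing base line raise :class:`FormatError`.
    """
    with open(path) as fh:
        try:
            parsed = bio_motifs.parse(fh, "jaspar")
        except Exception as exc:  # Bio raises bare Exception subclasses
            raise FormatError(f"malformed JASPAR PFM file {path}: {exc}") from exc
    out: list[PositionFrequencyMatrix] = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in PFM_ROW_ORDER], dtype=float)
        if counts.shape[1] < 1:
            raise FormatError("empty PFM record")
        if np.any(counts < 0):
            raise FormatError("negative PFM counts")
        colsum = counts.sum(axis=0)
        if np.any(colsum < 1):
            raise FormatError("PFM column sums must be >= 1")
        name = m.name or m.matrix_id or "unnamed"
        out.append(PositionFrequencyMatrix(str(name), counts))
    if not out:
        raise FormatError(f"no PFM records in {path}")
    return out


def write_jaspar_pfm(pfms: list[PositionFrequencyMatrix], path) -> None:
    """Write PFMs in the JASPAR 2016 text dialect (round-trips the reader)."""
    with open(path, "w") as fh:
        for i, pfm in enumerate(pfms, start=1):
            fh.write(f">M{i:04d} {pfm.tf_name}\n")
            for row, base in zip(pfm.counts, PFM_ROW_ORDER):
                cells = " ".join(f"{int(c):6d}" for c in row)
                fh.write(f"{base} [{cells} ]\n")


def pfm_to_pwm(
    pfm: PositionFrequencyMatrix,
    pseudocount: float = 0.8,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
) -> PwmMatrix:
    """Convert a count matrix to a log2-odds scoring matrix.

    entry(b, j) = log2(((count(b,j) + pseudocount·bg(b)) / (colsum(j) +
    pseudocount)) / bg(b)), the standard background-weighted pseudocount
    convention. ``background`` is given in A,C,G,T order (matching the
    count rows); the returned matrix rows are reordered to A,T,C,G, the
    convention of the scoring module.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or np.any(bg <= 0):
        raise ValueError("background must be 4 positive probabilities")
    if abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must sum to 1 within 1e-9")
    counts = pfm.counts.astype(float)
    colsum = counts.sum(axis=0)
    prob = (counts + pseudocount * bg[:, None]) / (colsum + pseudocount)
    acgt = np.log2(prob / bg[:, None])
    # reorder rows A,C,G,T -> A,T,C,G
    order = [PFM_ROW_ORDER.index(b) for b in PWM_ROW_ORDER]
    return PwmMatrix(pfm.tf_name, acgt[order])


def read_expression_matrix(values_path, groups_path) -> ExpressionMatrix:
    """Load a genes × samples TSV plus a sample_id → group TSV.

    Every sample column must have a group row; missing values in the
    expression table are rejected so that downstream Pearson correlations
    are unambiguous.
    """
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    if values.index.has_duplicates:
        dups = values.index[values.index.duplicated()].unique()
        raise FormatError(f"duplicate gene rows: {list(dups)[:5]}")
    if values.isna().any().any():
        raise FormatError("expression matrix contains missing values")
    groups = pd.read_csv(
        groups_path, sep="\t", header=None, names=["sample_id", "group"],
        comment="#", dtype=str,
    )
    mapping = dict(zip(groups["sample_id"], groups["group"]))
    missing = [s for s in values.columns if s not in mapping]
    if missing:
        raise FormatError(f"samples without a group assignment: {missing}")
    return ExpressionMatrix(values.astype(float), mapping)


def read_peaks(path) -> list[PeakRecord]:
    """Parse the peak TSV: chrom, start, end, fold_change, read_count.

    Coordinates are 0-based half-open; an empty file yields an empty list.
    """
    records: list[PeakRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError(f"line {lineno}: expected 5 columns, got {len(parts)}")
            try:
                rec = PeakRecord(
                    parts[0], int(parts[1]), int(parts[2]),
                    float(parts[3]), int(parts[4]),
                )
            except FormatError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
            except ValueError:
                raise FormatError(f"line {lineno}: unparseable numeric field") from None
            if rec.read_count < 0:
                raise FormatError(f"line {lineno}: negative read_count")
            records.append(rec)
    return records


def read_gene_list(path) -> set[str]:
    """One gene id per line (precomputed reference target set)."""
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip() and not line.startswith("#")}


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

PREDICTION_COLUMNS = [
    "gene_id", "r_score", "best_group", "k_max1", "k_max3", "k_total",
    "pass_r", "pass_pwm", "pass_all",
]


def predictions_to_frame(records: list[PredictionRecord]) -> pd.DataFrame:
    """Prediction records as a sorted DataFrame.

    Sorted by (pass_all desc, r_score desc, gene_id asc) so that passing
    genes lead and ties resolve deterministically.
    """
    rows = [
        {
            "gene_id": r.gene_id,
            "r_score": r.r_score,
            "best_group": r.best_group,
            "k_max1": r.k_max1,
            "k_max3": r.k_max3,
            "k_total": r.k_total,
            "pass_r": r.pass_r,
            "pass_pwm": r.pass_pwm,
            "pass_all": r.pass_all,
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
    if len(df):
        df = df.sort_values(
            ["pass_all", "r_score", "gene_id"],
            ascending=[False, False, True],
            kind="mergesort",
        ).reset_index(drop=True)
    return df


def write_prediction_table(records: list[PredictionRecord], path) -> None:
    """Write the final prediction TSV; floats use 6 significant digits."""
    df = predictions_to_frame(records)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
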