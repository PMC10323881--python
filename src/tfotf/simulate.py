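"""Synthetic benchmark generator with planted motifs and planted correlations.

Generates every input the pipeline consumes — a genome with annotated
TSSs, a TF count matrix, a pan-cancer-style expression matrix, and a
ChIP-seq peak table — with a known set of true target genes, so every
stage and the end-to-end pipeline are testable without external data.
True targets carry (a) at least one exact copy of the motif consensus in
their promoter, (b) expression correlated with the TF at a chosen effect
size ρ within every sample group, and (c) one peak passing the enrichment
filter inside their promoter. All generators are deterministic functions
of the configuration (which includes the seed).

Gene slots are spaced so that default promoter-proximity windows of
neighbouring genes never overlap; planted peaks therefore map back to
exactly the truth set.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import (
    GeneAnnotation,
    GenomeSequence,
    ExpressionMatrix,
    PeakRecord,
    PositionFrequencyMatrix,
    PFM_ROW_ORDER,
    write_jaspar_pfm,
)
from .pwm import reverse_complement

import pandas as pd

#: margin around each gene slot keeping neighbouring promoter windows disjoint
_SLOT_MARGIN = 1200
_SLOT_EXTRA = 2400


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic benchmark.

    Defaults give 1000 genes, 50 true targets, effect size ρ = 0.8 and
    5 groups × 100 samples — large enough that planted correlations
    separate cleanly from the null — with 5000 bp promoters matching the
    promoter definition used for scoring.
    """

    seed: int = 0
    n_genes: int = 1000
    n_groups: int = 5
    samples_per_group: int = 100
    n_true_targets: int = 50
    effect_size: float = 0.8  # within-group correlation ρ of targets with the TF
    motif_length: int = 9
    promoter_length: int = 5000
    motif_plant_rate: float = 1.0
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    genes_per_chrom: int = 100
    tf_gene_id: str = "TF1"
    tf_name: str = "SIMTF"
    n_decoy_peaks: int = 20  # peaks failing the enrichment filter
    n_intergenic_peaks: int = 10  # passing peaks outside every promoter window
    peak_width: int = 200

    def __post_init__(self) -> None:
        if self.n_true_targets > self.n_genes:
            raise ValueError("n_true_targets must be <= n_genes")
        if not 0 <= self.effect_size < 1:
            raise ValueError("effect_size must be in [0, 1)")
        if self.promoter_length < self.motif_length:
            raise ValueError("promoter_length must be >= motif_length")
        if not 0 <= self.motif_plant_rate <= 1:
            raise ValueError("motif_plant_rate must be in [0, 1]")
        for name in (
            "n_genes", "n_groups", "samples_per_group", "n_true_targets",
            "motif_length", "promoter_length", "genes_per_chrom", "peak_width",
        ):
            if getattr(self, name) < (0 if name == "n_true_targets" else 1):
                raise ValueError(f"{name} must be positive")

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def _rng(self, salt: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, salt])


def simulate_pfm(config: SimulationConfig) -> PositionFrequencyMatrix:
    """Count matrix with an unambiguous consensus (17:1:1:1 per column)."""
    rng = config._rng(1)
    dominant = rng.integers(0, 4, size=config.motif_length)
    counts = np.ones((4, config.motif_length))
    counts[dominant, np.arange(config.motif_length)] = 17
    return PositionFrequencyMatrix(config.tf_name, counts)


def _truth_set(config: SimulationConfig) -> list[str]:
    rng = config._rng(2)
    ids = config.gene_ids()
    idx = rng.choice(config.n_genes, size=config.n_true_targets, replace=False)
    return [ids[i] for i in sorted(idx)]


def _gene_layout(config: SimulationConfig):
    """(chrom, slot_start, tss, strand, promoter_start) per gene.

    Promoters occupy [slot+margin, slot+margin+L) on the forward strand
    for both orientations; the TSS sits at the downstream ("+") or
    upstream-1 ("−") edge accordingly.
    """
    rng = config._rng(3)
    L = config.promoter_length
    slot = L + _SLOT_EXTRA
    strands = rng.choice(["+", "-"], size=config.n_genes)
    layout = []
    for i in range(config.n_genes):
        chrom = f"chr{i // config.genes_per_chrom + 1}"
        slot_start = (i % config.genes_per_chrom) * slot
        p_start = slot_start + _SLOT_MARGIN
        strand = strands[i]
        tss = p_start + L if strand == "+" else p_start - 1
        layout.append((chrom, slot_start, tss, strand, p_start))
    return layout


def simulate_genome_and_annotation(
    config: SimulationConfig,
) -> tuple[GenomeSequence, list[GeneAnnotation], set[str]]:
    """Genome + TSS annotation with the consensus planted in true targets.

    Promoters are i.i.d. background sequence; each true target (subject
    to ``motif_plant_rate``) receives one exact consensus copy at a
    uniform random offset and strand within its promoter. Non-targets
    receive no planted copy, though background sequence may contain
    chance matches.
    """
    rng = config._rng(4)
    pfm = simulate_pfm(config)
    consensus = pfm.consensus
    truth = _truth_set(config)
    truth_set = set(truth)
    layout = _gene_layout(config)
    ids = config.gene_ids()

    L = config.promoter_length
    slot = L + _SLOT_EXTRA
    chrom_len = config.genes_per_chrom * slot
    n_chroms = -(-config.n_genes // config.genes_per_chrom)
    bases = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    bg = np.asarray(config.background, dtype=float)
    chrom_arrays = {
        f"chr{c + 1}": rng.choice(bases, size=chrom_len, p=bg)
        for c in range(n_chroms)
    }

    planted: set[str] = set()
    annotations = []
    for gene_id, (chrom, _slot_start, tss, strand, p_start) in zip(ids, layout):
        annotations.append(GeneAnnotation(gene_id, chrom, tss, strand))
        if gene_id not in truth_set:
            continue
        if rng.random() >= config.motif_plant_rate:
            continue
        offset = int(rng.integers(0, L - config.motif_length + 1))
        motif = consensus if rng.random() < 0.5 else reverse_complement(consensus)
        arr = chrom_arrays[chrom]
        pos = p_start + offset
        arr[pos : pos + config.motif_length] = np.frombuffer(
            motif.encode(), dtype=np.uint8
        )
        planted.add(gene_id)

    genome = GenomeSequence(
        {name: arr.tobytes().decode() for name, arr in chrom_arrays.items()}
    )
    return genome, annotations, truth_set


def simulate_expression(
    config: SimulationConfig, truth: set[str]
) -> ExpressionMatrix:
    """Expression with targets correlated to the TF at ρ within each group.

    TF expression is standard normal per sample; each true target is
    y = ρ·tf + √(1−ρ²)·ε with independent standard-normal ε, so its
    population correlation with the TF is exactly ρ in every group.
    Non-targets are independent noise.
    """
    rng = config._rng(5)
    ids = config.gene_ids()
    n_samples = config.n_groups * config.samples_per_group
    sample_ids = [f"S{i:04d}" for i in range(1, n_samples + 1)]
    group_labels = [f"T{g + 1:02d}" for g in range(config.n_groups)]
    group_of_sample = {
        s: group_labels[i // config.samples_per_group]
        for i, s in enumerate(sample_ids)
    }

    tf = rng.standard_normal(n_samples)
    rho = config.effect_size
    values = rng.standard_normal((config.n_genes, n_samples))
    truth_idx = [i for i, g in enumerate(ids) if g in truth]
    values[truth_idx] = rho * tf + np.sqrt(1 - rho**2) * values[truth_idx]

    frame = pd.DataFrame(
        np.vstack([tf, values]),
        index=[config.tf_gene_id] + ids,
        columns=sample_ids,
    )
    return ExpressionMatrix(frame, group_of_sample)


def simulate_peaks(
    config: SimulationConfig,
    truth: set[str],
    annotations: list[GeneAnnotation],
) -> list[PeakRecord]:
    """Peak table whose passing peaks recover exactly the truth set.

    One passing peak (fold change 2.0, 20 reads) inside each truth gene's
    promoter; decoy peaks in random promoters that fail the enrichment
    filter (fold change 1.2 or 5 reads); passing intergenic peaks placed
    in the inter-slot margins outside every promoter window.
    """
    rng = config._rng(6)
    L = config.promoter_length
    slot = L + _SLOT_EXTRA
    by_id = {a.gene_id: a for a in annotations}
    width = min(config.peak_width, L)

    def promoter_interval(gene: GeneAnnotation) -> tuple[int, int]:
        if gene.strand == "+":
            return gene.tss - L, gene.tss
        return gene.tss + 1, gene.tss + 1 + L

    peaks: list[PeakRecord] = []
    for gene_id in sorted(truth):
        gene = by_id[gene_id]
        p_start, p_end = promoter_interval(gene)
        start = int(rng.integers(p_start, p_end - width + 1))
        peaks.append(PeakRecord(gene.chrom, start, start + width, 2.0, 20))

    all_ids = sorted(by_id)
    for _ in range(config.n_decoy_peaks):
        gene = by_id[all_ids[int(rng.integers(0, len(all_ids)))]]
        p_start, p_end = promoter_interval(gene)
        start = int(rng.integers(p_start, p_end - width + 1))
        if rng.random() < 0.5:
            fc, reads = 1.2, 20  # fails the fold-change threshold
        else:
            fc, reads = 2.0, 5  # fails the read threshold
        peaks.append(PeakRecord(gene.chrom, start, start + width, fc, reads))

    # inter-slot margins: [slot_start, slot_start+150) lies outside every
    # default promoter-proximity window for either strand
    chroms = sorted({a.chrom for a in annotations})
    for _ in range(config.n_intergenic_peaks):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        slot_start = int(rng.integers(0, config.genes_per_chrom)) * slot
        peaks.append(
            PeakRecord(chrom, slot_start + 10, slot_start + 110, 2.0, 20)
        )
    return peaks


def write_fixture(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Write the full synthetic fixture in the formats the readers accept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, annotations, truth = simulate_genome_and_annotation(config)
    expr = simulate_expression(config, truth)
    peaks = simulate_peaks(config, truth, annotations)
    pfm = simulate_pfm(config)

    paths = {
        "genome": outdir / "genome.fa",
        "annotation": outdir / "annotation.tsv",
        "pfm": outdir / "motif.jaspar",
        "expression": outdir / "expression.tsv",
        "groups": outdir / "groups.tsv",
        "peaks": outdir / "peaks.tsv",
        "truth": outdir / "truth_genes.txt",
    }
    with open(paths["genome"], "w") as fh:
        for name, seq in genome.chroms.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    with open(paths["annotation"], "w") as fh:
        fh.write("#gene_id\tchrom\ttss\tstrand\n")
        for a in annotations:
            fh.write(f"{a.gene_id}\t{a.chrom}\t{a.tss}\t{a.strand}\n")
    write_jaspar_pfm([pfm], paths["pfm"])
    expr.values.to_csv(paths["expression"], sep="\t", index_label="gene_id")
    with open(paths["groups"], "w") as fh:
        for s in expr.sample_ids:
            fh.write(f"{s}\t{expr.group_of_sample[s]}\n")
    with open(paths["peaks"], "w") as fh:
        fh.write("#chrom\tstart\tend\tfold_change\tread_count\n")
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.fold_change}\t{p.read_count}\n"
            )
    with open(paths["truth"], "w") as fh:
        for g in sorted(truth):
            fh.write(g + "\n")
    return paths
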