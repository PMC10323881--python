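import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tfotf

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Small but fully featured benchmark: fast enough for unit tests."""
    return tfotf.SimulationConfig(
        seed=7,
        n_genes=40,
        n_true_targets=5,
        n_groups=3,
        samples_per_group=30,
        genes_per_chrom=10,
        promoter_length=300,
        motif_length=6,
    )


@pytest.fixture(scope="session")
def small_fixture(small_config):
    genome, annotations, truth = tfotf.simulate_genome_and_annotation(small_config)
    expr = tfotf.simulate_expression(small_config, truth)
    peaks = tfotf.simulate_peaks(small_config, truth, annotations)
    pfm = tfotf.simulate_pfm(small_config)
    return {
        "config": small_config,
        "genome": genome,
        "annotations": annotations,
        "truth": truth,
        "expr": expr,
        "peaks": peaks,
        "pfm": pfm,
    }


def brute_force_summary(pwm_entries, sequence, scan_reverse=True):
    """Independent window-enumeration oracle for promoter scoring.

    Pure-Python re-derivation: enumerate every length-n substring of the
    sequence (and of its reverse complement when scan_reverse), skip
    windows containing N, sum per-base row lookups sequentially.
    """
    row_of = {"A": 0, "T": 1, "C": 2, "G": 3}
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    n = len(pwm_entries[0])
    strands = [sequence]
    if scan_reverse:
        strands.append("".join(comp[c] for c in reversed(sequence)))
    scores = []
    for seq in strands:
        for i in range(len(seq) - n + 1):
            window = seq[i : i + n]
            if "N" in window:
                continue
            total = 0.0
            for j, base in enumerate(window):
                total += pwm_entries[row_of[base]][j]
            scores.append(total)
    if not scores:
        return {"k_max1": 0.0, "k_max3": 0.0, "k_total": 0.0, "n_windows": 0}
    top3 = sorted(scores)[-3:]
    total3 = 0.0
    for s in top3:
        total3 += s
    return {
        "k_max1": max(scores),
        "k_max3": total3,
        "k_total": sum(scores),
        "n_windows": len(scores),
        "scores": sorted(scores),
    }


@pytest.fixture
def brute_force_oracle():
    return brute_force_summary


def random_pwm(rng, n):
    return tfotf.PwmMatrix("RND", rng.normal(size=(4, n)))


def random_sequence(rng, length, alphabet="ACGT"):
    return "".join(rng.choice(list(alphabet), size=length))
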