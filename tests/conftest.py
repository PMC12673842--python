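"""Shared fixtures: a seeded synthetic study and independent oracle helpers."""

import numpy as np
import pytest

from isoscope import annotation, classify, simulate

#: Seed of the shared synthetic study used across the suite.
STUDY_SEED = 11


@pytest.fixture(scope="session")
def config():
    return simulate.SimulationConfig(seed=STUDY_SEED)


@pytest.fixture(scope="session")
def sim_annotation(config):
    return simulate.simulate_annotation(config)


@pytest.fixture(scope="session")
def sim_de(sim_annotation, config):
    return simulate.simulate_de_tables(sim_annotation.truth, config)


@pytest.fixture(scope="session")
def sim_gmt(sim_annotation, sim_de, config):
    return simulate.simulate_gmt(sim_annotation.truth, config, sim_de.truth)


@pytest.fixture(scope="session")
def tx2gene(sim_annotation):
    fasta_records = annotation.parse_fasta_headers(sim_annotation.fasta_text)
    gtf_records, _ = annotation.parse_gtf(sim_annotation.gtf_text)
    return annotation.make_tx_to_gene(fasta_records + gtf_records)


@pytest.fixture(scope="session")
def annotated_tx(sim_de, tx2gene):
    return classify.annotate_de_table(sim_de.tx_de, tx2gene)


def brute_force_es(stats: np.ndarray, hit: np.ndarray, p: float) -> float:
    """Naive running-sum enrichment score: explicit walk, explicit extremum.

    Independent of the vectorized implementation except for the shared weight
    normalization primitive (a plain sum over hit weights).
    """
    n = len(stats)
    nh = int(np.sum(hit))
    assert 0 < nh < n
    w = np.ones(n) if p == 0 else np.abs(stats) ** p
    total = float(np.sum(w[hit]))
    if total == 0.0:
        w = np.ones(n)
        total = float(np.sum(w[hit]))
    running = 0.0
    best, best_abs = 0.0, -1.0
    for i in range(n):
        running += w[i] / total if hit[i] else -1.0 / (n - nh)
        if abs(running) > best_abs:
            best_abs, best = abs(running), running
    return best
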