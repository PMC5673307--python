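"""Shared fixtures: toy annotations and small simulated datasets."""

import numpy as np
import pandas as pd
import pytest

from cracsplice import (
    GenomeAnnotation,
    TranscriptModel,
    simulate_crac_reads,
    simulate_genome,
    substream,
)
from cracsplice.simulate import SimulationConfig

BASES = "ACGT"


def random_seq(n: int, seed: int = 0) -> str:
    rng = substream(seed, "fixture")
    return "".join(BASES[i] for i in rng.integers(0, 4, n))


@pytest.fixture(scope="session")
def toy_ann() -> GenomeAnnotation:
    """Three-gene toy: single exon (+), two exons (+), two exons (-).

    Built from the GFF-style coordinates 1..100 / (1..50, 101..300) /
    (101..300, 1..50 in transcription order) used throughout the unit tests.
    """
    chroms = {f"chr{i}": random_seq(400, seed=i) for i in (1, 2, 3)}
    genes = [
        TranscriptModel("geneA", "chr1", "+", 0, 99, ((0, 100),)),
        TranscriptModel("geneB", "chr2", "+", 0, 299, ((0, 50), (100, 300))),
        TranscriptModel("geneC", "chr3", "-", 299, 0, ((100, 300), (0, 50))),
    ]
    return GenomeAnnotation(chromosomes=chroms, genes=genes)


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    return SimulationConfig(seed=17, n_genes=10, n_reads=8000)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    """(annotation, gene truth) for a 10-gene genome."""
    return simulate_genome(small_cfg)


@pytest.fixture(scope="session")
def small_crac(small_cfg, small_sim):
    ann, gt = small_sim
    reads, truth = simulate_crac_reads(ann, small_cfg, "protein_CRAC", gt)
    return reads, truth


def truth_junction_tally(truth: pd.DataFrame, genes) -> pd.DataFrame:
    """Independent tally of the simulator's per-read truth labels.

    Aggregates the truth table only; never calls the classifier it checks.
    """
    lab = truth.groupby(["gene_id", "junction_label"]).size().unstack(fill_value=0)
    flags = truth.groupby("gene_id")["has_intronic"].agg(["sum", "count"])
    tt = pd.DataFrame(index=list(genes))
    for c in ("EE", "EI", "IE"):
        tt[c] = lab[c] if c in lab.columns else 0
    tt = tt.fillna(0).astype(int)
    tt["I"] = flags["sum"].reindex(tt.index).fillna(0).astype(int)
    tt["E"] = (flags["count"] - flags["sum"]).reindex(tt.index).fillna(0).astype(int)
    return tt
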