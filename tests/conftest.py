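"""Shared fixtures: tiny hand-built genomes and one session-scoped simulation."""

from __future__ import annotations

import numpy as np
import pytest

from regulonmotifs.io_formats import GeneModel, GenomeRecord
from regulonmotifs.synthetic_data import SimulationConfig, simulate


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), p=probs, size=length))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_genome(rng) -> GenomeRecord:
    return GenomeRecord("chr1", random_dna(rng, 2000))


@pytest.fixture
def plus_gene() -> GeneModel:
    return GeneModel("gA", "chr1", 800, 1400, "+", "op1", 1)


@pytest.fixture
def minus_gene() -> GeneModel:
    return GeneModel("gB", "chr1", 100, 700, "-", "op2", 1)


@pytest.fixture(scope="session")
def planted_dataset():
    """One full synthetic study with the default palindromic plant."""
    return simulate(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def small_dataset():
    """A small, fast synthetic study for end-to-end smoke tests."""
    return simulate(SimulationConfig(seed=3, n_genes=80, regulon_size=12))
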