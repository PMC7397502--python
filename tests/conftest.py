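"""Shared fixtures: tiny in-memory genomes and a small simulated study."""

from __future__ import annotations

import numpy as np
import pytest

from exposig.io import ReferenceGenome
from exposig.simulate import SimulationConfig, simulate_study


@pytest.fixture
def toy_genome() -> ReferenceGenome:
    return ReferenceGenome({"chr1": "ACGTA"})


@pytest.fixture(scope="session")
def random_genome() -> ReferenceGenome:
    rng = np.random.Generator(np.random.PCG64(424242))
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=20_000)])
    return ReferenceGenome({"chr1": seq})


@pytest.fixture(scope="session")
def small_study():
    """A 3-control / 4-exposed simulated study, modest burdens."""
    cfg = SimulationConfig(
        seed=11,
        n_contigs=2,
        contig_length_bp=150_000,
        background_burden=800,
        exposure_burden=1500,
        n_genes=20,
        gene_length_bp=5_000,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def small_study_dir(tmp_path_factory):
    """The same study written to disk (VCFs, FASTA, BED, truth)."""
    cfg = SimulationConfig(
        seed=11,
        n_contigs=2,
        contig_length_bp=150_000,
        background_burden=800,
        exposure_burden=1500,
        n_genes=20,
        gene_length_bp=5_000,
    )
    out = tmp_path_factory.mktemp("study")
    simulate_study(cfg, out)
    return out
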