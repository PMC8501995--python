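"""Shared fixtures: one fully ground-truthed synthetic cohort reused by the
insertion-recovery and zygosity tests, plus small helper objects."""

from __future__ import annotations

import numpy as np
import pytest

from temkit import insertions, io, simulate


@pytest.fixture(scope="session")
def base_config() -> simulate.SimulationConfig:
    return simulate.SimulationConfig(
        seed=101,
        n_chromosomes=2,
        chromosome_length=200_000,
        depth=30.0,
        het_fraction=0.4,
    )


@pytest.fixture(scope="session")
def sim_genome(base_config):
    return simulate.simulate_genome(base_config)


@pytest.fixture(scope="session")
def donors(base_config):
    return simulate.make_donor_copies(base_config)


@pytest.fixture(scope="session")
def cohort(base_config, sim_genome, donors):
    """A diploid line with 50 planted insertions sequenced at 30x, with its
    reads, truth alignments and junction calls."""
    line = simulate.plant_insertions(
        sim_genome, donors, 50, base_config, seed=102, line_id="hcSim1"
    )
    reads = simulate.simulate_reads(line, base_config, seed=103)
    jcfg = insertions.JunctionConfig(head=donors.head, tail=donors.tail)
    calls = insertions.find_insertions(
        reads.sequences(), sim_genome.chromosomes, jcfg, line_id="hcSim1"
    )
    return {
        "config": base_config,
        "sim": sim_genome,
        "donors": donors,
        "line": line,
        "reads": reads,
        "jcfg": jcfg,
        "calls": calls,
        "truth": {(i.chrom, i.position): i for i in line.insertions},
    }


@pytest.fixture(scope="session")
def cohort_sam_records(cohort):
    """Truth alignments as pysam records (session-cached)."""
    return list(io.sam_records(cohort["reads"]))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
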