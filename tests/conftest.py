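"""Shared fixtures: small k-mer specs, hash families, and simulated read sets."""

import pytest
from hypothesis import settings

from kmerprep import HashFamily, KmerSpec, SequenceRecord, SimulationParams

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")
from kmerprep.simulate import simulate_genome, simulate_reads


@pytest.fixture
def spec3():
    return KmerSpec(k=3, canonical=True)


@pytest.fixture
def spec20():
    return KmerSpec(k=20, canonical=True)


@pytest.fixture
def small_family():
    """Tables big enough that desk-scale tests are collision-free w.h.p."""
    return HashFamily.from_request(100_003, 4)


@pytest.fixture
def big_family():
    """Tables sized for simulated genomes at <1% occupancy."""
    return HashFamily.from_request(2_000_003, 4)


@pytest.fixture
def homopolymer_reads():
    """The digital-normalization worked example: 10 copies of AAAAAAAA."""
    return [
        SequenceRecord(id=f"copy{i}", sequence="AAAAAAAA", quality="IIIIIIII")
        for i in range(10)
    ]


@pytest.fixture
def sim_genome():
    return simulate_genome(5_000, seed=42)


@pytest.fixture
def sim_reads(sim_genome):
    """20x error-free reads from a circular genome: every k-mer well covered."""
    params = SimulationParams(
        genome_length=5_000, read_length=100, coverage=20.0,
        error_rate=0.0, seed=7, circular=True,
    )
    return simulate_reads(sim_genome, params)
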