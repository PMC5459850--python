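import numpy as np
import pytest

from mirpeaks.core import GenomeInterval, MappedRead
from mirpeaks.preprocess import FilterParams, select_informative_frame
from mirpeaks.simulate import SimConfig, simulate_genome, simulate_reads


def make_read(chrom, start, end, strand="+", sample="S1"):
    return MappedRead(sample, GenomeInterval(chrom, start, end, strand))


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic cohort shared across the suite."""
    sim = simulate_genome(SimConfig(seed=20260901))
    reads = simulate_reads(sim)
    informative = select_informative_frame(reads, sim.repeats, FilterParams())
    return sim, reads, informative


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
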