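import numpy as np
import pytest

from cifi.contacts import MonomerAlignment
from cifi.simulate import SimConfig, simulate_genome, simulate_reads


def monomers_from_truth(truth):
    """Build MonomerAlignment objects straight from a simulator truth table."""
    return [
        MonomerAlignment(
            read_id=r.read_id,
            ordinal=r.ordinal,
            chrom=r.chrom,
            start=r.start,
            end=r.end,
            strand=r.strand,
            mapq=r.mapq,
        )
        for r in truth.itertuples()
    ]


@pytest.fixture(scope="session")
def small_sim():
    """A modest two-chromosome simulation reused across test modules."""
    cfg = SimConfig(
        seed=42,
        chrom_lengths=(400_000, 300_000),
        n_reads=400,
        segments_median=5,
        trans_fraction=0.2,
        alpha=1.0,
        min_cis_dist=1000,
    )
    genome = simulate_genome(cfg)
    readset = simulate_reads(genome, cfg)
    return genome, readset


@pytest.fixture(scope="session")
def small_monomers(small_sim):
    _, readset = small_sim
    return monomers_from_truth(readset.truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
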