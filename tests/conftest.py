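"""Shared fixtures: simulated datasets and pipeline runs reused across tests."""

import numpy as np
import pytest

from ovgraph import evalbench, simreads
from ovgraph.io_paf import Read, ReadSet, RunConfig
from ovgraph.graph_core import run_iterations


@pytest.fixture(scope="session")
def clean_dataset():
    """100-kb repeat-free genome, 30x error-free reads with truth."""
    genome = simreads.random_genome(100_000, seed=11)
    reads, placements = simreads.sample_reads(
        genome, depth=30, mean_len=13_000, len_sd=2_600, err_rate=0.0, seed=12
    )
    return genome, reads, placements


@pytest.fixture(scope="session")
def noisy_dataset():
    """Same genome, 13% error at the 23:31:46 mismatch:ins:del ratio."""
    genome = simreads.random_genome(100_000, seed=11)
    reads, placements = simreads.sample_reads(
        genome, depth=30, mean_len=13_000, len_sd=2_600,
        err_rate=0.13, err_ratio=(23, 31, 46), seed=12,
    )
    return genome, reads, placements


@pytest.fixture(scope="session")
def clean_run(clean_dataset):
    genome, reads, placements = clean_dataset
    graph, profile, state = run_iterations(reads, RunConfig(rng_seed=5))
    truth = evalbench.build_truth(placements=placements)
    return dict(genome=genome, reads=reads, placements=placements,
                graph=graph, profile=profile, state=state, truth=truth)


@pytest.fixture(scope="session")
def noisy_run(noisy_dataset):
    genome, reads, placements = noisy_dataset
    graph, profile, state = run_iterations(reads, RunConfig(rng_seed=5))
    truth = evalbench.build_truth(placements=placements)
    return dict(genome=genome, reads=reads, placements=placements,
                graph=graph, profile=profile, state=state, truth=truth)


@pytest.fixture(scope="session")
def misjoin_case():
    """A chimeric contig joining two distant genome segments, plus a clean
    control contig, with 30x error-free reads realigned to both."""
    from ovgraph import asmqc

    genome = simreads.random_genome(260_000, seed=21)
    g = genome.seq
    contigs = ReadSet([
        Read(0, "clean", g[10_000:80_000]),
        Read(1, "chim", g[90_000:135_000] + g[190_000:240_000]),
    ])
    junction = 45_000
    # 16-kb reads so a junction window is dominated by clipped alignments
    reads, placements = simreads.sample_reads(
        genome, depth=30, mean_len=16_000, len_sd=1_000, err_rate=0.0, seed=22
    )
    records = asmqc.map_reads_to_contigs(reads, contigs)
    return dict(genome=genome, contigs=contigs, junction=junction,
                reads=reads, records=records, depth=30.0)


def make_reads(seqs):
    """Helper: a ReadSet from bare sequences."""
    return ReadSet(Read(i, f"r{i}", s) for i, s in enumerate(seqs))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
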