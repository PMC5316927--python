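import numpy as np
import pytest

from wgdkit import corefind, simulate


@pytest.fixture(scope="session")
def planted_genome():
    """30-kb genome with a 3-fold collapsed repeat and a 2-copy retained repeat."""
    return simulate.simulate_genome(
        30_000,
        [
            simulate.FeatureSpec("collapsed", 1500, 3, 1),
            simulate.FeatureSpec("repeated_non_collapsed", 1500, 2),
        ],
        gc=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def planted_reads(planted_genome):
    return simulate.simulate_reads(planted_genome, depth=20, read_length=50, seed=12)


@pytest.fixture(scope="session")
def planted_tracks(planted_genome, planted_reads):
    return corefind.coverage_from_reads(planted_reads, planted_genome.assembly, seed=13)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
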