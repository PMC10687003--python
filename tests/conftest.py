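import numpy as np
import pytest
from hypothesis import settings

from epidiff.genome import GenomeLayout, Interval
from epidiff.simulate import (
    SimulationConfig,
    simulate_5hmc_counts,
    simulate_methylation,
    simulate_truth,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_truth():
    """Default study conditions: 2 x 5 Mb, 50 gain + 50 loss planted DhMRs
    at fold 3, 30 hyper + 30 hypo planted DMRs at delta 0.3."""
    return simulate_truth(SimulationConfig(), seed=1)


@pytest.fixture(scope="session")
def hmc_counts(default_truth):
    return simulate_5hmc_counts(default_truth)


@pytest.fixture(scope="session")
def meth_sites(default_truth):
    return simulate_methylation(default_truth)


@pytest.fixture(scope="session")
def fixture_dir(default_truth, tmp_path_factory):
    from epidiff.simulate import write_fixture

    out = tmp_path_factory.mktemp("fixture")
    write_fixture(out, default_truth)
    return out


@pytest.fixture
def small_layout():
    return GenomeLayout(("chr1", "chr2"), (10_000, 5_000))


def make_interval(chrom="chr1", start=0, end=100, strand=".", label=None):
    return Interval(chrom, start, end, strand, label)
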