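import numpy as np
import pytest

from clonecomp import NoiseModel, RunConfig, simulate_sample
from clonecomp.simulate import CNVEvent, ClonalArchitecture


@pytest.fixture(scope="session")
def cfg():
    return RunConfig()


@pytest.fixture(scope="session")
def deletion_arch():
    """One clone at overall fraction 0.6 carrying a 30-Mb single-copy
    deletion on chromosome 1."""
    return ClonalArchitecture(
        purity=0.6,
        clones={"c1": 1.0},
        events=[
            CNVEvent(chrom="1", start_bp=40_000_001, end_bp=70_000_000,
                     n_total=1, n_minor=0, clone_id="c1")
        ],
    )


@pytest.fixture(scope="session")
def deletion_sample(deletion_arch):
    """Zero-noise rendering of the 30-Mb deletion (40k probes)."""
    return simulate_sample(deletion_arch, NoiseModel.zero_noise(n_probes=40_000), seed=7)
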