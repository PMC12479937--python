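import numpy as np
import pytest

from shaman import CohortConfig, ParcelTimeseries, generate_cohort


@pytest.fixture(scope="session")
def tiny_cohort():
    """16 nodes x 96 frames x 24 participants, deterministic."""
    return generate_cohort(CohortConfig(
        n_nodes=16, n_frames=96, n_participants=24, seed=1234))


@pytest.fixture()
def toy_ts():
    """3 nodes x 6 frames with hand-set FD, two runs."""
    rng = np.random.default_rng(7)
    data = rng.standard_normal((3, 6))
    fd = np.array([0.05, 0.25, 0.15, 0.40, 0.10, 0.30])
    return ParcelTimeseries(data=data, fd=fd, run_starts=[0, 3], tr=0.8)
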