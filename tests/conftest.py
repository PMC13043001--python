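import numpy as np
import pytest

from cryopick.proposals import InstanceProposal
from cryopick.simdata import SynthConfig, simulate_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_scene():
    """A 256-pixel scene with contaminants at SNR 0.3 (shared, read-only)."""
    cfg = SynthConfig(size=256, n_particles=8, radius_mean=10, radius_sd=1.5,
                      snr=0.3, n_contaminants=2, seed=7)
    return simulate_scene(cfg)


@pytest.fixture(scope="session")
def clean_scene():
    """A noise-free scene (snr=inf) for ideal-input contracts."""
    cfg = SynthConfig(size=256, n_particles=8, radius_mean=10, radius_sd=1.5,
                      snr=float("inf"), n_contaminants=0, seed=11)
    return simulate_scene(cfg)


def disk_mask(shape, cx, cy, r):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= r * r


def make_proposal(shape, cx, cy, r, score):
    return InstanceProposal.from_mask(disk_mask(shape, cx, cy, r), score)


@pytest.fixture
def proposal_factory():
    return make_proposal
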