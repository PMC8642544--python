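"""Shared fixtures.

The expensive artifacts — a fully trained XOR teacher and its distilled
spiking network — are session-scoped and shared between the acceptance
tests, so the complete pipeline runs exactly once per session.
"""

import numpy as np
import pytest

from adsnet.distill import ADSNetworkParameters, FeedbackSchedule, train_ads
from adsnet.tasks import xor_sampler
from adsnet.teacher import RateNetworkParameters, train_rnn

XOR_TEACHER_SEED = 1
ADS_SEED = 5


@pytest.fixture(scope="session")
def sampler():
    return xor_sampler()


@pytest.fixture(scope="session")
def xor_teacher(sampler):
    """Teacher rate network trained on the temporal XOR task
    (64 units, 20 epochs of 500 samples)."""
    params0 = RateNetworkParameters.initialise(
        64, 1, 1, np.random.default_rng([XOR_TEACHER_SEED, 1]))
    params, losses = train_rnn(
        sampler, params0, epochs=20, samples_per_epoch=500, lr=2e-3,
        rng=np.random.default_rng([XOR_TEACHER_SEED, 2]))
    return params, losses


@pytest.fixture(scope="session")
def xor_ads(sampler, xor_teacher):
    """Spiking network distilled from the XOR teacher at reduced size
    (N=160, 500 samples, fixed k=75, eta=1e-5).

    Returns (trained parameters, training record, untrained initial
    parameters)."""
    teacher, _ = xor_teacher
    init = ADSNetworkParameters.initialise(
        teacher, 160, np.random.default_rng([ADS_SEED, 1]))
    schedule = FeedbackSchedule.xor(n_samples=500)
    params, record = train_ads(teacher, init.copy(), sampler, schedule,
                               np.random.default_rng([ADS_SEED, 2]))
    return params, record, init


@pytest.fixture
def tiny_teacher():
    """Small untrained teacher for structural tests."""
    return RateNetworkParameters.initialise(8, 2, 1,
                                            np.random.default_rng(0))
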