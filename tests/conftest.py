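"""Shared fixtures.

Heavy simulated epochs are session-scoped and shared across test
modules; small unit tests build their own light fixtures.
"""

import numpy as np
import pytest

from syncond import PipelineConfig, reconstruct, run_pipeline
from syncond.core import CURRENT_CLAMP
from syncond.simulate import (
    ConductanceTemplate,
    NeuronParams,
    Protocol,
    make_phenotype_fixture,
    make_standard_fixture,
    simulate,
)


def small_protocol(mode=CURRENT_CLAMP, levels=(-200.0, -125.0, -50.0),
                   cycles_per_level=5, sample_rate=2500.0):
    """A light-weight protocol for unit tests (QC-passing, fast)."""
    if mode != CURRENT_CLAMP:
        levels = (-95.0, -80.0, -65.0)
    return Protocol(mode=mode, levels=levels,
                    cycles_per_level=cycles_per_level,
                    sample_rate=sample_rate)


def small_fixture(seed=0, noise_sd=0.0, mode=CURRENT_CLAMP,
                  gi_peak=6.0, ge_peak=2.0):
    params = NeuronParams(noise_sd=noise_sd, rng_seed=seed)
    gi = (ConductanceTemplate(shape="bell", window=(0.30, 0.95),
                              peak=gi_peak),)
    ge = (ConductanceTemplate(shape="bell", window=(0.00, 0.45),
                              peak=ge_peak),)
    return simulate(params, gi, ge, small_protocol(mode=mode))


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def std_noiseless(config):
    """Standard fixture, no noise, reconstructed."""
    rec, truth = make_standard_fixture(seed=1, noise_sd=0.0)
    return rec, truth, reconstruct(rec, config)


@pytest.fixture(scope="session")
def std_noisy(config):
    """Standard fixture, 0.5 mV noise, reconstructed."""
    rec, truth = make_standard_fixture(seed=1, noise_sd=0.5)
    return rec, truth, reconstruct(rec, config)


@pytest.fixture(scope="session")
def rampi_result(config):
    """ramp-I phenotype fixture through the full pipeline with motifs."""
    rec, truth = make_phenotype_fixture("ramp-I", seed=1, noise_sd=0.5)
    return rec, truth, run_pipeline(rec, config, target="ramp-I")


@pytest.fixture(scope="session")
def small_result(config):
    rec, truth = small_fixture(seed=3, noise_sd=0.25)
    return rec, truth, reconstruct(rec, config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
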