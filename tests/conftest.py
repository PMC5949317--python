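"""Shared fixtures: synthetic datasets and the full study, computed once."""

import logging

import pytest

from kmnir import SimulationConfig, pipeline, simulate_dataset, pure_scatter_dataset

logging.getLogger("kmnir").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def default_dataset(default_config):
    """Default sieved-powder study: 30 base samples x 7 fractions, seed 1."""
    return simulate_dataset(default_config)


@pytest.fixture(scope="session")
def zero_noise_dataset(default_config):
    return simulate_dataset(default_config.zero_noise())


@pytest.fixture(scope="session")
def scatter_only_dataset(default_config):
    """Identical chemistry across samples; only particle size and noise vary."""
    return pure_scatter_dataset(default_config)


@pytest.fixture(scope="session")
def full_study(default_dataset):
    """The complete study on the default dataset (shared across tests)."""
    spectra, references, _ = default_dataset
    return pipeline.run_full_study(spectra, references)


@pytest.fixture(scope="session")
def zero_noise_study(zero_noise_dataset):
    spectra, references, _ = zero_noise_dataset
    return pipeline.run_full_study(spectra, references)
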