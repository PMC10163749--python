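"""Shared fixtures: a small synthetic world for linkage tests."""

from dataclasses import replace

import pytest

import bayeslink as bl


@pytest.fixture(scope="session")
def model():
    return bl.demo_frequency_model(total_population=2000)


@pytest.fixture(scope="session")
def config():
    # n_p matches the synthetic world size; k_postcode = 1 because the
    # synthetic population is spread across the whole synthetic geography.
    return replace(bl.MatchConfig(), n_p=2000, k_postcode=1.0)


@pytest.fixture(scope="session")
def population(model, config):
    return bl.generate_population(250, model, config, seed=11)


@pytest.fixture(scope="session")
def linked_world(model, config, population):
    """An error-injected proband/sample pair with its linkage results."""
    probands, sample, truth = bl.derive_sample_with_errors(
        population, overlap_fraction=0.6, profile=bl.ErrorProfile(),
        model=model, seed=12)
    results = bl.link_datasets(probands, sample, config, model=model)
    return probands, sample, truth, results
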