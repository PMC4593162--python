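"""Shared fixtures: a small synthetic world and its assembled model inputs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from gdiet.covariates import build_covariates
from gdiet.standardize import standardize_surveys
from gdiet.synthetic import (WorldConfig, generate_world, populations_table,
                             raw_covariates_table, simulate_fao, simulate_surveys)

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_config() -> WorldConfig:
    """2 regions x 2 countries, one food: cheap enough for unit tests."""
    return WorldConfig(n_regions=2, countries_per_region=2, foods=("fruits",), rng_seed=11)


@pytest.fixture(scope="session")
def tiny_world(tiny_config):
    return generate_world(tiny_config)


@pytest.fixture(scope="session")
def tiny_bundle(tiny_config, tiny_world):
    """World plus every table the model consumes."""
    surveys = simulate_surveys(tiny_world)
    fao = simulate_fao(tiny_world)
    covs, _ = build_covariates(fao, raw_covariates_table(tiny_world))
    return {
        "config": tiny_config,
        "world": tiny_world,
        "surveys": surveys,
        "std_obs": standardize_surveys(surveys),
        "fao": fao,
        "covariates": covs,
        "populations": populations_table(tiny_world),
    }
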