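"""Shared fixtures: a miniature world and the estimation chain run on it.

Expensive artifacts (the crosswalk model, prevalence draws, a full pipeline
run) are session-scoped so many tests can interrogate the same run.
"""
import numpy as np
import pandas as pd
import pytest

import bmiburden as bb
from bmiburden.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def tiny_config():
    return bb.WorldConfig(
        n_counties=6,
        years=(2000, 2001),
        age_groups=[("20-44", 20), ("45-64", 45)],
        races=["Black", "White"],
        survey_size=2500,
        seed=42,
    )


@pytest.fixture(scope="session")
def tiny_world(tiny_config):
    return bb.build_world(tiny_config)


@pytest.fixture(scope="session")
def tiny_calibration(tiny_world):
    return bb.generate_calibration(tiny_world, 2000, rng_seed=7)


@pytest.fixture(scope="session")
def tiny_model(tiny_calibration):
    return bb.fit_crosswalk(tiny_calibration)


@pytest.fixture(scope="session")
def tiny_surveys(tiny_world):
    return pd.concat(
        [
            bb.generate_survey(tiny_world, year, rng_seed=100 + i)
            for i, year in enumerate(tiny_world.config.year_list)
        ],
        ignore_index=True,
    )


@pytest.fixture(scope="session")
def adjusted_sets(tiny_model, tiny_surveys):
    return bb.apply_crosswalk(tiny_model, tiny_surveys, n_sets=2, rng_seed=11)


@pytest.fixture(scope="session")
def prevalence(tiny_world, adjusted_sets):
    return bb.estimate_prevalence(
        adjusted_sets,
        tiny_world.population,
        tiny_world.graph,
        tiny_world.covariates,
        n_draws=25,
        seed=13,
    )


@pytest.fixture(scope="session")
def pipeline_config():
    world = bb.WorldConfig(
        n_counties=4,
        years=(2000, 2001),
        age_groups=[("20-44", 20), ("45-64", 45)],
        races=["Black", "White"],
        survey_size=800,
        pop_range=(50, 500),  # small enough that some (county, race) mask
        seed=3,
    )
    return PipelineConfig(
        world=world, n_sets=2, n_draws=5, seed=5, calibration_n=600
    )


@pytest.fixture(scope="session")
def pipeline_run(pipeline_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("pipeline")
    return run_pipeline(pipeline_config, outdir)


def constant_draws(value, n_draws=100, key="x"):
    """A DrawMatrix with a single key row of constant draws."""
    return bb.DrawMatrix(
        pd.DataFrame({"k": [key]}), np.full((1, n_draws), float(value))
    )
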