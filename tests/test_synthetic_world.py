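"""The generator must be deterministic, conserve population, carry a
self-consistent ground truth, and bias self-reports in the documented
direction."""
import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.stats import lognorm

import bmiburden as bb
from bmiburden.errors import ConfigError, DomainError


def small_config(**kw):
    base = dict(
        n_counties=4,
        years=(2000, 2000),
        age_groups=[("20-44", 20), ("45-64", 45)],
        races=["Black", "White"],
        survey_size=1000,
        seed=1,
    )
    base.update(kw)
    return bb.WorldConfig(**base)


# ----------------------------------------------------------------------
def test_same_seed_gives_identical_world_and_survey():
    w1 = bb.build_world(small_config())
    w2 = bb.build_world(small_config())
    pd.testing.assert_frame_equal(w1.exposure, w2.exposure)
    pd.testing.assert_frame_equal(w1.population, w2.population)
    pd.testing.assert_frame_equal(w1.ylls, w2.ylls)
    s1 = bb.generate_survey(w1, 2000, rng_seed=9)
    s2 = bb.generate_survey(w2, 2000, rng_seed=9)
    pd.testing.assert_frame_equal(s1, s2)
    c1 = bb.generate_calibration(w1, 500, rng_seed=4)
    c2 = bb.generate_calibration(w2, 500, rng_seed=4)
    pd.testing.assert_frame_equal(c1, c2)


def test_stratum_count_minimal_config():
    cfg = small_config(
        n_counties=2, age_groups=[("20plus", 20)], sexes=["female"], races=["White"]
    )
    world = bb.build_world(cfg)
    assert len(world.population) == 2
    assert len(world.exposure) == 2


def test_population_conservation():
    world = bb.build_world(small_config())
    assert world.population.population.sum() == world.total_population


def test_county_graph_connected_with_extra_edges():
    world = bb.build_world(small_config(n_counties=7, n_extra_edges=3))
    import networkx as nx

    assert nx.is_connected(world.graph)
    assert world.graph.number_of_nodes() == 7
    assert not any(a == b for a, b in world.graph.edges())


def test_ground_truth_matches_numeric_integration():
    """Integrating the true density above 30 reproduces the stored truth.

    The oracle integrates scipy's log-normal pdf with explicit truncation,
    independent of the package's closed-form tail."""
    world = bb.build_world(small_config())
    for _, row in world.exposure.head(5).iterrows():
        scale = np.exp(row.mu)
        mass = lognorm.cdf(80, row.sigma, scale=scale) - lognorm.cdf(
            10, row.sigma, scale=scale
        )
        val, _ = integrate.quad(
            lambda x: lognorm.pdf(x, row.sigma, scale=scale) / mass, 30, 80
        )
        assert abs(val - row.true_p30) < 1e-6


def test_covariate_effect_zero_gives_no_poverty_correlation():
    """With covariate effects switched off, county poverty and true obesity
    are uncorrelated (within-race, across 50 counties)."""
    cfg = small_config(
        n_counties=50, beta_p25=(0.0, 0.0, 0.0), beta_obesity=(0.0, 0.0, 0.0)
    )
    world = bb.build_world(cfg)
    sub = world.exposure.query("race == 'White' and sex == 'female'")
    by_county = sub.groupby("county").true_p30.mean()
    pov = world.covariates.query("race == 'White'").set_index("county").poverty_rate
    r = np.corrcoef(by_county[pov.index], pov)[0, 1]
    assert abs(r) < 0.2


def test_recorded_effects_present():
    world = bb.build_world(small_config())
    assert world.effects["beta_p25"] == world.config.beta_p25
    assert set(world.effects["race_off_p25"]) == set(world.config.races)


# ----------------------------------------------------------------------
def test_zero_bias_selfreport_equals_truth():
    world = bb.build_world(small_config(bias=bb.BiasSpec.zero()))
    survey = bb.generate_survey(world, 2000, rng_seed=2)
    assert np.array_equal(survey.bmi_selfreport.values, survey.bmi_true.values)


def test_constant_shift_bias():
    world = bb.build_world(
        small_config(bias=bb.BiasSpec(0.5, 0.0, {}, {}, {}, {}))
    )
    survey = bb.generate_survey(world, 2000, rng_seed=2)
    np.testing.assert_allclose(
        survey.bmi_selfreport.values, survey.bmi_true.values - 0.5, atol=1e-12
    )


def test_bias_direction_underestimation():
    """Positive deltas push mean self-report below mean true BMI in every
    stratum with enough respondents."""
    world = bb.build_world(small_config(survey_size=8000))
    survey = bb.generate_survey(world, 2000, rng_seed=2)
    g = survey.groupby(bb.STRATUM_KEYS).agg(
        self_mean=("bmi_selfreport", "mean"),
        true_mean=("bmi_true", "mean"),
        n=("bmi_true", "size"),
    )
    big = g[g.n >= 30]
    assert len(big) > 10
    assert (big.self_mean < big.true_mean).all()


def test_survey_counts_proportional_to_population():
    """Two strata in the same county with a 2:1 population ratio receive
    respondents in a 2:1 ratio (multinomial oracle, 200 replicates)."""
    cfg = small_config(
        n_counties=2, age_groups=[("20plus", 20)], races=["Black", "White"],
        nonresponse_strength=0.0, survey_size=400,
    )
    world = bb.build_world(cfg)
    pop = world.population
    # force known populations for two strata of county c000
    mask_a = (pop.county == "c000") & (pop.race == "Black") & (pop.sex == "female")
    mask_b = (pop.county == "c000") & (pop.race == "White") & (pop.sex == "female")
    pop.loc[mask_a, "population"] = 2000
    pop.loc[mask_b, "population"] = 1000
    world.propensity["propensity"] = 1.0
    tot_a = tot_b = 0
    for rep in range(200):
        s = bb.generate_survey(world, 2000, rng_seed=1000 + rep)
        grp = s.groupby(["county", "race", "sex"]).size()
        tot_a += grp.get(("c000", "Black", "female"), 0)
        tot_b += grp.get(("c000", "White", "female"), 0)
    ratio = tot_a / tot_b
    # delta-method standard error of the count ratio
    se = ratio * np.sqrt(1 / tot_a + 1 / tot_b)
    assert abs(ratio - 2.0) < 3 * se


def test_survey_year_out_of_range():
    world = bb.build_world(small_config())
    with pytest.raises(DomainError):
        bb.generate_survey(world, 1990, rng_seed=0)


def test_survey_weights_positive_and_bmi_in_support():
    world = bb.build_world(small_config())
    s = bb.generate_survey(world, 2000, rng_seed=3)
    assert (s.weight > 0).all()
    assert ((s.bmi_selfreport > 10) & (s.bmi_selfreport < 80)).all()


# ----------------------------------------------------------------------
def test_calibration_identity_when_noise_and_bias_zero():
    world = bb.build_world(
        small_config(bias=bb.BiasSpec.zero(), calibration_noise_sd=0.0)
    )
    cal = bb.generate_calibration(world, 200, rng_seed=5)
    np.testing.assert_array_equal(cal.bmi_measured.values, cal.bmi_selfreport.values)


def test_calibration_mean_gap_recovers_delta0():
    """With a pure constant shift, the mean measured-minus-self-report gap
    is delta0 up to CLT noise (n = 5000)."""
    world = bb.build_world(small_config(bias=bb.BiasSpec(1.0, 0.0, {}, {}, {}, {})))
    cal = bb.generate_calibration(world, 5000, rng_seed=6)
    gap = cal.bmi_measured - cal.bmi_selfreport
    se = gap.std() / np.sqrt(len(gap))
    assert abs(gap.mean() - 1.0) < 3 * se


def test_calibration_covers_every_cell_and_rejects_tiny_n():
    world = bb.build_world(small_config())
    cal = bb.generate_calibration(world, 100, rng_seed=5)
    cells = cal.groupby(["age_group", "sex", "race"]).size()
    assert len(cells) == 2 * 2 * 2
    with pytest.raises(DomainError):
        bb.generate_calibration(world, 3, rng_seed=5)


# ----------------------------------------------------------------------
@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_counties": 1},
        {"years": (2005, 2000)},
        {"age_groups": [("20-44", 20), ("bad", 20)]},
        {"age_groups": [("30-44", 30)]},
        {"sexes": []},
        {"pop_range": (0, 10)},
        {"bias": bb.BiasSpec(0.0, 1.5, {}, {}, {}, {})},
    ],
)
def test_invalid_config_raises_named_error(kwargs):
    with pytest.raises(ConfigError):
        bb.build_world(small_config(**kwargs))
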