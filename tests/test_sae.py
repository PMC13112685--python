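"""Small-area model behavior: tabulation arithmetic, degenerate-data
limits, smoothing of empty counties, poststratification, and the
probability logic tying the two outcome models together."""
import numpy as np
import pandas as pd
import pytest

import bmiburden as bb
from bmiburden.errors import AlignmentError, EstimationError, SchemaError
from bmiburden.exposure import lognormal_params_from_tails
from bmiburden.sae import SaeSpec, fit_sae, tabulate


def make_survey(rows):
    base = {"year": 2000, "county": "c000", "age_group": "20plus",
            "sex": "female", "race": "White"}
    return pd.DataFrame([{**base, **r} for r in rows])


def single_cell_tab(p_hat, ess):
    return pd.DataFrame(
        {
            "year": [2000], "county": ["c000"], "age_group": ["20plus"],
            "ess": [ess], "p25_hat": [p_hat],
            "ess_ge25": [ess], "p30given25_hat": [p_hat],
        }
    )


def single_county_graph(n=1):
    import networkx as nx

    g = nx.Graph()
    ids = [f"c{i:03d}" for i in range(n)]
    g.add_nodes_from(ids)
    g.add_edges_from(zip(ids, ids[1:]))
    return g


FLAT_COV = pd.DataFrame(
    {
        "county": [f"c{i:03d}" for i in range(10)],
        "z_poverty": 0.0, "z_foreign_born": 0.0, "z_log_density": 0.0,
    }
)


# ----------------------------------------------------------------------
def test_tabulate_single_record():
    t = tabulate(
        make_survey([{"bmi_adjusted": 31.0, "weight": 1.0}]),
        bmi_col="bmi_adjusted",
    )
    assert t.p25_hat.iloc[0] == 1.0
    assert t.p30given25_hat.iloc[0] == 1.0
    assert t.ess.iloc[0] == 1.0


def test_tabulate_equal_weights():
    t = tabulate(
        make_survey(
            [{"bmi_adjusted": 24.0, "weight": 1.0},
             {"bmi_adjusted": 31.0, "weight": 1.0}]
        ),
        bmi_col="bmi_adjusted",
    )
    assert t.p25_hat.iloc[0] == 0.5


def test_tabulate_weighted_proportion_and_ess():
    """Weights (1, 3) on BMIs (24, 31): p25 = 0.75, ESS = 16/10 = 1.6."""
    t = tabulate(
        make_survey(
            [{"bmi_adjusted": 24.0, "weight": 1.0},
             {"bmi_adjusted": 31.0, "weight": 3.0}]
        ),
        bmi_col="bmi_adjusted",
    )
    assert t.p25_hat.iloc[0] == 0.75
    assert t.ess.iloc[0] == pytest.approx(1.6)


def test_tabulate_retains_empty_strata_and_rejects_negative_weights():
    strata = pd.DataFrame(
        {
            "year": [2000, 2000], "county": ["c000", "c001"],
            "age_group": "20plus", "sex": "female", "race": "White",
        }
    )
    t = tabulate(
        make_survey([{"bmi_adjusted": 31.0, "weight": 2.0}]),
        bmi_col="bmi_adjusted", strata=strata,
    )
    assert len(t) == 2
    empty = t[t.county == "c001"]
    assert (empty.n_records == 0).all()
    with pytest.raises(SchemaError):
        tabulate(
            make_survey([{"bmi_adjusted": 31.0, "weight": -1.0}]),
            bmi_col="bmi_adjusted",
        )


# ----------------------------------------------------------------------
def test_single_cell_beta_binomial_limit():
    """1000 Bernoulli(0.4) trials in one cell: the posterior concentrates
    on 0.4 (within 3 posterior standard deviations)."""
    fit = fit_sae(
        SaeSpec("p25", n_draws=400),
        single_cell_tab(0.4, 1000.0),
        single_county_graph(1),
        FLAT_COV,
        rng_seed=0,
    )
    post = fit.p_draws[0]
    assert abs(post.mean() - 0.4) < 3 * post.std()
    assert post.std() < 0.05


def test_empty_county_predicted_from_neighbors():
    """A county with no respondents is predicted by spatial smoothing:
    its posterior mean lies in the neighbors' range widened by 2 sds."""
    counties = [f"c{i:03d}" for i in range(4)]
    rows = []
    p_by_county = {"c000": 0.55, "c001": 0.60, "c003": 0.58}
    for c in counties:
        rows.append(
            {
                "year": 2000, "county": c, "age_group": "20plus",
                "ess": 0.0 if c == "c002" else 500.0,
                "p25_hat": p_by_county.get(c, np.nan),
                "ess_ge25": 0.0, "p30given25_hat": np.nan,
            }
        )
    fit = fit_sae(
        SaeSpec("p25", n_draws=300),
        pd.DataFrame(rows),
        single_county_graph(4),
        FLAT_COV,
        rng_seed=1,
    )
    cells = fit.cells.reset_index(drop=True)
    idx = cells.index[cells.county == "c002"][0]
    post = fit.p_draws[idx]
    lo = min(p_by_county.values()) - 2 * post.std()
    hi = max(p_by_county.values()) + 2 * post.std()
    assert lo <= post.mean() <= hi


def test_fit_requires_observations_and_connected_graph():
    import networkx as nx

    with pytest.raises(EstimationError):
        fit_sae(
            SaeSpec("p25", n_draws=10), single_cell_tab(np.nan, 0.0),
            single_county_graph(1), FLAT_COV, rng_seed=0,
        )
    g = nx.Graph()
    g.add_nodes_from(["c000", "c001"])  # two components
    with pytest.raises(EstimationError):
        fit_sae(
            SaeSpec("p25", n_draws=10), single_cell_tab(0.4, 10.0), g,
            FLAT_COV, rng_seed=0,
        )


def test_fit_is_deterministic_in_seed():
    tab = single_cell_tab(0.4, 200.0)
    f1 = fit_sae(SaeSpec("p25", n_draws=50), tab, single_county_graph(1),
                 FLAT_COV, rng_seed=7)
    f2 = fit_sae(SaeSpec("p25", n_draws=50), tab, single_county_graph(1),
                 FLAT_COV, rng_seed=7)
    np.testing.assert_array_equal(f1.p_draws, f2.p_draws)


# ----------------------------------------------------------------------
def test_poststratified_aggregation_weighted_mean():
    """Two cells with populations (1000, 3000) and prevalences (0.2, 0.4)
    aggregate to 0.35; equal populations give the unweighted mean."""
    keys = pd.DataFrame(
        {
            "year": [2000, 2000], "county": ["c000", "c001"],
            "age_group": "20plus", "sex": "female", "race": "White",
        }
    )
    dm = bb.DrawMatrix(keys, np.array([[0.2, 0.2], [0.4, 0.4]]))
    pop = keys.copy()
    pop["population"] = [1000, 3000]
    ps = bb.poststratify(dm, pop)
    agg = ps.aggregate(ps.population, over=["county"])
    np.testing.assert_allclose(agg.values, 0.35)
    pop_eq = keys.copy()
    pop_eq["population"] = [500, 500]
    ps_eq = bb.poststratify(dm, pop_eq)
    agg_eq = ps_eq.aggregate(ps_eq.population, over=["county"])
    np.testing.assert_allclose(agg_eq.values, 0.3)
    with pytest.raises(SchemaError):
        bb.poststratify(dm, pop.iloc[:1])


def test_poststratification_corrects_nonresponse_bias():
    """With response propensity favoring low-BMI strata, the model-based
    poststratified national prevalence beats the raw weighted estimate in
    nearly all replicates (bias-free surveys isolate the MRP step)."""
    wins = 0
    n_reps = 20
    for rep in range(n_reps):
        cfg = bb.WorldConfig(
            n_counties=6, years=(2000, 2000),
            age_groups=[("20-44", 20), ("45-64", 45)],
            sexes=["female", "male"], races=["White"],
            survey_size=1500, bias=bb.BiasSpec.zero(),
            nonresponse_strength=1.0, seed=600 + rep,
        )
        world = bb.build_world(cfg)
        survey = bb.generate_survey(world, 2000, rng_seed=700 + rep)
        survey["bmi_adjusted"] = survey["bmi_selfreport"]
        res = bb.estimate_prevalence(
            [survey], world.population, world.graph, world.covariates,
            n_draws=30, seed=800 + rep,
        )
        ob = res["obesity"]
        pop_w = bb.population_weights(ob.keys, world.population)
        mrp = float(
            ob.aggregate(pop_w, over=bb.STRATUM_KEYS).values.mean()
        )
        truth_tbl = world.exposure.merge(world.population, on=bb.STRATUM_KEYS)
        truth = np.average(truth_tbl.true_p30, weights=truth_tbl.population)
        w = survey.weight.values
        raw = float((w * (survey.bmi_true >= 30)).sum() / w.sum())
        wins += abs(mrp - truth) < abs(raw - truth)
    assert wins >= 0.9 * n_reps


# ----------------------------------------------------------------------
def test_combine_prevalence_product_and_identity():
    keys = pd.DataFrame({"year": [2000], "county": ["c000"],
                         "age_group": ["20plus"], "sex": ["f"], "race": ["W"]})
    p25 = bb.DrawMatrix(keys, np.array([[0.7, 0.7]]))
    p30g = bb.DrawMatrix(keys, np.array([[0.5, 0.5]]))
    np.testing.assert_allclose(
        bb.combine_prevalence(p25, p30g).values, 0.35
    )
    ones = bb.DrawMatrix(keys, np.ones((1, 2)))
    np.testing.assert_allclose(
        bb.combine_prevalence(p25, ones).values, p25.values
    )
    other = bb.DrawMatrix(keys, np.ones((1, 3)))
    with pytest.raises(AlignmentError):
        bb.combine_prevalence(p25, other)


def test_obesity_draws_never_exceed_p25(prevalence):
    assert (prevalence["obesity"].values <= prevalence["p25"].values + 1e-12).all()
    prevalence["obesity"].assert_probability()


def test_national_draw_is_population_weighted_mean(prevalence, tiny_world):
    """Per-draw national prevalence equals the population-weighted mean of
    stratum draws, exactly."""
    ob = prevalence["obesity"]
    w = bb.population_weights(ob.keys, tiny_world.population)
    national = ob.aggregate(w, over=bb.STRATUM_KEYS)
    manual = (ob.values * w[:, None]).sum(axis=0) / w.sum()
    np.testing.assert_allclose(national.values[0], manual, rtol=1e-12)


def test_draw_count_is_sets_times_draws(prevalence):
    assert prevalence["obesity"].n_draws == 2 * 25


def test_pipeline_recovers_lognormal_stratum_truth():
    """A stratum whose true distribution has tails (p25, p30) = (0.6, 0.3)
    is recovered by the estimation chain within 3 posterior sds at
    survey n = 2000 (closed-form log-normal oracle)."""
    cfg = bb.WorldConfig(
        n_counties=2, years=(2000, 2000), age_groups=[("20plus", 20)],
        sexes=["female", "male"], races=["White"], survey_size=2000,
        bias=bb.BiasSpec.zero(), nonresponse_strength=0.0, seed=9,
    )
    world = bb.build_world(cfg)
    mu, sigma = lognormal_params_from_tails(0.6, 0.3)
    world.exposure["mu"] = mu
    world.exposure["sigma"] = sigma
    survey = bb.generate_survey(world, 2000, rng_seed=10)
    survey["bmi_adjusted"] = survey["bmi_selfreport"]
    res = bb.estimate_prevalence(
        [survey], world.population, world.graph, world.covariates,
        n_draws=100, seed=11,
    )
    ob = res["obesity"]
    for i in range(len(ob.keys)):
        post = ob.values[i]
        assert abs(post.mean() - 0.30) < 3 * max(post.std(), 1e-6)
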