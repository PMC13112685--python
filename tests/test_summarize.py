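"""Summarization arithmetic: means/percentiles over draws, draw-first
aggregation, age standardization, significance thresholds, dispersion,
masking, and rate ratios — including the published worked-example ratios."""
import numpy as np
import pandas as pd
import pytest

import bmiburden as bb
from bmiburden import summarize as sm
from bmiburden.errors import DomainError, SchemaError

from conftest import constant_draws


def draws_from(values, keys=None):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    keys = keys or [f"k{i}" for i in range(values.shape[0])]
    return bb.DrawMatrix(pd.DataFrame({"k": keys}), values)


# ----------------------------------------------------------------------
def test_constant_draws_collapse_to_the_constant():
    s = bb.summarize_draws(constant_draws(0.37))
    assert s["mean"].iloc[0] == pytest.approx(0.37, abs=1e-12)
    assert s.lower.iloc[0] == s.upper.iloc[0] == 0.37


def test_percentiles_linear_interpolation_order_statistics():
    """Draws 1..1000: 2.5th percentile 25.975, 97.5th 975.025 under linear
    interpolation between order statistics."""
    s = bb.summarize_draws(draws_from(np.arange(1, 1001)))
    assert s.lower.iloc[0] == pytest.approx(25.975)
    assert s.upper.iloc[0] == pytest.approx(975.025)


def test_two_draw_mean():
    s = bb.summarize_draws(draws_from([[0.2, 0.4]]))
    assert s["mean"].iloc[0] == pytest.approx(0.3)


def test_summarize_requires_at_least_two_draws():
    with pytest.raises(DomainError):
        bb.summarize_draws(draws_from([[1.0]]))


def test_interval_nesting_80_inside_95():
    rng = np.random.default_rng(0)
    dm = draws_from(rng.normal(size=(1, 500)))
    s95 = bb.summarize_draws(dm, level=95.0)
    s80 = bb.summarize_draws(dm, level=80.0)
    assert s95.lower.iloc[0] < s80.lower.iloc[0]
    assert s80.upper.iloc[0] < s95.upper.iloc[0]


# ----------------------------------------------------------------------
def test_weighted_aggregation():
    dm = draws_from([[0.2, 0.2], [0.4, 0.4]])
    np.testing.assert_allclose(
        dm.aggregate([1.0, 3.0], over=["k"]).values, 0.35
    )
    np.testing.assert_allclose(
        dm.aggregate([2.0, 2.0], over=["k"]).values, 0.3
    )


def test_both_sex_rate_population_weighting():
    """Sex-specific rates 38.0 and 42.4 with equal populations -> 40.2."""
    dm = draws_from([[38.0], [42.4]], keys=["male", "female"])
    agg = dm.aggregate([100_000.0, 100_000.0], over=["k"])
    assert agg.values[0, 0] == pytest.approx(40.2)


def test_aggregate_then_summarize_order_of_operations():
    """Aggregating draws then taking means equals averaging the summaries'
    means, but intervals must come from the draws-first path."""
    rng = np.random.default_rng(1)
    dm = draws_from(rng.uniform(0.1, 0.5, size=(4, 200)))
    w = np.array([1.0, 2.0, 3.0, 4.0])
    draws_first = bb.summarize_draws(dm.aggregate(w, over=["k"]))
    means_after = np.average(
        bb.summarize_draws(dm)["mean"], weights=w
    )
    assert draws_first["mean"].iloc[0] == pytest.approx(means_after, rel=1e-12)
    width = draws_first.upper.iloc[0] - draws_first.lower.iloc[0]
    assert width > 0


# ----------------------------------------------------------------------
def age_draws(rates, ages=("20-44", "45-64")):
    keys = pd.DataFrame({"age_group": list(ages), "race": "White"})
    return bb.DrawMatrix(keys, np.asarray(rates, dtype=float))


def test_age_standardization_weighted_sum():
    std = bb.AgeStandard({"20-44": 0.5, "45-64": 0.5})
    out = bb.age_standardize(age_draws([[10.0, 10.0], [30.0, 30.0]]), std)
    np.testing.assert_allclose(out.values, 20.0)
    flat = bb.age_standardize(age_draws([[7.0, 7.0], [7.0, 7.0]]), std)
    np.testing.assert_allclose(flat.values, 7.0)


def test_age_standard_weights_come_from_standard_not_stratum():
    """Changing the stratum's own population cannot change the
    age-standardized rate when age-specific rates are unchanged."""
    std = bb.AgeStandard({"20-44": 0.7, "45-64": 0.3})
    dm = age_draws([[12.0], [20.0]])
    out = bb.age_standardize(dm, std)
    assert out.values[0, 0] == pytest.approx(0.7 * 12 + 0.3 * 20)
    # no population argument exists on this path: invariance by design


def test_age_standard_validation():
    with pytest.raises(DomainError):
        bb.AgeStandard({"a": 0.6, "b": 0.5})
    with pytest.raises(SchemaError):
        bb.age_standardize(
            age_draws([[1.0], [2.0]]), bb.AgeStandard({"20-44": 1.0})
        )


def test_age_standard_from_population():
    pop = pd.DataFrame(
        {"year": 2000, "age_group": ["20-44", "45-64"], "population": [300, 100]}
    )
    std = bb.AgeStandard.from_population(pop)
    assert std.weights["20-44"] == pytest.approx(0.75)


# ----------------------------------------------------------------------
def test_significance_thresholds():
    def diff(n_pos, n=1000):
        vals = np.concatenate([np.ones(n_pos), -np.ones(n - n_pos)])
        return draws_from([vals])

    assert bb.significance(diff(1000))[0]
    assert not bb.significance(diff(500))[0]
    assert not bb.significance(diff(974))[0]
    assert bb.significance(diff(976))[0]
    assert bb.significance(diff(24))[0]
    assert not bb.significance(diff(26))[0]
    with pytest.raises(DomainError):
        bb.significance(draws_from([np.ones(30)]))


def test_significance_ties_at_zero_count_as_not_greater():
    """970 positive + 30 zero draws: if zeros counted as greater the share
    would be 1.0 (significant); counted as not-greater it is 0.97."""
    vals = np.concatenate([np.ones(970), np.zeros(30)])
    assert not bb.significance(draws_from([vals]))[0]


# ----------------------------------------------------------------------
def test_coefficient_of_variation():
    assert bb.coefficient_of_variation([5.0, 5.0, 5.0]) == 0.0
    assert bb.coefficient_of_variation([1.0, 3.0]) == pytest.approx(0.5)
    a = np.random.default_rng(0).uniform(1, 2, 20)
    assert bb.coefficient_of_variation(3.7 * a) == pytest.approx(
        bb.coefficient_of_variation(a)
    )
    with pytest.raises(DomainError):
        bb.coefficient_of_variation([-2.0, 1.0])
    with pytest.raises(DomainError):
        bb.coefficient_of_variation([1.0])


# ----------------------------------------------------------------------
def test_masking_strictly_below_threshold():
    summary = pd.DataFrame({"county": ["a", "b", "c"], "mean": 1.0})
    population = pd.DataFrame(
        {
            "year": [2000, 2001] * 3,
            "county": ["a", "a", "b", "b", "c", "c"],
            "population": [999, 999, 1000, 1000, 800, 1300],
        }
    )
    out = bb.mask_small(summary, population, threshold=1000)
    masked = dict(zip(out.county, out.masked))
    assert masked["a"] is np.True_ or masked["a"] == True  # noqa: E712  (999 < 1000)
    assert not masked["b"]                                 # boundary: not masked
    assert not masked["c"]                                 # mean 1050 >= 1000


# ----------------------------------------------------------------------
def test_ratio_of_equal_series_is_one_with_zero_width():
    a = constant_draws(3.3)
    r = bb.ratio_of_rates(a, a)
    assert r["mean"].iloc[0] == 1.0
    assert r.lower.iloc[0] == r.upper.iloc[0] == 1.0


def test_published_prevalence_and_yll_ratios():
    """National 2019 point estimates: obesity prevalence 49.2% vs 20.6%
    gives a ratio of 2.4; IHD attributable YLL rates 1006 vs 216 per
    100,000 give 4.7 (both at one decimal)."""
    prev = bb.ratio_of_rates(constant_draws(49.2), constant_draws(20.6))
    assert round(prev["mean"].iloc[0], 1) == 2.4
    ylls = bb.ratio_of_rates(constant_draws(1006.0), constant_draws(216.0))
    assert round(ylls["mean"].iloc[0], 1) == 4.7


def test_ratio_rejects_nonpositive_denominator():
    with pytest.raises(DomainError):
        bb.ratio_of_rates(constant_draws(1.0), constant_draws(0.0))
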