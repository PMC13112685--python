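"""Collapse draws into point estimates, intervals, and derived summaries.

Point estimates are means over draws; 95% uncertainty intervals are the
2.5th and 97.5th percentiles (linear interpolation between order
statistics).  All aggregation and age-standardization happens draw by draw
*before* summarization.  Pairwise differences are called statistically
significant when the share of difference draws above zero is below 2.5% or
above 97.5%.  Small strata (mean annual population below a threshold,
default 1000) are masked in outputs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .draws import DrawMatrix
from .errors import DomainError, SchemaError


def summarize_draws(dm: DrawMatrix, level: float = 95.0) -> pd.DataFrame:
    """Mean and percentile interval per key row."""
    if dm.n_draws < 2:
        raise DomainError("need at least 2 draws to summarize")
    lo = (100.0 - level) / 2.0
    out = dm.keys.copy()
    out["mean"] = dm.values.mean(axis=1)
    qs = np.percentile(dm.values, [lo, 100.0 - lo], axis=1, method="linear")
    out["lower"] = qs[0]
    out["upper"] = qs[1]
    return out


def aggregate(
    dm: DrawMatrix, weights, over: list[str], kind: str = "rate", name: str = ""
) -> DrawMatrix:
    """Population-weighted aggregation over key columns, draw by draw."""
    return dm.aggregate(weights, over, kind=kind, name=name)


@dataclass
class AgeStandard:
    """Reference age structure: age group -> weight, summing to 1."""

    weights: dict

    def __post_init__(self):
        w = np.array(list(self.weights.values()), dtype=float)
        if (w < 0).any():
            raise DomainError("age-standard weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise DomainError(
                f"age-standard weights must sum to 1 (got {w.sum():.15f})"
            )

    @classmethod
    def from_population(cls, population: pd.DataFrame, year=None) -> "AgeStandard":
        """Derive reference weights from a population table (the miniature
        analogue of standardizing to a census adult age structure)."""
        pop = population
        if year is not None:
            pop = pop[pop.year == year]
        totals = pop.groupby("age_group").population.sum()
        return cls((totals / totals.sum()).to_dict())


def age_standardize(dm: DrawMatrix, standard: AgeStandard) -> DrawMatrix:
    """Weighted sum over age groups with *reference* weights, per draw.

    Unlike plain aggregation, the weights come from the standard, not from
    the stratum's own population, so results are comparable across
    populations with different age structures.
    """
    if "age_group" not in dm.key_columns:
        raise SchemaError("draws have no age_group column to standardize over")
    ages = set(dm.keys["age_group"].unique())
    missing = ages - set(standard.weights)
    if missing:
        raise SchemaError(f"age standard lacks weights for {sorted(missing)}")
    if set(standard.weights) - ages:
        raise SchemaError(
            f"age groups absent from draws: {sorted(set(standard.weights) - ages)}"
        )
    w = dm.keys["age_group"].map(standard.weights).to_numpy(dtype=float)
    keep = [c for c in dm.key_columns if c != "age_group"]
    codes, uniques = pd.factorize(
        pd.MultiIndex.from_frame(dm.keys[keep]), sort=True
    )
    counts = np.bincount(codes)
    if len(set(counts)) != 1 or counts[0] != len(standard.weights):
        raise SchemaError("every group must contain every age group exactly once")
    out = np.zeros((len(uniques), dm.n_draws))
    np.add.at(out, codes, dm.values * w[:, None])
    keys = pd.DataFrame([tuple(u) for u in uniques], columns=keep)
    return DrawMatrix(keys, out, dm.name, dm.units, dm.draw_info)


def significance(diff: DrawMatrix) -> np.ndarray:
    """Two-sided posterior-probability test at alpha 0.05.

    Significant iff the share of difference draws strictly greater than 0
    is below 0.025 or above 0.975; draws exactly at 0 count as not-greater.
    """
    if diff.n_draws < 40:
        raise DomainError(
            "need >= 40 draws so a 2.5% tail probability is resolvable"
        )
    share = (diff.values > 0).mean(axis=1)
    return (share < 0.025) | (share > 0.975)


def coefficient_of_variation(values) -> float:
    """Relative dispersion: population standard deviation over the mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise DomainError("need at least 2 values")
    m = v.mean()
    if m <= 0:
        raise DomainError("coefficient of variation requires a positive mean")
    return float(v.std(ddof=0) / m)


def mask_small(
    summary: pd.DataFrame,
    population: pd.DataFrame,
    threshold: float = 1000.0,
    key_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Flag rows whose mean annual population is strictly below threshold.

    ``population`` has a year column plus key columns plus ``population``;
    the mean is over the years present.
    """
    key_cols = key_cols or [
        c for c in summary.columns
        if c in population.columns and c not in ("year", "population")
    ]
    if not key_cols:
        raise SchemaError("no key columns in common for masking")
    mean_annual = (
        population.groupby(["year", *key_cols], as_index=False)
        .population.sum()
        .groupby(key_cols, as_index=False)
        .population.mean()
        .rename(columns={"population": "_mean_annual_pop"})
    )
    out = summary.merge(mean_annual, on=key_cols, how="left")
    if out["_mean_annual_pop"].isna().any():
        raise SchemaError("population missing for some summary rows")
    out["masked"] = out["_mean_annual_pop"] < threshold
    return out.drop(columns="_mean_annual_pop")


def ratio_of_rates(num: DrawMatrix, den: DrawMatrix) -> pd.DataFrame:
    """Ratio computed draw-by-draw, then summarized."""
    num._check_aligned(den)
    if (den.values <= 0).any():
        raise DomainError("denominator draws must be strictly positive")
    return summarize_draws(num.copy_with(num.values / den.values, "ratio"))
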