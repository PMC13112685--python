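"""Quantile-based crosswalk from self-reported to measured-scale BMI.

The correction is additive on the BMI scale and estimated separately by
sex: within each sex, the gap (measured - self-reported) is regressed on a
piecewise-linear basis in the record's quantile of self-reported BMI (a
decile grid by default) plus age-group and race indicators, so there is
one correction parameter per grid quantile.  Applying the model
interpolates the quantile corrections linearly across the sex-specific BMI
knots (the self-report quantiles), with constant extrapolation beyond the
outermost knots.

Correction uncertainty is propagated by a stratified nonparametric
bootstrap: each of the requested adjusted datasets is produced by refitting
the model on a resample of the calibration records (resampling within
(sex, age, race) cells so no cell is ever lost) and applying that refit.

Quantile-crossing artifacts — fitted corrections that would make the map
x -> x + correction(x) decreasing — are repaired by isotonic projection of
the corrected knot values and logged, never silently.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression

from .errors import DomainError, EstimationError
from .synthetic_world import _BMI_EPS

logger = logging.getLogger(__name__)

DEFAULT_QUANTILE_GRID = tuple(np.round(np.arange(1, 10) / 10.0, 10))

_MIN_PER_SEX = 30


@dataclass
class SexCrosswalk:
    """Fitted correction surface for one sex."""

    knots: np.ndarray                # self-report BMI at the grid quantiles
    coef_qbin: np.ndarray            # one coefficient per grid quantile
    coef_age: dict                   # additive offsets; reference level -> 0
    coef_race: dict

    def correction_at_knots(self, age_group: str, race: str) -> np.ndarray:
        return (
            self.coef_qbin
            + self.coef_age.get(age_group, 0.0)
            + self.coef_race.get(race, 0.0)
        )


@dataclass
class CrosswalkModel:
    """Corrections by (sex, age group, race, BMI quantile bin).

    Retains the calibration records so adjusted datasets can be produced by
    bootstrap refits (one refit per requested set).
    """

    quantile_grid: np.ndarray
    by_sex: dict
    calibration: pd.DataFrame
    repairs: list = field(default_factory=list)

    def correction(self, sex: str, age_group: str, race: str, x) -> np.ndarray:
        """Interpolated additive correction for self-reported BMI ``x``,
        monotonicity-repaired so x + correction(x) is non-decreasing."""
        x = np.asarray(x, dtype=float)
        m = self.by_sex[sex]
        corr = m.correction_at_knots(age_group, race)
        corr = self._repair(m.knots, corr, (sex, age_group, race))
        return np.interp(x, m.knots, corr)

    def _repair(self, knots, corr, cell) -> np.ndarray:
        corrected = knots + corr
        if np.all(np.diff(corrected) >= 0):
            return corr
        iso = IsotonicRegression(increasing=True).fit_transform(knots, corrected)
        self.repairs.append(
            {"cell": cell, "max_change": float(np.max(np.abs(iso - corrected)))}
        )
        logger.warning(
            "crosswalk: non-monotone correction in cell %s repaired by "
            "isotonic projection (max change %.4g)",
            cell, float(np.max(np.abs(iso - corrected))),
        )
        return iso - knots

    def to_json(self, path, seed=None):
        payload = {
            "quantile_grid": list(map(float, self.quantile_grid)),
            "seed": seed,
            "by_sex": {
                s: {
                    "knots": m.knots.tolist(),
                    "coef_qbin": m.coef_qbin.tolist(),
                    "coef_age": m.coef_age,
                    "coef_race": m.coef_race,
                }
                for s, m in self.by_sex.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ----------------------------------------------------------------------
def _tent_basis(ranks: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Piecewise-linear hat functions over the quantile grid.

    Row r has weight (1 - frac) on the grid point below rank r and frac on
    the one above (constant beyond the outermost points), so a regression
    coefficient estimates the gap *at* its grid quantile rather than the
    average over a tail bin.  Rows sum to one.
    """
    k = len(grid)
    t = np.clip(np.interp(ranks, grid, np.arange(k, dtype=float)), 0.0, k - 1.0)
    lo = np.minimum(np.floor(t).astype(int), k - 2)
    frac = t - lo
    basis = np.zeros((len(ranks), k))
    basis[np.arange(len(ranks)), lo] = 1.0 - frac
    basis[np.arange(len(ranks)), lo + 1] = frac
    return basis


def _fit_one_sex(df: pd.DataFrame, grid: np.ndarray) -> SexCrosswalk:
    x = df["bmi_selfreport"].to_numpy(dtype=float)
    gap = (df["bmi_measured"] - df["bmi_selfreport"]).to_numpy(dtype=float)
    knots = np.quantile(x, grid)
    ranks = rankdata(x) / (len(x) + 1.0)
    # tail-guard knots between the outer grid quantiles and 0/1: the open
    # tails (where the gap is steepest in rank) load on these nuisance
    # coefficients, so the outermost grid coefficients estimate the gap at
    # their quantiles rather than a tail average
    low = grid[0] * np.array([1.0 / 3.0, 2.0 / 3.0])
    high = 1.0 - (1.0 - grid[-1]) * np.array([2.0 / 3.0, 1.0 / 3.0])
    fit_grid = np.concatenate((low, grid, high))
    basis = _tent_basis(ranks, fit_grid)

    age_levels = sorted(df["age_group"].unique())
    race_levels = sorted(df["race"].unique())
    cols = []
    names = []
    for j in range(len(fit_grid)):
        cols.append(basis[:, j])
        names.append(("qbin", j - 2))  # negative / >= len(grid): tail guards
    for lev in age_levels[1:]:
        cols.append((df["age_group"] == lev).to_numpy(dtype=float))
        names.append(("age", lev))
    for lev in race_levels[1:]:
        cols.append((df["race"] == lev).to_numpy(dtype=float))
        names.append(("race", lev))
    design = np.column_stack(cols)
    fit = sm.OLS(gap, design).fit()
    coef = dict(zip(names, fit.params))
    return SexCrosswalk(
        knots=knots,
        coef_qbin=np.array([coef[("qbin", j)] for j in range(len(grid))]),
        coef_age={lev: coef.get(("age", lev), 0.0) for lev in age_levels},
        coef_race={lev: coef.get(("race", lev), 0.0) for lev in race_levels},
    )


def fit_crosswalk(
    calibration: pd.DataFrame, quantile_grid=None
) -> CrosswalkModel:
    """Fit the self-report correction model on paired calibration records."""
    grid = np.asarray(
        quantile_grid if quantile_grid is not None else DEFAULT_QUANTILE_GRID,
        dtype=float,
    )
    if grid.ndim != 1 or len(grid) < 2 or np.any(np.diff(grid) <= 0):
        raise DomainError("quantile grid must be strictly increasing")
    if grid[0] <= 0 or grid[-1] >= 1:
        raise DomainError("quantile grid must lie strictly inside (0, 1)")
    required = {"sex", "age_group", "race", "bmi_selfreport", "bmi_measured"}
    missing_cols = required - set(calibration.columns)
    if missing_cols:
        raise EstimationError(f"calibration table missing columns {missing_cols}")

    by_sex = {}
    for sex, df in calibration.groupby("sex"):
        if len(df) < _MIN_PER_SEX:
            raise EstimationError(
                f"need >= {_MIN_PER_SEX} calibration records for sex {sex!r}, got {len(df)}"
            )
        ages = set(calibration["age_group"].unique())
        races = set(calibration["race"].unique())
        have = set(map(tuple, df[["age_group", "race"]].drop_duplicates().to_numpy()))
        want = {(a, r) for a in ages for r in races}
        empty = sorted(want - have)
        if empty:
            raise EstimationError(
                f"empty calibration cells for sex {sex!r}: {empty}"
            )
        by_sex[sex] = _fit_one_sex(df, grid)
    return CrosswalkModel(
        quantile_grid=grid, by_sex=by_sex, calibration=calibration.copy()
    )


def _stratified_resample(calibration: pd.DataFrame, rng) -> pd.DataFrame:
    parts = []
    for _, df in calibration.groupby(["sex", "age_group", "race"], sort=True):
        idx = rng.integers(0, len(df), size=len(df))
        parts.append(df.iloc[idx])
    return pd.concat(parts, ignore_index=True)


def apply_crosswalk(
    model: CrosswalkModel,
    survey: pd.DataFrame,
    n_sets: int = 10,
    rng_seed: int = 0,
    support: tuple[float, float] = (10.0, 80.0),
) -> list[pd.DataFrame]:
    """Produce ``n_sets`` adjusted survey datasets (default 10).

    Each set applies an independent bootstrap refit of the crosswalk; within
    a set each record's adjusted BMI is its self-report plus the interpolated
    correction, clipped to the BMI support.  Record counts and weights are
    unchanged.
    """
    if n_sets < 1:
        raise DomainError("n_sets must be >= 1")
    rng = np.random.default_rng(rng_seed)
    out = []
    for _ in range(n_sets):
        resample = _stratified_resample(model.calibration, rng)
        boot = fit_crosswalk(resample, model.quantile_grid)
        adjusted = survey.copy()
        adj = np.empty(len(survey), dtype=float)
        for (sex, age, race), idx in survey.groupby(
            ["sex", "age_group", "race"], sort=False
        ).indices.items():
            x = survey["bmi_selfreport"].to_numpy(dtype=float)[idx]
            adj[idx] = x + boot.correction(sex, age, race, x)
        adjusted["bmi_adjusted"] = np.clip(
            adj, support[0] + _BMI_EPS, support[1] - _BMI_EPS
        )
        model.repairs.extend(boot.repairs)
        out.append(adjusted)
    return out
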