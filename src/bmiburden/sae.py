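"""Small-area estimation of obesity prevalence.

Two hierarchical logistic models per (sex, race): one for P(BMI >= 25) and
one for P(BMI >= 30 | BMI >= 25), fit to design-weighted survey proportions
with effective sample sizes.  The linear predictor over (year, county,
age-group) cells combines

  - fixed effects: intercept + three standardized county covariates
    (poverty rate, share born outside the country, log population density),
  - a spatially structured county effect with an intrinsic pairwise-
    difference (ICAR) prior on the county adjacency graph,
  - an independent age-group effect, and
  - a first-order random-walk year effect.

Inference is an empirical-Bayes Laplace approximation, the standard
machinery for latent Gaussian small-area models: for fixed variance
parameters the latent field is maximized by Newton iterations (the binomial
logit likelihood is concave), the variance parameters maximize the
Laplace-approximate marginal posterior, and draws come from the Gaussian
approximation N(zhat, H^{-1}) at the optimum.  Cells with no respondents
are predicted entirely by the smoothing structure.

Poststratification then weights cell estimates by stratum populations,
draw by draw, to produce population-representative aggregates.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit

from .draws import STRATUM_KEYS, DrawMatrix
from .errors import (
    AlignmentError,
    ConvergenceError,
    EstimationError,
    SchemaError,
)

COVARIATE_COLS = ("z_poverty", "z_foreign_born", "z_log_density")


# ----------------------------------------------------------------------
def tabulate(
    survey: pd.DataFrame,
    threshold_low: float = 25.0,
    threshold_high: float = 30.0,
    bmi_col: str = "bmi_adjusted",
    strata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Weighted per-stratum counts and effective sample sizes.

    Returns one row per stratum with weighted totals, weighted counts above
    each threshold, the design-effect effective sample size
    (sum w)^2 / sum w^2 (overall and among records >= threshold_low), and
    the weighted proportions.  If ``strata`` (a frame of stratum keys) is
    given, strata with zero respondents are retained with zero counts and
    flagged via ``n_records == 0`` — never dropped.
    """
    if bmi_col not in survey.columns:
        raise SchemaError(f"survey table lacks BMI column {bmi_col!r}")
    w = survey["weight"].to_numpy(dtype=float)
    if (w < 0).any():
        raise SchemaError("negative survey weight")
    bmi = survey[bmi_col].to_numpy(dtype=float)
    df = survey[STRATUM_KEYS].copy()
    df["w"] = w
    df["w2"] = w * w
    ge_low = bmi >= threshold_low
    df["w25"] = w * ge_low
    df["w30"] = w * (bmi >= threshold_high)
    df["w25_2"] = df["w2"] * ge_low
    g = df.groupby(STRATUM_KEYS, as_index=False).agg(
        n_weighted=("w", "sum"),
        _w2=("w2", "sum"),
        n_ge25_weighted=("w25", "sum"),
        n_ge30_weighted=("w30", "sum"),
        _w25_2=("w25_2", "sum"),
        n_records=("w", "size"),
    )
    if strata is not None:
        g = strata[STRATUM_KEYS].drop_duplicates().merge(
            g, on=STRATUM_KEYS, how="left"
        )
        g = g.fillna(
            {c: 0.0 for c in ["n_weighted", "_w2", "n_ge25_weighted",
                              "n_ge30_weighted", "_w25_2", "n_records"]}
        )
        g["n_records"] = g["n_records"].astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        g["ess"] = np.where(g["_w2"] > 0, g["n_weighted"] ** 2 / g["_w2"], 0.0)
        g["ess_ge25"] = np.where(
            g["_w25_2"] > 0, g["n_ge25_weighted"] ** 2 / g["_w25_2"], 0.0
        )
        g["p25_hat"] = np.where(
            g["n_weighted"] > 0, g["n_ge25_weighted"] / g["n_weighted"], np.nan
        )
        g["p30given25_hat"] = np.where(
            g["n_ge25_weighted"] > 0,
            g["n_ge30_weighted"] / g["n_ge25_weighted"],
            np.nan,
        )
    return g.drop(columns=["_w2", "_w25_2"])


# ----------------------------------------------------------------------
@dataclass
class SaeSpec:
    """Model specification for one outcome."""

    outcome: str  # "p25" or "p30given25"
    n_draws: int = 100
    covariate_cols: tuple = COVARIATE_COLS
    beta_prior_sd: float = 10.0
    hyper_prior_scale: float = 1.0  # half-normal scale on random-effect sds
    max_newton: int = 60
    grad_tol: float = 1e-7

    def __post_init__(self):
        if self.outcome not in ("p25", "p30given25"):
            raise SchemaError(f"unknown outcome {self.outcome!r}")
        if self.n_draws < 1:
            raise SchemaError("n_draws must be >= 1")


@dataclass
class SaeFit:
    """Posterior draws on the modelled (year, county, age group) grid for
    one (sex, race, outcome)."""

    cells: pd.DataFrame
    p_draws: np.ndarray           # (n_cells, n_draws), inverse-logit scale
    beta_names: list
    beta_draws: np.ndarray        # (n_draws, n_beta)
    theta: dict                   # estimated log-sd hyperparameters
    diagnostics: dict


def _path_laplacian(k: int) -> np.ndarray:
    L = np.zeros((k, k))
    for i in range(k - 1):
        L[i, i] += 1.0
        L[i + 1, i + 1] += 1.0
        L[i, i + 1] -= 1.0
        L[i + 1, i] -= 1.0
    return L


def _soft_zero_mean(dim: int, sd: float = 0.01) -> np.ndarray:
    # precision contribution of mean(effect) ~ N(0, sd^2): identifies the
    # level jointly with the intercept (the intrinsic priors are improper)
    return np.full((dim, dim), 1.0 / (sd**2 * dim**2))


class _LaplaceModel:
    """Binomial-logit latent Gaussian model with block priors."""

    def __init__(self, y, n, M, blocks, beta_dim, spec: SaeSpec):
        self.y = y
        self.n = n
        self.M = M
        self.blocks = blocks      # list of (slice, kind, structure matrix)
        self.beta_dim = beta_dim
        self.spec = spec
        self.d = M.shape[1]
        self._zwarm = np.zeros(self.d)

    def prior_precision(self, theta: np.ndarray) -> np.ndarray:
        Q = np.zeros((self.d, self.d))
        bsl = slice(0, self.beta_dim)
        Q[bsl, bsl] = np.eye(self.beta_dim) / self.spec.beta_prior_sd**2
        for (sl, kind, struct), th in zip(self.blocks, theta):
            s2inv = float(np.exp(-2.0 * th))
            dim = sl.stop - sl.start
            if kind in ("icar", "rw1"):
                Q[sl, sl] = s2inv * struct + _soft_zero_mean(dim)
            elif kind == "iid":
                Q[sl, sl] = s2inv * np.eye(dim)
        return Q

    def _nll_parts(self, z):
        eta = self.M @ z
        # y*log p + (n-y)*log(1-p) = y*eta - n*softplus(eta)
        ll = self.y @ eta - self.n @ np.logaddexp(0.0, eta)
        return eta, -ll

    def inner_map(self, theta):
        """Newton maximization of the latent field given hyperparameters."""
        Q = self.prior_precision(theta)
        z = self._zwarm.copy()
        eta, nll = self._nll_parts(z)
        f = nll + 0.5 * z @ Q @ z
        converged = False
        for _ in range(self.spec.max_newton):
            p = expit(eta)
            grad = self.M.T @ (self.n * p - self.y) + Q @ z
            if np.max(np.abs(grad)) < self.spec.grad_tol:
                converged = True
                break
            w = self.n * p * (1.0 - p)
            H = (self.M.T * w) @ self.M + Q
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            # backtracking line search on the penalized deviance
            t = 1.0
            for _ in range(30):
                z_new = z - t * step
                eta_new, nll_new = self._nll_parts(z_new)
                f_new = nll_new + 0.5 * z_new @ Q @ z_new
                if f_new <= f + 1e-12:
                    break
                t *= 0.5
            z, eta, f = z_new, eta_new, f_new
        p = expit(eta)
        w = self.n * p * (1.0 - p)
        H = (self.M.T * w) @ self.M + Q
        grad = self.M.T @ (self.n * p - self.y) + Q @ z
        self._zwarm = z
        return z, f, H, converged, float(np.max(np.abs(grad)))

    def neg_log_marginal(self, theta):
        z, f, H, _, _ = self.inner_map(theta)
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            return 1e10
        # half-normal(hyper_prior_scale) prior on each sd, with log-Jacobian
        sd = np.exp(theta)
        hyper = float(np.sum(0.5 * (sd / self.spec.hyper_prior_scale) ** 2 - theta))
        return f + 0.5 * logdet - 0.5 * self.d * np.log(2.0 * np.pi) + hyper


def fit_sae(
    spec: SaeSpec,
    tabulated: pd.DataFrame,
    graph: nx.Graph,
    covariates: pd.DataFrame,
    rng_seed: int,
) -> SaeFit:
    """Fit one (sex, race, outcome) model and draw from the posterior.

    ``tabulated`` holds the stratum table for a single sex and race (the
    output of :func:`tabulate`, restricted); ``covariates`` maps each county
    to the standardized covariate values for that race.
    """
    if not nx.is_connected(graph):
        raise EstimationError("county graph must be connected for the ICAR prior")
    counties = sorted(graph.nodes())
    years = sorted(tabulated["year"].unique())
    ages = sorted(tabulated["age_group"].unique())
    cells = pd.DataFrame(
        itertools.product(years, counties, ages),
        columns=["year", "county", "age_group"],
    )
    t = cells.merge(tabulated, on=["year", "county", "age_group"], how="left")
    if spec.outcome == "p25":
        n = np.nan_to_num(t["ess"].to_numpy(dtype=float))
        phat = t["p25_hat"].to_numpy(dtype=float)
    else:
        n = np.nan_to_num(t["ess_ge25"].to_numpy(dtype=float))
        phat = t["p30given25_hat"].to_numpy(dtype=float)
    y = np.where(n > 0, np.nan_to_num(phat) * n, 0.0)
    if not (n > 0).any():
        raise EstimationError("no observed cells for this (sex, race, outcome)")

    cov = cells[["county"]].merge(
        covariates[["county", *spec.covariate_cols]], on="county", how="left"
    )
    if cov[list(spec.covariate_cols)].isna().any().any():
        raise SchemaError("covariates missing for some county")
    X = np.column_stack(
        [np.ones(len(cells))] + [cov[c].to_numpy(dtype=float) for c in spec.covariate_cols]
    )
    beta_names = ["intercept", *spec.covariate_cols]
    beta_dim = X.shape[1]

    parts = [X]
    blocks = []
    pos = beta_dim
    county_idx = pd.Categorical(cells["county"], categories=counties).codes
    Zu = np.zeros((len(cells), len(counties)))
    Zu[np.arange(len(cells)), county_idx] = 1.0
    L_county = nx.laplacian_matrix(graph, nodelist=counties).toarray().astype(float)
    parts.append(Zu)
    blocks.append((slice(pos, pos + len(counties)), "icar", L_county))
    pos += len(counties)
    if len(ages) > 1:
        age_idx = pd.Categorical(cells["age_group"], categories=ages).codes
        Za = np.zeros((len(cells), len(ages)))
        Za[np.arange(len(cells)), age_idx] = 1.0
        parts.append(Za)
        blocks.append((slice(pos, pos + len(ages)), "iid", None))
        pos += len(ages)
    if len(years) > 1:
        year_idx = pd.Categorical(cells["year"], categories=years).codes
        Zt = np.zeros((len(cells), len(years)))
        Zt[np.arange(len(cells)), year_idx] = 1.0
        parts.append(Zt)
        blocks.append((slice(pos, pos + len(years)), "rw1", _path_laplacian(len(years))))
        pos += len(years)
    M = np.hstack(parts)

    model = _LaplaceModel(y, n, M, blocks, beta_dim, spec)
    theta0 = np.full(len(blocks), np.log(0.3))
    res = optimize.minimize(
        model.neg_log_marginal,
        theta0,
        method="Nelder-Mead",
        options={"xatol": 1e-3, "fatol": 1e-4, "maxfev": 400},
    )
    zhat, f, H, converged, gnorm = model.inner_map(res.x)
    if not converged or not np.all(np.isfinite(zhat)):
        raise ConvergenceError(
            "SAE latent-field optimization did not converge",
            diagnostics={"grad_norm": gnorm, "theta": res.x.tolist(),
                         "outcome": spec.outcome},
        )
    rng = np.random.default_rng(rng_seed)
    Lc = np.linalg.cholesky(H)
    eps = rng.standard_normal((model.d, spec.n_draws))
    z_draws = zhat[:, None] + np.linalg.solve(Lc.T, eps)
    p_draws = expit(M @ z_draws)
    return SaeFit(
        cells=cells,
        p_draws=p_draws,
        beta_names=beta_names,
        beta_draws=z_draws[:beta_dim].T.copy(),
        theta={f"log_sd_{kind}": float(th) for (_, kind, _), th in zip(blocks, res.x)},
        diagnostics={
            "grad_norm": gnorm,
            "marginal_nll": float(res.fun),
            "nelder_mead_success": bool(res.success),
            "n_observed_cells": int((n > 0).sum()),
        },
    )


# ----------------------------------------------------------------------
def poststratify(cell_draws: DrawMatrix, population: pd.DataFrame) -> DrawMatrix:
    """Attach population weights to modelled cells.

    The modelled cells are already at stratum granularity, so values pass
    through unchanged; this step validates that every cell has a population
    entry and records the weights used by any later draw-by-draw
    aggregation (the poststratification proper).
    """
    from .draws import population_weights

    weights = population_weights(cell_draws.keys, population)
    out = cell_draws.copy_with(cell_draws.values)
    out.population = weights
    return out


def combine_prevalence(p25: DrawMatrix, p30given25: DrawMatrix) -> DrawMatrix:
    """Obesity prevalence draws: P(BMI>=25) x P(BMI>=30 | BMI>=25)."""
    p25.assert_probability()
    p30given25.assert_probability()
    out = p25.multiply(p30given25, name="obesity")
    if hasattr(p25, "population"):
        out.population = p25.population
    return out


def estimate_prevalence(
    adjusted_sets: list[pd.DataFrame],
    population: pd.DataFrame,
    graph: nx.Graph,
    covariates: pd.DataFrame,
    n_draws: int = 100,
    seed: int = 0,
    threshold_low: float = 25.0,
    threshold_high: float = 30.0,
) -> dict:
    """Full prevalence estimation across crosswalk sets.

    Fits one pair of models per (crosswalk set, sex, race) and concatenates
    draws across sets, so the final draw count is n_sets x n_draws.
    Returns draw matrices for P(BMI>=25), P(BMI>=30|>=25) and obesity, plus
    fitted-model metadata.
    """
    strata = population[STRATUM_KEYS].drop_duplicates().reset_index(drop=True)
    sexes = sorted(strata["sex"].unique())
    races = sorted(strata["race"].unique())
    ss = np.random.SeedSequence(seed)
    child = iter(ss.generate_state(len(adjusted_sets) * len(sexes) * len(races) * 2 + 8) % (2**31))

    p25_parts, p30_parts = [], []
    info = {"beta_draws": {}, "diagnostics": [], "draw_info": []}
    for k, adj in enumerate(adjusted_sets):
        tab = tabulate(adj, threshold_low, threshold_high, strata=strata)
        set_p25, set_p30 = [], []
        for sex in sexes:
            for race in races:
                sub = tab[(tab.sex == sex) & (tab.race == race)]
                cov = covariates[covariates.race == race] if "race" in covariates else covariates
                fit25 = fit_sae(
                    SaeSpec("p25", n_draws=n_draws), sub, graph, cov, int(next(child))
                )
                fit30 = fit_sae(
                    SaeSpec("p30given25", n_draws=n_draws), sub, graph, cov,
                    int(next(child)),
                )
                keys = fit25.cells.copy()
                keys["sex"] = sex
                keys["race"] = race
                keys = keys[STRATUM_KEYS]
                set_p25.append(DrawMatrix(keys, fit25.p_draws, "p25"))
                set_p30.append(DrawMatrix(keys.copy(), fit30.p_draws, "p30given25"))
                info["beta_draws"][(k, sex, race, "p25")] = (
                    fit25.beta_names, fit25.beta_draws,
                )
                info["beta_draws"][(k, sex, race, "p30given25")] = (
                    fit30.beta_names, fit30.beta_draws,
                )
                info["diagnostics"].append(
                    {"set": k, "sex": sex, "race": race,
                     "p25": fit25.diagnostics, "p30given25": fit30.diagnostics,
                     "theta_p25": fit25.theta, "theta_p30given25": fit30.theta}
                )
        p25_parts.append(_vstack(set_p25).sort_keys())
        p30_parts.append(_vstack(set_p30).sort_keys())
        info["draw_info"].extend({"set": k, "draw": d} for d in range(n_draws))

    p25_all = p25_parts[0].copy_with(
        np.hstack([p.values for p in p25_parts]), "p25"
    )
    p30_all = p30_parts[0].copy_with(
        np.hstack([p.values for p in p30_parts]), "p30given25"
    )
    p25_all.draw_info = pd.DataFrame(info["draw_info"])
    p25_ps = poststratify(p25_all, population.groupby(STRATUM_KEYS, as_index=False).population.mean())
    p30_all.population = p25_ps.population
    obesity = combine_prevalence(p25_ps, p30_all)
    return {
        "p25": p25_ps,
        "p30given25": p30_all,
        "obesity": obesity,
        "info": info,
    }


def _vstack(parts: list[DrawMatrix]) -> DrawMatrix:
    keys = pd.concat([p.keys for p in parts], ignore_index=True)
    vals = np.vstack([p.values for p in parts])
    return DrawMatrix(keys, vals, parts[0].name, parts[0].units)
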