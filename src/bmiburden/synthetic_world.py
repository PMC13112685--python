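"""Synthetic miniature world with known ground truth.

Generates everything the estimation chain consumes — counties on a
contiguity graph, stratum populations, true continuous BMI distributions,
surveys with self-report bias and non-response, paired calibration records,
cause-specific relative-risk curves, and total YLL rate tables — so that
every downstream stage can be tested against a known truth without any
external data.

Strata are (year, county, age group, sex, race/ethnicity) cells.  Each
stratum's true BMI distribution is a truncated log-normal whose two tail
prevalences P(BMI>=25) and P(BMI>=30) follow logistic models in county
covariates, age, sex, race, year, and a spatially smooth county effect; the
generative coefficients are recorded on the world object so recovery tests
can compare estimates against them.

Self-report bias is a monotone hinge distortion of true BMI,

    b(x) = x - (delta0 + delta1 * max(x - 25, 0)),

with cell-specific deltas: underestimation that grows with true BMI, the
empirically documented direction of self-reported height/weight error.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from .attribution import RiskCurve, Tmrel, make_risk_curve
from .draws import STRATUM_KEYS
from .errors import ConfigError, DomainError, EstimationError
from .exposure import SUPPORT, ExposureDistribution

DEFAULT_RACES = ["AIAN", "Asian", "Black", "Latino", "White"]
DEFAULT_AGE_GROUPS = [("20-44", 20), ("45-64", 45), ("65plus", 65)]
DEFAULT_SEXES = ["female", "male"]

_BMI_EPS = 1e-6


def distort(x, delta0: float, delta1: float):
    """Self-report distortion b(x); monotone increasing when delta1 < 1."""
    x = np.asarray(x, dtype=float)
    out = x - (delta0 + delta1 * np.maximum(x - 25.0, 0.0))
    return out if out.ndim else float(out)


def invert_distortion(s, delta0: float, delta1: float):
    """Analytic inverse of the hinge distortion: true BMI given self-report."""
    s = np.asarray(s, dtype=float)
    below = s + delta0                      # valid when true BMI <= 25
    above = (s + delta0 - 25.0 * delta1) / (1.0 - delta1)
    out = np.where(below <= 25.0, below, above)
    return out if out.ndim else float(out)


@dataclass
class BiasSpec:
    """Hinge self-report bias parameters, varying by sex/age/race.

    ``delta0`` is the baseline underestimation (kg/m^2) and ``delta1`` the
    extra underestimation per unit of true BMI above 25.  The ``*_by_*``
    dictionaries hold additive offsets to delta0 for specific labels.
    """

    delta0: float = 0.4
    delta1: float = 0.08
    delta0_by_sex: dict = field(default_factory=lambda: {"female": 0.25})
    delta0_by_age: dict = field(default_factory=lambda: {"65plus": 0.15})
    delta0_by_race: dict = field(default_factory=dict)
    delta1_by_sex: dict = field(default_factory=dict)

    def deltas(self, sex: str, age_group: str, race: str) -> tuple[float, float]:
        d0 = (
            self.delta0
            + self.delta0_by_sex.get(sex, 0.0)
            + self.delta0_by_age.get(age_group, 0.0)
            + self.delta0_by_race.get(race, 0.0)
        )
        d1 = self.delta1 + self.delta1_by_sex.get(sex, 0.0)
        return d0, d1

    @classmethod
    def zero(cls) -> "BiasSpec":
        return cls(0.0, 0.0, {}, {}, {}, {})


@dataclass
class CauseSpec:
    """One cause of death: relative-risk curve shape plus total YLL scale."""

    name: str
    rr_form: str = "loglinear"
    rr_params: tuple = (np.log(2.0) / 9.0,)
    base_yll_rate: float = 1000.0  # per 100,000, at the reference age
    age_slope: float = 0.7  # log rate increase per decade of age


def default_causes() -> list[CauseSpec]:
    # Loosely patterned on the focal causes: ischemic heart disease (large
    # burden, moderate RR gradient), diabetes (steep RR gradient), and
    # colorectal cancer (small gradient).
    return [
        CauseSpec("ihd", "loglinear", (np.log(2.0) / 9.0,), 2800.0, 0.9),
        CauseSpec("diabetes", "loglinear", (np.log(4.0) / 9.0,), 550.0, 0.6),
        CauseSpec("colorectal_cancer", "loglinear", (np.log(1.4) / 9.0,), 520.0, 0.8),
    ]


@dataclass
class WorldConfig:
    """Parameters of the synthetic world.

    The defaults describe a miniature but structurally faithful analogue of
    the real estimation problem: five mutually exclusive racial/ethnic
    populations, adults 20+, a contiguous county graph, covariate-linked
    obesity, and self-report bias of realistic magnitude.
    """

    n_counties: int = 12
    years: tuple[int, int] = (2000, 2004)
    age_groups: list = field(default_factory=lambda: list(DEFAULT_AGE_GROUPS))
    sexes: list = field(default_factory=lambda: list(DEFAULT_SEXES))
    races: list = field(default_factory=lambda: list(DEFAULT_RACES))
    causes: list = field(default_factory=default_causes)
    seed: int = 0
    survey_size: int = 5000  # expected respondents per year
    bias: BiasSpec = field(default_factory=BiasSpec)
    pop_range: tuple[int, int] = (200, 20000)
    # effects of standardized covariates (poverty, foreign-born, log density)
    beta_p25: tuple = (0.25, -0.15, -0.10)
    beta_obesity: tuple = (0.15, -0.10, -0.05)  # on logit P(BMI>=30 | >=25)
    spatial_sd: float = 0.25
    year_slope: tuple = (0.06, 0.04)  # logit drift per year for p25, p30|25
    nonresponse_strength: float = 0.5
    calibration_noise_sd: float = 1.0
    n_extra_edges: int = 2
    support: tuple = SUPPORT
    tmrel: tuple = (20.0, 21.0)

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    @property
    def age_labels(self) -> list[str]:
        return [a[0] for a in self.age_groups]

    def validate(self):
        if self.n_counties < 2:
            raise ConfigError("n_counties", "need at least 2 counties")
        if self.years[1] < self.years[0]:
            raise ConfigError("years", "empty year range")
        bounds = [a[1] for a in self.age_groups]
        if not self.age_groups:
            raise ConfigError("age_groups", "must be non-empty")
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ConfigError("age_groups", "age bounds must be strictly increasing")
        if bounds[0] != 20:
            raise ConfigError("age_groups", "analysis covers adults: lowest bound is 20")
        if not 1 <= len(self.sexes) <= 2:
            raise ConfigError("sexes", "need 1 or 2 sex labels")
        if not self.races:
            raise ConfigError("races", "must be non-empty")
        if not self.causes:
            raise ConfigError("causes", "must be non-empty")
        if self.survey_size < 1:
            raise ConfigError("survey_size", "must be >= 1")
        if not (0 < self.pop_range[0] <= self.pop_range[1]):
            raise ConfigError("pop_range", "need 0 < min <= max")
        d1_max = self.bias.delta1 + max([0.0, *self.bias.delta1_by_sex.values()])
        if d1_max >= 1.0:
            raise ConfigError("bias", "delta1 must be < 1 for a monotone distortion")
        if self.calibration_noise_sd < 0:
            raise ConfigError("calibration_noise_sd", "must be >= 0")


@dataclass
class World:
    """A fully specified synthetic world (see module docstring)."""

    config: WorldConfig
    counties: list
    graph: nx.Graph
    covariates: pd.DataFrame  # county x race covariates + standardized columns
    population: pd.DataFrame  # per stratum
    exposure: pd.DataFrame    # per stratum: mu, sigma, true_p25, true_p30
    ylls: pd.DataFrame        # per stratum x cause: yll_rate per 100,000
    risk_curves: dict
    propensity: pd.DataFrame  # per stratum: relative response propensity
    effects: dict             # generative coefficients, for recovery tests
    total_population: int

    def distribution_for(self, row) -> ExposureDistribution:
        return ExposureDistribution(
            float(row["mu"]), float(row["sigma"]), self.config.support
        )

    def write(self, outdir):
        """Write the world as the documented set of delimited text files."""
        import os

        os.makedirs(outdir, exist_ok=True)
        self.population[STRATUM_KEYS + ["population"]].to_csv(
            f"{outdir}/population.csv", index=False
        )
        edges = pd.DataFrame(
            sorted((min(a, b), max(a, b)) for a, b in self.graph.edges()),
            columns=["county_a", "county_b"],
        )
        edges.to_csv(f"{outdir}/adjacency.csv", index=False)
        self.covariates.to_csv(f"{outdir}/covariates.csv", index=False)
        self.ylls[STRATUM_KEYS + ["cause", "yll_rate"]].to_csv(
            f"{outdir}/ylls.csv", index=False
        )
        curves = pd.DataFrame(
            [
                {
                    "cause": c.name,
                    "form": c.rr_form,
                    "param1": c.rr_params[0],
                    "param2": c.rr_params[1] if len(c.rr_params) > 1 else "",
                    "tmrel_lower": self.config.tmrel[0],
                    "tmrel_upper": self.config.tmrel[1],
                }
                for c in self.config.causes
            ]
        )
        curves.to_csv(f"{outdir}/risk_curves.csv", index=False)
        self.exposure[
            STRATUM_KEYS + ["mu", "sigma", "true_p25", "true_p30"]
        ].to_csv(f"{outdir}/truth.csv", index=False)


# ----------------------------------------------------------------------
def _lattice_graph(n_counties: int, n_extra_edges: int, rng) -> tuple[list, nx.Graph]:
    """Connected 2-D lattice over county ids, with optional extra edges."""
    cols = int(np.ceil(np.sqrt(n_counties)))
    ids = [f"c{i:03d}" for i in range(n_counties)]
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i in range(n_counties):
        r, c = divmod(i, cols)
        for (r2, c2) in ((r + 1, c), (r, c + 1)):
            j = r2 * cols + c2
            if c2 < cols and j < n_counties:
                g.add_edge(ids[i], ids[j])
    added = 0
    attempts = 0
    while added < n_extra_edges and attempts < 50 * max(1, n_extra_edges):
        a, b = rng.choice(n_counties, size=2, replace=False)
        attempts += 1
        if not g.has_edge(ids[a], ids[b]):
            g.add_edge(ids[a], ids[b])
            added += 1
    assert nx.is_connected(g)
    return ids, g


def _spatial_noise(rng, graph: nx.Graph, counties: list, sd: float) -> dict:
    """Spatially smooth county effects: neighbourhood-averaged white noise,
    rescaled to the requested standard deviation."""
    raw = {c: rng.normal() for c in counties}
    sm = np.array(
        [
            (raw[c] + sum(raw[n] for n in graph.neighbors(c)))
            / (1 + graph.degree(c))
            for c in counties
        ]
    )
    if sd == 0 or sm.std() == 0:
        return {c: 0.0 for c in counties}
    sm = (sm - sm.mean()) / sm.std() * sd
    return dict(zip(counties, sm))


def _race_offsets(races, preset, rng, scale):
    out = {}
    for r in races:
        if r in preset:
            out[r] = preset[r]
        else:
            out[r] = float(rng.normal(0.0, scale))
    return out


def _truncated_tail(mu, sigma, threshold, support):
    zlo = (np.log(support[0]) - mu) / sigma
    zhi = (np.log(support[1]) - mu) / sigma
    zt = (np.log(threshold) - mu) / sigma
    return (norm.cdf(zhi) - norm.cdf(zt)) / (norm.cdf(zhi) - norm.cdf(zlo))


def build_world(config: WorldConfig) -> World:
    """Deterministically generate a world from the config (pure in seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    counties, graph = _lattice_graph(config.n_counties, config.n_extra_edges, rng)

    # --- county x race covariates -------------------------------------
    race_pov = _race_offsets(
        config.races,
        {"AIAN": 0.5, "Asian": -0.3, "Black": 0.6, "Latino": 0.4, "White": 0.0},
        rng, 0.3,
    )
    race_fb = _race_offsets(
        config.races,
        {"AIAN": -1.0, "Asian": 2.2, "Black": 0.0, "Latino": 1.8, "White": -0.5},
        rng, 0.5,
    )
    density = np.exp(rng.normal(4.0, 1.2, size=len(counties)))  # persons/km^2
    rows = []
    for ci, county in enumerate(counties):
        county_pov = rng.normal(0.0, 0.4)
        county_fb = rng.normal(0.0, 0.5)
        for race in config.races:
            pov = expit(logit(0.12) + race_pov[race] + county_pov + rng.normal(0, 0.2))
            fb = expit(logit(0.05) + race_fb[race] + county_fb + rng.normal(0, 0.3))
            rows.append(
                {
                    "county": county,
                    "race": race,
                    "poverty_rate": pov,
                    "pct_foreign_born": fb,
                    "population_density": density[ci],
                }
            )
    cov = pd.DataFrame(rows)
    cov["z_poverty"] = (cov.poverty_rate - cov.poverty_rate.mean()) / cov.poverty_rate.std()
    cov["z_foreign_born"] = (
        cov.pct_foreign_born - cov.pct_foreign_born.mean()
    ) / cov.pct_foreign_born.std()
    logd = np.log(cov.population_density)
    cov["z_log_density"] = (logd - logd.mean()) / logd.std()

    # --- stratum grid --------------------------------------------------
    grid = pd.DataFrame(
        itertools.product(
            config.year_list, counties, config.age_labels, config.sexes, config.races
        ),
        columns=STRATUM_KEYS,
    )
    grid = grid.merge(
        cov[["county", "race", "z_poverty", "z_foreign_born", "z_log_density"]],
        on=["county", "race"],
        how="left",
    )

    # --- true tail-prevalence model ------------------------------------
    # offsets sized so the default world mirrors the observed US pattern of
    # adult obesity by race/ethnicity (highest in the Black and AIAN
    # populations, lowest in the Asian population, roughly 49/48/45/39/21%)
    race_off25 = _race_offsets(
        config.races,
        {"AIAN": 0.36, "Asian": -1.05, "Black": 0.36, "Latino": 0.42, "White": 0.0},
        rng, 0.4,
    )
    race_off30 = _race_offsets(
        config.races,
        {"AIAN": 0.25, "Asian": -0.33, "Black": 0.37, "Latino": 0.11, "White": 0.0},
        rng, 0.3,
    )
    age_mid = {
        lab: (lo + (config.age_groups[i + 1][1] if i + 1 < len(config.age_groups) else lo + 20))
        / 2.0
        for i, (lab, lo) in enumerate(config.age_groups)
    }
    u25 = _spatial_noise(rng, graph, counties, config.spatial_sd)
    u30 = _spatial_noise(rng, graph, counties, config.spatial_sd)
    sex_ref = config.sexes[0]

    z = grid[["z_poverty", "z_foreign_born", "z_log_density"]].to_numpy()
    year0 = config.years[0]
    eta25 = (
        0.85
        + grid.race.map(race_off25).to_numpy()
        + np.where(grid.sex == sex_ref, -0.10, 0.10)
        + grid.age_group.map(lambda a: 0.12 * (age_mid[a] - 45.0) / 10.0).to_numpy()
        + (grid.year - year0).to_numpy() * config.year_slope[0]
        + z @ np.asarray(config.beta_p25, dtype=float)
        + grid.county.map(u25).to_numpy()
    )
    eta30 = (
        0.20
        + grid.race.map(race_off30).to_numpy()
        + np.where(grid.sex == sex_ref, 0.15, -0.15)
        + grid.age_group.map(lambda a: 0.08 * (age_mid[a] - 45.0) / 10.0).to_numpy()
        + (grid.year - year0).to_numpy() * config.year_slope[1]
        + z @ np.asarray(config.beta_obesity, dtype=float)
        + grid.county.map(u30).to_numpy()
    )
    p25 = np.clip(expit(eta25), 0.05, 0.97)
    p30g25 = np.clip(expit(eta30), 0.05, 0.90)
    p30 = p25 * p30g25

    # log-normal parameters exactly identified by the untruncated tails ...
    z1 = norm.isf(p25)
    z2 = norm.isf(p30)
    sigma = (np.log(30.0) - np.log(25.0)) / (z2 - z1)
    mu = np.log(25.0) - sigma * z1
    # ... and ground truth recorded from the truncated distribution.
    true_p25 = _truncated_tail(mu, sigma, 25.0, config.support)
    true_p30 = _truncated_tail(mu, sigma, 30.0, config.support)

    exposure = grid[STRATUM_KEYS].copy()
    exposure["mu"] = mu
    exposure["sigma"] = sigma
    exposure["true_p25"] = true_p25
    exposure["true_p30"] = true_p30

    # --- populations ----------------------------------------------------
    n_strata_per_year = len(counties) * len(config.age_labels) * len(config.sexes) * len(
        config.races
    )
    base_pop = rng.integers(
        config.pop_range[0], config.pop_range[1] + 1, size=n_strata_per_year
    )
    population = grid[STRATUM_KEYS].copy()
    year_index = population.year.to_numpy() - year0
    jitter = np.exp(
        rng.normal(0.0, 0.02, size=len(population))
    )
    population["population"] = np.maximum(
        1, np.rint(np.tile(base_pop, len(config.year_list)) * jitter)
    ).astype(int)
    del year_index

    # --- response propensity (unknown to the analyst) -------------------
    zp = (true_p30 - true_p30.mean()) / max(true_p30.std(), 1e-12)
    propensity = grid[STRATUM_KEYS].copy()
    propensity["propensity"] = np.exp(-config.nonresponse_strength * zp)

    # --- cause-specific total YLL rates ---------------------------------
    yll_rows = []
    for cause in config.causes:
        race_mult = _race_offsets(
            config.races,
            {"AIAN": 0.35, "Asian": -0.85, "Black": 0.40, "Latino": -0.15, "White": 0.0},
            rng, 0.3,
        )
        age_term = grid.age_group.map(
            lambda a: cause.age_slope * (age_mid[a] - 45.0) / 10.0
        ).to_numpy()
        noise = rng.normal(0.0, 0.15, size=len(grid))
        rate = cause.base_yll_rate * np.exp(
            age_term
            + grid.race.map(race_mult).to_numpy()
            + np.where(grid.sex == sex_ref, -0.15, 0.15)
            - 0.01 * (grid.year - year0).to_numpy()
            + noise
        )
        f = grid[STRATUM_KEYS].copy()
        f["cause"] = cause.name
        f["yll_rate"] = rate
        yll_rows.append(f)
    ylls = pd.concat(yll_rows, ignore_index=True)

    tmrel = Tmrel(*config.tmrel)
    curves = {
        c.name: make_risk_curve(c.name, c.rr_form, c.rr_params, tmrel)
        for c in config.causes
    }

    effects = {
        "beta_p25": tuple(config.beta_p25),
        "beta_obesity": tuple(config.beta_obesity),
        "race_off_p25": race_off25,
        "race_off_p30g25": race_off30,
        "spatial_sd": config.spatial_sd,
        "year_slope": tuple(config.year_slope),
    }
    return World(
        config=config,
        counties=counties,
        graph=graph,
        covariates=cov,
        population=population,
        exposure=exposure,
        ylls=ylls,
        risk_curves=curves,
        propensity=propensity,
        effects=effects,
        total_population=int(population.population.sum()),
    )


# ----------------------------------------------------------------------
def _sample_truncated_lognormal(rng, mu, sigma, support, size):
    zlo = norm.cdf((np.log(support[0]) - mu) / sigma)
    zhi = norm.cdf((np.log(support[1]) - mu) / sigma)
    u = rng.uniform(size=size)
    return np.exp(mu + sigma * norm.ppf(zlo + u * (zhi - zlo)))


def generate_survey(world: World, year: int, rng_seed: int) -> pd.DataFrame:
    """One year of survey microdata with self-report bias and non-response.

    Respondent counts are multinomial over strata with probability
    proportional to (design inclusion) x (response propensity).  The design
    allocates equal expected sample to each county, proportional to
    population within county; the reported ``weight`` is the inverse of that
    *design* inclusion probability.  The response propensity is not
    reflected in the weights — it is the non-response bias the downstream
    poststratification must correct.

    The returned frame carries a ``bmi_true`` column for testing; it is not
    part of the survey schema written to disk.
    """
    config = world.config
    if year not in config.year_list:
        raise DomainError(f"year {year} outside the world's range {config.years}")
    rng = np.random.default_rng(rng_seed)
    strata = (
        world.population[world.population.year == year]
        .merge(world.propensity, on=STRATUM_KEYS)
        .merge(world.exposure, on=STRATUM_KEYS)
        .reset_index(drop=True)
    )
    county_pop = strata.groupby("county").population.transform("sum").to_numpy()
    n_c = len(world.counties)
    design_share = strata.population.to_numpy() / (n_c * county_pop)
    pi = design_share * strata.propensity.to_numpy()
    pi = pi / pi.sum()
    counts = rng.multinomial(config.survey_size, pi)

    frames = []
    for i, cnt in enumerate(counts):
        if cnt == 0:
            continue
        row = strata.iloc[i]
        x = _sample_truncated_lognormal(
            rng, row.mu, row.sigma, config.support, cnt
        )
        d0, d1 = config.bias.deltas(row.sex, row.age_group, row.race)
        s = np.clip(
            distort(x, d0, d1),
            config.support[0] + _BMI_EPS,
            config.support[1] - _BMI_EPS,
        )
        f = pd.DataFrame(
            {
                "year": year,
                "county": row.county,
                "age_group": row.age_group,
                "sex": row.sex,
                "race": row.race,
                "bmi_selfreport": s,
                "weight": n_c * county_pop[i] / config.survey_size,
                "bmi_true": x,
            }
        )
        frames.append(f)
    if not frames:
        return pd.DataFrame(
            columns=STRATUM_KEYS + ["bmi_selfreport", "weight", "bmi_true"]
        )
    return pd.concat(frames, ignore_index=True)


def generate_calibration(world: World, n: int, rng_seed: int) -> pd.DataFrame:
    """Paired (self-reported, measured) BMI records, stratified over
    age x sex x race cells, emulating an examination survey."""
    config = world.config
    cells = list(
        itertools.product(config.age_labels, config.sexes, config.races)
    )
    if n < len(cells):
        raise DomainError(
            f"need n >= {len(cells)} so every (age, sex, race) cell has a record"
        )
    rng = np.random.default_rng(rng_seed)
    base, extra = divmod(n, len(cells))
    frames = []
    for k, (age, sex, race) in enumerate(cells):
        m = base + (1 if k < extra else 0)
        if m == 0:
            continue
        strata = (
            world.population.merge(world.exposure, on=STRATUM_KEYS)
            .query("age_group == @age and sex == @sex and race == @race")
            .reset_index(drop=True)
        )
        pw = strata.population.to_numpy(dtype=float)
        idx = rng.choice(len(strata), size=m, p=pw / pw.sum())
        mu = strata.mu.to_numpy()[idx]
        sigma = strata.sigma.to_numpy()[idx]
        measured = _sample_truncated_lognormal(rng, mu, sigma, config.support, m)
        d0, d1 = config.bias.deltas(sex, age, race)
        noise = (
            rng.normal(0.0, config.calibration_noise_sd, size=m)
            if config.calibration_noise_sd > 0
            else np.zeros(m)
        )
        selfrep = np.clip(
            distort(measured, d0, d1) + noise,
            config.support[0] + _BMI_EPS,
            config.support[1] - _BMI_EPS,
        )
        frames.append(
            pd.DataFrame(
                {
                    "age_group": age,
                    "sex": sex,
                    "race": race,
                    "bmi_selfreport": selfrep,
                    "bmi_measured": measured,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
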