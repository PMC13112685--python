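"""Pipeline orchestration, file schemas, validation, and provenance.

Stages operate on a working directory holding the documented delimited
text files (population.csv, survey.csv, calibration.csv, adjacency.csv,
covariates.csv, ylls.csv, risk_curves.csv, ...).  ``run_pipeline`` chains
them end to end — simulate, crosswalk, prevalence models, distribution
fitting, attribution, summaries — and writes a manifest recording the
configuration hash, per-stage seeds, and row counts, so a rerun with the
same configuration is byte-identical.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import crosswalk as cw
from . import sae as sae_mod
from . import summarize as sm
from .attribution import Tmrel, attributable_ylls, compute_paf, make_risk_curve
from .draws import STRATUM_KEYS, DrawMatrix, population_weights
from .errors import ConfigError, SchemaError
from .exposure import ExposureDistribution, fit_distribution
from .synthetic_world import (
    BiasSpec,
    CauseSpec,
    World,
    WorldConfig,
    build_world,
    generate_calibration,
    generate_survey,
)

SURVEY_COLS = STRATUM_KEYS + ["bmi_selfreport", "weight"]


@dataclass
class PipelineConfig:
    """End-to-end run configuration; defaults are the study's constants
    (10 crosswalk sets x 100 draws, TMREL 20-21 kg/m^2, thresholds 25/30,
    masking below 1000)."""

    world: WorldConfig = field(default_factory=WorldConfig)
    n_sets: int = 10
    n_draws: int = 100
    seed: int = 0
    calibration_n: int = 2000
    thresholds: tuple = (25.0, 30.0)
    tmrel: tuple = (20.0, 21.0)
    mask_threshold: float = 1000.0
    quantile_grid: tuple = cw.DEFAULT_QUANTILE_GRID

    def validate(self):
        self.world.validate()
        if self.n_sets < 1:
            raise ConfigError("n_sets", "must be >= 1")
        if self.n_draws < 1:
            raise ConfigError("n_draws", "must be >= 1")
        if not self.thresholds[0] < self.thresholds[1]:
            raise ConfigError("thresholds", "low threshold must be below high")

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["world"]["causes"] = [dataclasses.asdict(c) for c in self.world.causes]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        w = dict(d.pop("world", {}))
        if "bias" in w and isinstance(w["bias"], dict):
            w["bias"] = BiasSpec(**w["bias"])
        if "causes" in w:
            w["causes"] = [
                CauseSpec(**c) if isinstance(c, dict) else c for c in w["causes"]
            ]
        for key in ("years", "pop_range", "beta_p25", "beta_obesity",
                    "year_slope", "support", "tmrel"):
            if key in w and isinstance(w[key], list):
                w[key] = tuple(w[key])
        if "age_groups" in w:
            w["age_groups"] = [tuple(a) for a in w["age_groups"]]
        world = WorldConfig(**w)
        for key in ("thresholds", "tmrel", "quantile_grid"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(world=world, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        def default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, (np.ndarray, tuple)):
                return list(o)
            raise TypeError(type(o))

        blob = json.dumps(self.to_dict(), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()


def stage_seeds(seed: int) -> dict:
    state = np.random.SeedSequence(seed).generate_state(4) % (2**31)
    return {
        "survey": int(state[0]),
        "calibration": int(state[1]),
        "crosswalk": int(state[2]),
        "sae": int(state[3]),
    }


# ----------------------------------------------------------------------
# stages
# ----------------------------------------------------------------------
def simulate_stage(config: PipelineConfig, outdir) -> World:
    """Build the synthetic world and write all its input tables."""
    os.makedirs(outdir, exist_ok=True)
    seeds = stage_seeds(config.seed)
    world = build_world(config.world)
    world.write(outdir)
    surveys = [
        generate_survey(world, year, seeds["survey"] + i)
        for i, year in enumerate(config.world.year_list)
    ]
    survey = pd.concat(surveys, ignore_index=True)
    survey[SURVEY_COLS].to_csv(f"{outdir}/survey.csv", index=False)
    calib = generate_calibration(world, config.calibration_n, seeds["calibration"])
    calib.to_csv(f"{outdir}/calibration.csv", index=False)
    return world


def crosswalk_stage(config: PipelineConfig, workdir) -> list[pd.DataFrame]:
    """Fit the crosswalk on calibration.csv and write the adjusted sets."""
    seeds = stage_seeds(config.seed)
    calibration = pd.read_csv(f"{workdir}/calibration.csv")
    survey = pd.read_csv(f"{workdir}/survey.csv")
    model = cw.fit_crosswalk(calibration, config.quantile_grid)
    sets = cw.apply_crosswalk(
        model, survey, n_sets=config.n_sets, rng_seed=seeds["crosswalk"],
        support=config.world.support,
    )
    for k, adj in enumerate(sets, start=1):
        adj[SURVEY_COLS + ["bmi_adjusted"]].to_csv(
            f"{workdir}/survey_adjusted_{k}.csv", index=False
        )
    model.to_json(f"{workdir}/crosswalk_model.json", seed=seeds["crosswalk"])
    return sets


def _read_graph(workdir) -> nx.Graph:
    edges = pd.read_csv(f"{workdir}/adjacency.csv")
    counties = pd.read_csv(f"{workdir}/population.csv").county.unique()
    g = nx.Graph()
    g.add_nodes_from(counties)
    g.add_edges_from(edges.itertuples(index=False, name=None))
    return g


def sae_stage(config: PipelineConfig, workdir, adjusted_sets=None) -> dict:
    """Fit the prevalence models and write prevalence_draws.csv."""
    seeds = stage_seeds(config.seed)
    if adjusted_sets is None:
        adjusted_sets = [
            pd.read_csv(f"{workdir}/survey_adjusted_{k}.csv")
            for k in range(1, config.n_sets + 1)
        ]
    population = pd.read_csv(f"{workdir}/population.csv")
    covariates = pd.read_csv(f"{workdir}/covariates.csv")
    graph = _read_graph(workdir)
    result = sae_mod.estimate_prevalence(
        adjusted_sets, population, graph, covariates,
        n_draws=config.n_draws, seed=seeds["sae"],
        threshold_low=config.thresholds[0], threshold_high=config.thresholds[1],
    )
    long = result["p25"].to_long("p25")
    long["obesity"] = result["obesity"].to_long("v")["v"]
    long.to_csv(f"{workdir}/prevalence_draws.csv", index=False)
    diag = {
        "n_sets": config.n_sets,
        "n_draws_per_model": config.n_draws,
        "fits": result["info"]["diagnostics"],
    }
    with open(f"{workdir}/sae_diagnostics.json", "w") as fh:
        json.dump(diag, fh, indent=2, default=float)
    return result


def distfit_stage(config: PipelineConfig, workdir) -> pd.DataFrame:
    """Fit one continuous BMI distribution per stratum and draw."""
    prev = pd.read_csv(f"{workdir}/prevalence_draws.csv")
    mus, sigmas, a25, a30 = [], [], [], []
    for p25, p30 in zip(prev["p25"].to_numpy(), prev["obesity"].to_numpy()):
        # rare extreme draws can imply tail pairs outside the truncated
        # family's reach; those are projected just inside the boundary and
        # remain visible via achieved_p30 != the draw's obesity value
        d = fit_distribution(
            float(p25), float(p30), support=config.world.support,
            project_infeasible=True,
        )
        mus.append(d.mu)
        sigmas.append(d.sigma)
        a25.append(d.achieved_p25)
        a30.append(d.achieved_p30)
    out = prev[STRATUM_KEYS + ["draw"]].copy()
    out["family"] = "lognormal"
    out["param1"] = mus
    out["param2"] = sigmas
    out["achieved_p25"] = a25
    out["achieved_p30"] = a30
    out.to_csv(f"{workdir}/exposure_params.csv", index=False)
    return out


def _read_risk_curves(workdir, tmrel: Tmrel):
    curves = {}
    for row in pd.read_csv(f"{workdir}/risk_curves.csv").itertuples():
        params = (float(row.param1),)
        if str(row.param2) not in ("", "nan"):
            params = params + (float(row.param2),)
        curves[row.cause] = make_risk_curve(row.cause, row.form, params, tmrel)
    return curves


def attribute_stage(config: PipelineConfig, workdir) -> pd.DataFrame:
    """Compute PAFs and attributable YLLs per stratum, cause, and draw."""
    params = pd.read_csv(f"{workdir}/exposure_params.csv")
    ylls = pd.read_csv(f"{workdir}/ylls.csv")
    population = pd.read_csv(f"{workdir}/population.csv")
    tmrel = Tmrel(*config.tmrel)
    curves = _read_risk_curves(workdir, tmrel)

    dists = [
        ExposureDistribution(m, s, config.world.support)
        for m, s in zip(params["param1"].to_numpy(), params["param2"].to_numpy())
    ]
    frames = []
    for cause, curve in curves.items():
        f = params[STRATUM_KEYS + ["draw"]].copy()
        f["cause"] = cause
        f["paf"] = [compute_paf(d, curve) for d in dists]
        frames.append(f)
    paf_long = pd.concat(frames, ignore_index=True)
    paf_dm = DrawMatrix.from_long(
        paf_long, STRATUM_KEYS + ["cause"], "paf", name="paf"
    )
    result = attributable_ylls(paf_dm, ylls, population)
    out = result.paf.to_long("paf")
    out["attr_rate"] = result.rate.to_long("v")["v"]
    out["attr_count"] = result.count.to_long("v")["v"]
    out.to_csv(f"{workdir}/attributable_draws.csv", index=False)
    return out


def _summarize(dm: DrawMatrix) -> pd.DataFrame:
    # smoke-mode runs with a single draw get degenerate (zero-width)
    # intervals; proper interval estimation requires >= 2 draws
    if dm.n_draws == 1:
        out = dm.keys.copy()
        out["mean"] = dm.values[:, 0]
        out["lower"] = dm.values[:, 0]
        out["upper"] = dm.values[:, 0]
        return out
    return sm.summarize_draws(dm)


def summarize_stage(config: PipelineConfig, workdir) -> dict:
    """Aggregate, age-standardize, summarize, test disparities, and mask."""
    population = pd.read_csv(f"{workdir}/population.csv")
    prev = pd.read_csv(f"{workdir}/prevalence_draws.csv")
    attr = pd.read_csv(f"{workdir}/attributable_draws.csv")
    obesity = DrawMatrix.from_long(prev, STRATUM_KEYS, "obesity", name="obesity")
    rate = DrawMatrix.from_long(
        attr, STRATUM_KEYS + ["cause"], "attr_rate", name="attr_rate"
    )
    standard = sm.AgeStandard.from_population(population, year=population.year.min())
    pop_w = population_weights(obesity.keys, population)

    rows = []

    def add_rows(summary: pd.DataFrame, quantity: str, scale: float = 1.0):
        for r in summary.itertuples(index=False):
            d = r._asdict()
            keys = {k: d[k] for k in d if k not in ("mean", "lower", "upper")}
            rows.append(
                {
                    "level": ",".join(f"{k}={v}" for k, v in keys.items()) or "national",
                    "quantity": quantity,
                    "mean": d["mean"] * scale,
                    "lower": d["lower"] * scale,
                    "upper": d["upper"] * scale,
                }
            )

    # national and by-race age-standardized obesity prevalence (%)
    by_age_race = obesity.aggregate(pop_w, over=["county", "sex"], name="obesity")
    natl_by_age = obesity.aggregate(pop_w, over=["county", "sex", "race"])
    add_rows(
        _summarize(sm.age_standardize(natl_by_age, standard)),
        "obesity_prevalence_pct", 100.0,
    )
    race_std = sm.age_standardize(by_age_race, standard)
    add_rows(_summarize(race_std), "obesity_prevalence_pct", 100.0)

    pop_w_cause = population_weights(rate.keys[STRATUM_KEYS], population)
    natl_rate = rate.aggregate(pop_w_cause, over=["county", "sex", "race"])
    add_rows(
        _summarize(sm.age_standardize(natl_rate, standard)),
        "attributable_yll_rate_per_100k",
    )
    race_rate_std = sm.age_standardize(
        rate.aggregate(pop_w_cause, over=["county", "sex"]), standard
    )
    add_rows(_summarize(race_rate_std), "attributable_yll_rate_per_100k")

    estimates = pd.DataFrame(rows)

    # stratum-level obesity with small-population masking
    stratum = _summarize(obesity)
    stratum = sm.mask_small(
        stratum, population, config.mask_threshold, key_cols=["county", "race"]
    )
    stratum.loc[stratum.masked, ["mean", "lower", "upper"]] = np.nan
    estimates.to_csv(f"{workdir}/estimates.csv", index=False)
    stratum.to_csv(f"{workdir}/stratum_estimates.csv", index=False)

    # disparities: highest- vs lowest-prevalence race in the final year
    disp_rows = []
    last = race_std.keys.year.max()
    sel = race_std.keys.year == last
    final = DrawMatrix(race_std.keys[sel], race_std.values[sel.to_numpy()])
    means = final.values.mean(axis=1)
    hi, lo = int(np.argmax(means)), int(np.argmin(means))
    if hi != lo:
        num = DrawMatrix(pd.DataFrame({"k": ["ratio"]}), final.values[[hi]])
        den = DrawMatrix(pd.DataFrame({"k": ["ratio"]}), final.values[[lo]])
        ratio = sm.ratio_of_rates(num, den)
        diff = num.copy_with(num.values - den.values)
        sig = (
            bool(sm.significance(diff)[0]) if diff.n_draws >= 40 else None
        )
        disp_rows.append(
            {
                "quantity": "obesity_prevalence",
                "year": int(last),
                "numerator": final.keys.race.iloc[hi],
                "denominator": final.keys.race.iloc[lo],
                "ratio_mean": ratio["mean"].iloc[0],
                "ratio_lower": ratio["lower"].iloc[0],
                "ratio_upper": ratio["upper"].iloc[0],
                "significant": sig,
            }
        )
        sel_r = (race_rate_std.keys.year == last).to_numpy()
        fr = DrawMatrix(race_rate_std.keys[sel_r], race_rate_std.values[sel_r])
        for cause in fr.keys.cause.unique():
            c = fr.keys.cause == cause
            ck = fr.keys[c.to_numpy()]
            cv = fr.values[c.to_numpy()]
            i_hi = ck.race.tolist().index(final.keys.race.iloc[hi])
            i_lo = ck.race.tolist().index(final.keys.race.iloc[lo])
            numc = DrawMatrix(pd.DataFrame({"k": ["r"]}), cv[[i_hi]])
            denc = DrawMatrix(pd.DataFrame({"k": ["r"]}), cv[[i_lo]])
            rc = sm.ratio_of_rates(numc, denc)
            diffc = numc.copy_with(numc.values - denc.values)
            disp_rows.append(
                {
                    "quantity": f"attributable_yll_rate:{cause}",
                    "year": int(last),
                    "numerator": final.keys.race.iloc[hi],
                    "denominator": final.keys.race.iloc[lo],
                    "ratio_mean": rc["mean"].iloc[0],
                    "ratio_lower": rc["lower"].iloc[0],
                    "ratio_upper": rc["upper"].iloc[0],
                    "significant": bool(sm.significance(diffc)[0])
                    if diffc.n_draws >= 40 else None,
                }
            )
    disparities = pd.DataFrame(disp_rows)
    disparities.to_csv(f"{workdir}/disparities.csv", index=False)
    return {
        "estimates": estimates,
        "stratum_estimates": stratum,
        "disparities": disparities,
    }


# ----------------------------------------------------------------------
def _file_entry(path) -> dict:
    with open(path, "rb") as fh:
        data = fh.read()
    return {
        "sha256": hashlib.sha256(data).hexdigest(),
        "rows": max(0, data.count(b"\n") - 1),
    }


@dataclass
class PipelineResult:
    outdir: str
    manifest: dict
    estimates: pd.DataFrame
    stratum_estimates: pd.DataFrame
    disparities: pd.DataFrame
    world: World


def run_pipeline(config: PipelineConfig, outdir) -> PipelineResult:
    """Execute the full chain and write a provenance manifest."""
    config.validate()
    os.makedirs(outdir, exist_ok=True)
    world = simulate_stage(config, outdir)
    sets = crosswalk_stage(config, outdir)
    sae_stage(config, outdir, adjusted_sets=sets)
    distfit_stage(config, outdir)
    attribute_stage(config, outdir)
    summaries = summarize_stage(config, outdir)
    manifest = {
        "config_hash": config.config_hash(),
        "config": json.loads(
            json.dumps(config.to_dict(), default=lambda o: list(o)
                       if isinstance(o, (tuple, np.ndarray)) else float(o))
        ),
        "stage_seeds": stage_seeds(config.seed),
        "world_seed": config.world.seed,
        "draws_total": config.n_sets * config.n_draws,
        "files": {
            name: _file_entry(os.path.join(outdir, name))
            for name in sorted(os.listdir(outdir))
            if name.endswith((".csv", ".json")) and name != "manifest.json"
        },
    }
    with open(f"{outdir}/manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return PipelineResult(
        outdir=str(outdir),
        manifest=manifest,
        estimates=summaries["estimates"],
        stratum_estimates=summaries["stratum_estimates"],
        disparities=summaries["disparities"],
        world=world,
    )


# ----------------------------------------------------------------------
@dataclass
class ValidationReport:
    violations: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, file, row, column, message):
        self.violations.append(
            {"file": file, "row": row, "column": column, "message": message}
        )


def validate_inputs(workdir, strict: bool = False) -> ValidationReport:
    """Schema, range, and referential-integrity checks on the input tables.

    Violations are report content; with ``strict`` the first report with
    any violation raises SchemaError.
    """
    report = ValidationReport()
    req = {
        "population.csv": STRATUM_KEYS + ["population"],
        "survey.csv": SURVEY_COLS,
        "calibration.csv": ["age_group", "sex", "race", "bmi_selfreport",
                            "bmi_measured"],
        "adjacency.csv": ["county_a", "county_b"],
        "covariates.csv": ["county", "race", "poverty_rate", "pct_foreign_born",
                           "population_density"],
        "ylls.csv": STRATUM_KEYS + ["cause", "yll_rate"],
    }
    tables = {}
    for name, cols in req.items():
        path = os.path.join(workdir, name)
        if not os.path.exists(path):
            report.add(name, None, None, "file missing")
            continue
        df = pd.read_csv(path)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            report.add(name, None, ",".join(missing), "missing columns")
            continue
        tables[name] = df

    def check_range(name, col, ok_mask):
        df = tables[name]
        for idx in df.index[~ok_mask]:
            report.add(name, int(idx), col, f"value {df.loc[idx, col]!r} out of range")

    if "population.csv" in tables:
        pop = tables["population.csv"]
        check_range("population.csv", "population", pop.population >= 0)
        if pop.duplicated(STRATUM_KEYS).any():
            report.add("population.csv", None, None, "duplicate stratum keys")
    if "survey.csv" in tables:
        survey = tables["survey.csv"]
        check_range(
            "survey.csv", "bmi_selfreport",
            (survey.bmi_selfreport > 10) & (survey.bmi_selfreport < 80),
        )
        check_range("survey.csv", "weight", survey.weight > 0)
        if "population.csv" in tables:
            merged = survey[STRATUM_KEYS].merge(
                tables["population.csv"][STRATUM_KEYS].drop_duplicates(),
                on=STRATUM_KEYS, how="left", indicator=True,
            )
            for idx in merged.index[merged._merge == "left_only"]:
                report.add(
                    "survey.csv", int(idx), None,
                    "stratum not present in population table",
                )
    if "calibration.csv" in tables:
        cal = tables["calibration.csv"]
        for col in ("bmi_selfreport", "bmi_measured"):
            check_range("calibration.csv", col, (cal[col] > 10) & (cal[col] < 80))
    if "adjacency.csv" in tables and "population.csv" in tables:
        adj = tables["adjacency.csv"]
        known = set(tables["population.csv"].county.unique())
        for idx, row in adj.iterrows():
            if row.county_a == row.county_b:
                report.add("adjacency.csv", int(idx), None, "self-loop edge")
            for col in ("county_a", "county_b"):
                if row[col] not in known:
                    report.add(
                        "adjacency.csv", int(idx), col,
                        f"unknown county {row[col]!r}",
                    )
    if "covariates.csv" in tables:
        cov = tables["covariates.csv"]
        check_range(
            "covariates.csv", "poverty_rate",
            (cov.poverty_rate >= 0) & (cov.poverty_rate <= 1),
        )
        check_range(
            "covariates.csv", "pct_foreign_born",
            (cov.pct_foreign_born >= 0) & (cov.pct_foreign_born <= 1),
        )
        check_range(
            "covariates.csv", "population_density", cov.population_density >= 0
        )
    if "ylls.csv" in tables:
        check_range("ylls.csv", "yll_rate", tables["ylls.csv"].yll_rate >= 0)

    if strict and not report.ok:
        raise SchemaError(f"input validation failed: {report.violations[:5]} ...")
    return report
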