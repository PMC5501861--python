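"""Configuration, file schemas and the staged pipeline.

Interchange is long/tidy CSV throughout (landscape, the three survey
tables, rivers as WKT linestrings) plus JSON for truths and manifests and a
CSV posterior summary (parameter, mean, q2.5, q97.5, rhat). Every run
writes a manifest echoing the effective configuration, the seed and the
package version, so no setting is applied silently.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely import wkt as shapely_wkt

from . import __version__
from .evaluation import evaluate_fit
from .drivers import driver_table, abundance_by_stratum, decline_rate
from .inference import (ChainSet, MCMCConfig, PriorSpec, forest_indicator_array,
                        run_mcmc, summarize_posterior, PARAM_NAMES)
from .landscape import (GridLandscape, build_neighbor_graph,
                        connected_forest_patches, standardize_covariates)
from .observation import SurveyData, survey_from_frames, survey_to_frames
from .synthetic import SyntheticScenario, generate_dataset, truths_json

STAGES = ("simulate", "fit", "evaluate", "drivers")

#: mid-years of the three default survey periods (1997-2002 ... 2009-2015)
DEFAULT_MID_YEARS = (1999.5, 2005.5, 2012.0)


class PipelineError(RuntimeError):
    """A stage was requested without its prerequisites."""


@dataclass
class RunConfig:
    """Pipeline settings; YAML file fields override these defaults."""

    outdir: str = "apedyn_run"
    seed: int = 0
    stages: tuple = STAGES
    scenario: dict = field(default_factory=dict)
    chains: int = 3
    iterations: int = 2000
    burn_in: int = 1000
    latent_thin: int = 50
    landscape_csv: str | None = None
    rivers_csv: str | None = None
    counts_csv: str | None = None
    occurrence_csv: str | None = None
    interviews_csv: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def manifest(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["stages"] = list(d["stages"])
        d["version"] = __version__
        d["config_hash"] = hashlib.sha256(
            yaml.safe_dump({k: str(v) for k, v in sorted(d.items())}).encode()
        ).hexdigest()[:16]
        return d


def write_rivers(rivers, path: Path) -> None:
    pd.DataFrame({"wkt": [g.wkt for g in rivers]}).to_csv(path, index=False)


def read_rivers(path: str | Path) -> list:
    df = pd.read_csv(path)
    if "wkt" not in df.columns:
        raise ValueError("rivers CSV must have a 'wkt' column")
    return [shapely_wkt.loads(s) for s in df["wkt"]]


def load_inputs(config: RunConfig):
    """Load (GridLandscape, SurveyData, rivers) from the configured CSVs."""
    if config.landscape_csv is None:
        raise PipelineError("no landscape_csv configured and no simulate stage ran")
    land = GridLandscape.from_frame(pd.read_csv(config.landscape_csv))
    frames = {}
    for key, path in (("counts", config.counts_csv),
                      ("occurrence", config.occurrence_csv),
                      ("interviews", config.interviews_csv)):
        if path is None:
            raise PipelineError(f"no {key}_csv configured")
        frames[key] = pd.read_csv(path)
    survey = survey_from_frames(frames)
    rivers = read_rivers(config.rivers_csv) if config.rivers_csv else []
    return land, survey, rivers


def run_pipeline(config: RunConfig) -> Path:
    """Execute the requested stages in order simulate -> fit -> evaluate ->
    drivers, writing one artifact set per stage under the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "manifest.json").write_text(
        json.dumps(config.manifest(), indent=2, default=str))

    land = survey = rivers = None
    chains: ChainSet | None = None

    if "simulate" in config.stages:
        scenario = SyntheticScenario(**config.scenario)
        ds = generate_dataset(scenario, config.seed)
        land, survey, rivers = ds.landscape, ds.survey, ds.rivers
        land.to_frame().to_csv(outdir / "landscape.csv", index=False)
        for name, df in survey_to_frames(survey).items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        write_rivers(rivers, outdir / "rivers.csv")
        (outdir / "truths.json").write_text(truths_json(ds))

    def ensure_data():
        nonlocal land, survey, rivers
        if land is None:
            land, survey, rivers = load_inputs(config)
        return land, survey, rivers

    if "fit" in config.stages:
        land, survey, rivers = ensure_data()
        z = standardize_covariates(land)
        graph = build_neighbor_graph(land, rivers)
        ind = forest_indicator_array(land)
        mcfg = MCMCConfig(n_chains=config.chains, n_iter=config.iterations,
                          n_burn=config.burn_in, seed=config.seed,
                          latent_thin=config.latent_thin)
        chains = run_mcmc(survey, z, graph, PriorSpec(), mcfg, ind)
        summary = summarize_posterior(chains)
        summary.table.reset_index().to_csv(outdir / "posterior_summary.csv",
                                           index=False)
        np.savez_compressed(outdir / "draws.npz", draws=chains.draws,
                            Nou_draws=chains.Nou_draws, O_mean=chains.O_mean,
                            latent_rows=chains.latent_rows)

    if "evaluate" in config.stages:
        if chains is None:
            raise PipelineError("evaluate requires a prior fit stage in this run")
        land, survey, rivers = ensure_data()
        ind = forest_indicator_array(land)
        report = evaluate_fit(chains, survey, land, ind)
        (outdir / "fit_report.json").write_text(
            json.dumps(report.to_dict(), indent=2))

    if "drivers" in config.stages:
        if chains is None:
            raise PipelineError("drivers requires a prior fit stage in this run")
        land, survey, rivers = ensure_data()
        z = standardize_covariates(land)
        summary = summarize_posterior(chains)
        eta_hat = {n: float(summary.table.loc[n, "mean"])
                   for n in PARAM_NAMES if n.startswith("eta")}
        nou_mean = chains.Nou_draws.mean(axis=(0, 1))       # (C, T)
        occupied = chains.O_mean > 0.5
        patches = [connected_forest_patches(land, t)
                   for t in range(land.nperiod)]
        table = driver_table(land, eta_hat, z, occupied, patches)
        table.to_csv(outdir / "driver_scores.csv", index=False)
        strata = pd.concat([abundance_by_stratum(nou_mean[:, t], land, t)
                            for t in range(land.nperiod)], ignore_index=True)
        strata.to_csv(outdir / "abundance_by_stratum.csv", index=False)
        totals = nou_mean.sum(axis=0)
        trend = {
            "totals_by_period": totals.tolist(),
            "decline_10yr_percent": decline_rate(
                totals, DEFAULT_MID_YEARS[:land.nperiod]),
        }
        (outdir / "trend.json").write_text(json.dumps(trend, indent=2))

    return outdir
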