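"""End-to-end pipeline: simulate (or read) -> kinematics -> quantification ->
paternity -> classical comparisons -> Bayesian fit -> report.

``PipelineConfig`` is the single schema-validated configuration object
(unknown keys are rejected); ``run_all`` orchestrates every stage into an
output directory and returns the report dictionary it also writes as JSON.
The report is free of timestamps and machine detail, so a fixed seed yields
a byte-identical report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__, classical, gamete, kinematics
from .glmm import MCMCConfig, build_design, fit, summarize_fit
from .paternity import tally_trials
from .synthetic import SCHEMA_VERSION, TruthConfig, write_dataset

logger = logging.getLogger(__name__)

__all__ = ["KinematicsSettings", "MCMCSettings", "PipelineConfig", "run_all"]


class KinematicsSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    fps: float = Field(60.0, gt=0)
    vap_window: int = Field(kinematics.DEFAULT_VAP_WINDOW, ge=1)
    min_track_points: int = Field(kinematics.DEFAULT_MIN_POINTS, ge=2)

    @model_validator(mode="after")
    def _odd_window(self) -> "KinematicsSettings":
        if self.vap_window % 2 == 0:
            raise ValueError("vap_window must be odd")
        return self


class MCMCSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    chains: int = Field(4, ge=2)
    iters: int = Field(20_000, ge=2)
    burnin: int = Field(10_000, ge=0)
    thin: int = Field(5, ge=1)
    prior_scale: float = Field(2.5, gt=0)
    prior_df: float = Field(1.0, gt=0)

    @model_validator(mode="after")
    def _check(self) -> "MCMCSettings":
        if self.burnin >= self.iters:
            raise ValueError("burnin must be < iters")
        if (self.iters - self.burnin) // self.thin < 10:
            raise ValueError("fewer than 10 draws would be retained")
        return self

    def to_mcmc_config(self, seed: int) -> MCMCConfig:
        from .glmm.model import PriorSpec

        return MCMCConfig(
            n_chains=self.chains,
            n_iter=self.iters,
            burnin=self.burnin,
            thin=self.thin,
            seed=seed,
            prior=PriorSpec(fixed_scale=self.prior_scale, fixed_df=self.prior_df),
        )


class PipelineConfig(BaseModel):
    """Full pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    out_dir: str = "pipeline_out"
    data_dir: Optional[str] = None  # read an existing dataset instead of simulating
    seed: int = 0
    truth: TruthConfig = TruthConfig()
    kinematics: KinematicsSettings = KinematicsSettings()
    mcmc: MCMCSettings = MCMCSettings()
    n_subsamples: int = Field(3, ge=1)
    n_tracks: int = Field(116, ge=1)
    track_duration_s: float = Field(3.0, gt=0)
    gsi_lf: float = gamete.GSI_LF
    gsi_lp: float = gamete.GSI_LP


def _male_traits(
    data_dir: Path, males: pd.DataFrame, settings: KinematicsSettings
) -> pd.DataFrame:
    """Measure every male's VCL/VAP from the trajectory CSVs."""
    rows = []
    for _, male in males.iterrows():
        paths = sorted((data_dir / "trajectories").glob(f"{male.male_id}_*.csv"))
        if not paths:
            raise FileNotFoundError(f"no trajectory files for male {male.male_id}")
        subs = []
        for path in paths:
            trajs = kinematics.read_trajectories(path, fps=settings.fps)
            subs.append(
                kinematics.summarize_subsample(
                    trajs, window=settings.vap_window, min_points=settings.min_track_points
                )
            )
        traits = kinematics.summarize_male(
            subs, male.male_id, male.ecotype, male.concentration
        )
        rows.append(
            {
                "male_id": traits.male_id,
                "ecotype": traits.ecotype,
                "vcl_mean": traits.vcl_mean,
                "vap_mean": traits.vap_mean,
                "concentration": traits.concentration,
                "body_mass_g": male.body_mass_g,
                "gsi": male.gsi,
                "total_sperm": gamete.total_sperm(
                    male.body_mass_g, male.gsi, male.concentration
                ),
            }
        )
    return pd.DataFrame(rows)


def _trait_report(traits: pd.DataFrame) -> dict:
    """Ecotype mean +/- SE of the measured traits, plus the trait tests."""
    grp = {}
    for eco, g in traits.groupby("ecotype"):
        grp[eco] = {
            col: {
                "mean": float(g[col].mean()),
                "se": float(g[col].std(ddof=1) / np.sqrt(len(g))),
            }
            for col in ("vcl_mean", "vap_mean", "concentration", "total_sperm")
        }
    lf = traits[traits.ecotype == "LF"]
    lp = traits[traits.ecotype == "LP"]
    tests = {
        "concentration_mann_whitney": classical.mann_whitney(
            lf.concentration, lp.concentration
        ).__dict__,
        "total_sperm_mann_whitney": classical.mann_whitney(
            lf.total_sperm, lp.total_sperm
        ).__dict__,
        "vap_t_test": classical.t_test(lf.vap_mean, lp.vap_mean).__dict__,
        "vcl_t_test": classical.t_test(lf.vcl_mean, lp.vcl_mean).__dict__,
    }
    return {"by_ecotype": grp, "tests": tests}


def _cell_means(tallies: pd.DataFrame) -> dict:
    """Observed LP-sired share per female-ecotype x experiment cell."""
    out = {}
    for (eco, exp), g in tallies.groupby(["female_ecotype", "experiment"]):
        share = g.c_lp / g.n
        out[f"{eco}_{exp}"] = {
            "lp_share_mean": float(share.mean()),
            "lp_share_se": float(share.std(ddof=1) / np.sqrt(len(g))),
            "n_trials": int(len(g)),
        }
    return out


def run_all(config: PipelineConfig) -> dict:
    """Run every stage and write tables plus report.json under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.data_dir is None:
        data_dir = out / "synthetic"
        logger.info("simulating dataset (seed=%d) -> %s", config.seed, data_dir)
        truth = config.truth.model_copy(update={"seed": config.seed})
        write_dataset(
            truth,
            data_dir,
            n_subsamples=config.n_subsamples,
            n_tracks=config.n_tracks,
            fps=config.kinematics.fps,
            duration=config.track_duration_s,
        )
    else:
        data_dir = Path(config.data_dir)

    males = pd.read_csv(data_dir / "males.csv")
    females = pd.read_csv(data_dir / "females.csv")
    trials = pd.read_csv(data_dir / "trials.csv")
    genotypes = pd.read_csv(data_dir / "genotypes.csv")

    logger.info("kinematics: measuring %d males", len(males))
    traits = _male_traits(data_dir, males, config.kinematics)
    traits.to_csv(out / "traits.csv", index=False)

    logger.info("paternity: tallying %d trials", len(trials))
    mothers = dict(zip(females.female_id, females.genotype))
    tallies = tally_trials(genotypes, trials, mothers)
    tallies.to_csv(out / "tallies.csv", index=False)

    # per-pair measured speeds: the i-th LF male is paired with the i-th LP male
    pair_speed_rows = []
    pair_ids = sorted(trials.pair_id.unique())
    lf_ids = sorted(males[males.ecotype == "LF"].male_id)
    lp_ids = sorted(males[males.ecotype == "LP"].male_id)
    traits_idx = traits.set_index("male_id")
    for i, pid in enumerate(pair_ids):
        pair_speed_rows.append(
            {
                "pair_id": pid,
                "vap_lf": float(traits_idx.loc[lf_ids[i], "vap_mean"]),
                "vap_lp": float(traits_idx.loc[lp_ids[i], "vap_mean"]),
            }
        )
    pair_speeds = pd.DataFrame(pair_speed_rows)

    data = build_design(tallies, pair_speeds)
    logger.info(
        "bayes: fitting %d trials, %d chains x %d iters",
        data.n_trials,
        config.mcmc.chains,
        config.mcmc.iters,
    )
    samples = fit(data, config.mcmc.to_mcmc_config(config.seed))
    for chain in range(samples.draws.shape[0]):
        pd.DataFrame(samples.draws[chain], columns=samples.names).to_csv(
            out / f"chain_{chain + 1}.csv", index=False
        )
    summary = summarize_fit(samples, data, seed=config.seed)

    report = {
        "package_version": __version__,
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "traits": _trait_report(traits),
        "paternity_cells": _cell_means(tallies),
        "n_trials_analyzed": int(len(tallies)),
        "n_larvae_genotyped": int(tallies.n.sum()),
        "model": summary,
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    logger.info("report written to %s", out / "report.json")
    return report
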