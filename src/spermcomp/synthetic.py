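"""Synthetic-data generator for the paired-male sperm-competition pipeline.

Generates every input the analysis consumes — male sperm profiles, tracked
head trajectories, competitive-fertilization trials and larval genotypes —
from a known truth, so each downstream stage can be tested against the
generating parameters.

The default truth emulates the study system this package models:

* 13 males per ecotype; brook lamprey (LP) semen roughly twice as
  concentrated as river lamprey (LF) semen, with LF sperm faster (higher VAP
  and VCL). Concentrations are lognormal across males (positive support,
  right skew typical of count-derived quantities); speeds are Gaussian with
  a shared per-male motility deviation so VAP never exceeds VCL.
* Trajectories are correlated random walks at 60 frames/s for 3 s: constant
  step length VCL/fps, Gaussian turning increments whose SD is calibrated in
  closed form so the moving-average-smoothed path speed matches the male's
  true VAP at the analysis smoothing window.
* Competition trials cross 13 male pairs with females of both ecotypes under
  both mixing designs; the LP-sired count is Binomial(N, p) with logit(p)
  given by the hierarchical model (fixed effects on female ecotype,
  experiment type and scaled sperm speeds; Gaussian female-identity and
  male-pair random intercepts). By default one pair's equal-number trials
  fail (N = 0, exercising the exclusion rule) and one trial has only 22
  surviving larvae instead of 27, so the default design totals 1345
  genotyped larvae.
* Larval genotypes at the diagnostic locus follow Mendel: an LF (ff) mother's
  offspring are ff (LF sire) or pf (LP sire); an LP (pp) mother's are pf or
  pp.

All randomness flows from ``TruthConfig.seed``; fixed seed reproduces every
table byte-identically.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator
from scipy.special import expit

from . import gamete
from .kinematics import DEFAULT_VAP_WINDOW

__all__ = [
    "TruthConfig",
    "simulate_males",
    "make_females",
    "simulate_trajectories",
    "turning_sd_for_vap",
    "simulate_competition",
    "write_dataset",
]

SCHEMA_VERSION = 1


class TruthConfig(BaseModel):
    """Generating truth for the synthetic study; defaults are the study design."""

    model_config = ConfigDict(extra="forbid")

    n_males_per_ecotype: int = Field(13, ge=1)
    # lognormal medians (sperm/mL); LP ~ 2x LF, magnitudes chosen so GSI-based
    # total sperm lands near the reported ecotype means
    conc_mean_LF: float = Field(3.8e8, gt=0)
    conc_mean_LP: float = Field(7.6e8, gt=0)
    conc_cv: float = Field(0.45, ge=0)
    # speeds in um/s; LF faster, VCL means from the reported group means
    vcl_mean_LF: float = Field(353.2, gt=0)
    vcl_mean_LP: float = Field(321.6, gt=0)
    vap_mean_LF: float = Field(262.0, gt=0)
    vap_mean_LP: float = Field(221.0, gt=0)
    speed_sd: float = Field(45.0, gt=0)
    # body mass (g) and GSI used for total-sperm estimates
    mass_mean_LF: float = Field(50.0, gt=0)
    mass_mean_LP: float = Field(8.5, gt=0)
    mass_cv: float = Field(0.15, ge=0)
    gsi_LF: float = gamete.GSI_LF
    gsi_LP: float = gamete.GSI_LP
    # logit-scale truth of the siring model (a0..a6)
    alpha: Tuple[float, float, float, float, float, float, float] = (
        0.26,
        -0.04,
        -0.70,
        -0.18,
        0.13,
        0.21,
        -0.83,
    )
    sd_female: float = Field(0.3, ge=0)
    sd_pair: float = Field(0.3, ge=0)
    larvae_per_trial: int = Field(27, ge=1)
    n_females_LF: int = Field(3, ge=1)
    n_females_LP: int = Field(6, ge=1)
    # one pair's equal-number fertilization fails (N=0) and one trial loses
    # larvae before genotyping, mirroring the study design
    include_failed_pair: bool = True
    short_trial_larvae: Optional[int] = 22
    seed: int = 0

    @model_validator(mode="after")
    def _check_speed_order(self) -> "TruthConfig":
        if self.vcl_mean_LF < self.vap_mean_LF or self.vcl_mean_LP < self.vap_mean_LP:
            raise ValueError("VCL means must be >= VAP means")
        return self


def simulate_males(cfg: TruthConfig) -> pd.DataFrame:
    """Per-male true profiles: ecotype, concentration, body mass, VCL/VAP.

    Concentrations are lognormal around the ecotype median with coefficient
    of variation ``conc_cv``; a single per-male motility deviation shifts VCL
    and (proportionally) VAP so the VAP <= VCL ordering is preserved.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    rows = []
    for ecotype, conc_med, vcl_m, vap_m, mass_m, gsi in (
        ("LF", cfg.conc_mean_LF, cfg.vcl_mean_LF, cfg.vap_mean_LF, cfg.mass_mean_LF, cfg.gsi_LF),
        ("LP", cfg.conc_mean_LP, cfg.vcl_mean_LP, cfg.vap_mean_LP, cfg.mass_mean_LP, cfg.gsi_LP),
    ):
        sigma = np.sqrt(np.log1p(cfg.conc_cv**2))
        for i in range(cfg.n_males_per_ecotype):
            conc = conc_med * np.exp(sigma * rng.standard_normal()) if sigma else conc_med
            z = rng.standard_normal()
            vcl_true = max(vcl_m + cfg.speed_sd * z, 1.0)
            vap_true = max(vap_m + cfg.speed_sd * z * (vap_m / vcl_m), 0.5)
            vap_true = min(vap_true, vcl_true)
            mass_sigma = np.sqrt(np.log1p(cfg.mass_cv**2))
            mass = mass_m * np.exp(mass_sigma * rng.standard_normal()) if mass_sigma else mass_m
            rows.append(
                {
                    "male_id": f"{ecotype}{i + 1:02d}",
                    "ecotype": ecotype,
                    "concentration": conc,
                    "body_mass_g": mass,
                    "gsi": gsi,
                    "vcl_true": vcl_true,
                    "vap_true": vap_true,
                }
            )
    return pd.DataFrame(rows)


def make_females(cfg: TruthConfig) -> pd.DataFrame:
    """Females used for in vitro fertilization: ecotype and diagnostic genotype."""
    rows = [
        {"female_id": f"F_LF{i + 1:02d}", "ecotype": "LF", "genotype": "ff"}
        for i in range(cfg.n_females_LF)
    ] + [
        {"female_id": f"F_LP{i + 1:02d}", "ecotype": "LP", "genotype": "pp"}
        for i in range(cfg.n_females_LP)
    ]
    return pd.DataFrame(rows)


def turning_sd_for_vap(
    vcl_true: float, vap_true: float, window: int = DEFAULT_VAP_WINDOW
) -> float:
    """Turning-angle SD (radians/step) giving a target VAP/VCL ratio.

    For a correlated random walk with constant step length and Gaussian
    heading increments of SD sigma, successive steps decorrelate as
    rho^|lag| with rho = exp(-sigma^2 / 2). The w-point moving-average path
    then travels at an expected fraction

        f(rho) = sqrt( sum_{j,k<w} rho^|j-k| ) / w

    of VCL, which is solved for rho by bisection; sigma follows. Ratios at or
    above 1 give straight tracks (sigma = 0); ratios below f(0) = 1/sqrt(w)
    are unreachable at this window and are clamped.
    """
    ratio = vap_true / vcl_true
    if ratio >= 1.0:
        return 0.0
    w = window

    def f(rho: float) -> float:
        total = float(w)
        for d in range(1, w):
            total += 2.0 * (w - d) * rho**d
        return np.sqrt(total) / w

    if ratio <= f(0.0):
        ratio = f(0.0) + 1e-9
    lo, hi = 0.0, 1.0
    for _ in range(200):
        mid = (lo + hi) / 2
        if f(mid) < ratio:
            lo = mid
        else:
            hi = mid
    rho = (lo + hi) / 2
    rho = min(max(rho, 1e-12), 1 - 1e-12)
    return float(np.sqrt(-2.0 * np.log(rho)))


def simulate_trajectories(
    male: pd.Series,
    n_tracks: int,
    fps: float = 60.0,
    duration: float = 3.0,
    window: int = DEFAULT_VAP_WINDOW,
    rng: Optional[np.random.Generator] = None,
    field_um: float = 600.0,
) -> pd.DataFrame:
    """Correlated-random-walk tracks for one male's subsample.

    Returns a tidy frame (track, frame, x_um, y_um) of ``n_tracks`` tracks of
    floor(fps * duration) points each. Step length is VCL/fps exactly, so the
    measured VCL is unbiased; the turning-angle SD comes from
    :func:`turning_sd_for_vap` so the measured VAP at the analysis smoothing
    window recovers the male's true VAP.
    """
    if not (fps > 0 and duration > 0):
        raise ValueError("fps and duration must be > 0")
    if n_tracks < 1:
        raise ValueError("n_tracks must be >= 1")
    rng = rng or np.random.default_rng(0)
    n_points = int(np.floor(fps * duration))
    if n_points < 2:
        raise ValueError("fps * duration must give at least 2 points")
    step = float(male["vcl_true"]) / fps
    sigma = turning_sd_for_vap(float(male["vcl_true"]), float(male["vap_true"]), window)
    frames = np.arange(n_points)
    out = []
    for t in range(n_tracks):
        heading = rng.uniform(0, 2 * np.pi)
        turns = sigma * rng.standard_normal(n_points - 1) if sigma else np.zeros(n_points - 1)
        headings = heading + np.concatenate(([0.0], np.cumsum(turns)))[: n_points - 1]
        # headings per step: first step uses initial heading
        dx = step * np.cos(headings)
        dy = step * np.sin(headings)
        x0, y0 = rng.uniform(0, field_um, size=2)
        x = x0 + np.concatenate(([0.0], np.cumsum(dx)))
        y = y0 + np.concatenate(([0.0], np.cumsum(dy)))
        out.append(
            pd.DataFrame(
                {"track": f"t{t + 1:03d}", "frame": frames, "x_um": x, "y_um": y}
            )
        )
    return pd.concat(out, ignore_index=True)


def _pair_table(males: pd.DataFrame) -> pd.DataFrame:
    """Pair the i-th LF male with the i-th LP male."""
    lf = males[males.ecotype == "LF"].reset_index(drop=True)
    lp = males[males.ecotype == "LP"].reset_index(drop=True)
    if len(lf) == 0 or len(lp) == 0 or len(lf) != len(lp):
        raise ValueError("males must contain equally many LF and LP individuals")
    return pd.DataFrame(
        {
            "pair_id": [f"P{i + 1:02d}" for i in range(len(lf))],
            "male_lf": lf.male_id.to_numpy(),
            "male_lp": lp.male_id.to_numpy(),
            "conc_lf": lf.concentration.to_numpy(),
            "conc_lp": lp.concentration.to_numpy(),
            "vap_lf_true": lf.vap_true.to_numpy(),
            "vap_lp_true": lp.vap_true.to_numpy(),
        }
    )


def _scale(v: np.ndarray) -> np.ndarray:
    if v.size < 2:
        return np.zeros_like(v)
    sd = v.std(ddof=1)
    return np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd


def simulate_competition(
    males: pd.DataFrame, females: pd.DataFrame, cfg: TruthConfig
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Competitive-fertilization trials and per-larva genotypes under the truth.

    Every male pair is crossed under both mixing designs with one female of
    each ecotype (females cycle when fewer females than pairs exist, as in
    the study). The LP-sired count is Binomial(N, p) with logit(p) from the
    hierarchical model evaluated at the truth: ``cfg.alpha``, the pair's true
    VAPs scaled across pairs, and Gaussian female/pair random intercepts.

    Returns (trials, genotypes); trials carries the generator's bookkeeping
    column ``c_lp_true`` for round-trip testing.
    """
    if not set(females.genotype) <= {"ff", "pp"}:
        raise ValueError("female genotypes must be homozygous (ff or pp)")
    pairs = _pair_table(males)
    rng = np.random.default_rng([cfg.seed, 2])
    alpha = np.asarray(cfg.alpha, dtype=float)
    b_female = {
        f: cfg.sd_female * rng.standard_normal() for f in females.female_id
    }
    b_pair = {p: cfg.sd_pair * rng.standard_normal() for p in pairs.pair_id}
    vs_lp = _scale(pairs.vap_lp_true.to_numpy())
    vs_lf = _scale(pairs.vap_lf_true.to_numpy())

    fem_by_eco = {
        eco: females[females.ecotype == eco].reset_index(drop=True)
        for eco in ("LF", "LP")
    }
    failed_pair = pairs.pair_id.iloc[-1] if cfg.include_failed_pair and len(pairs) > 1 else None

    trial_rows = []
    geno_rows = []
    short_used = False
    trial_no = 0
    for i, pair in pairs.iterrows():
        for experiment in ("equal_volume", "equal_number"):
            if experiment == "equal_volume":
                v_lf = v_lp = 3.0
            else:
                mix = gamete.equal_number_volumes(pair.conc_lf, pair.conc_lp)
                v_lf, v_lp = mix.v_lf_ul, mix.v_lp_ul
            for eco in ("LF", "LP"):
                fems = fem_by_eco[eco]
                female = fems.iloc[i % len(fems)]
                trial_no += 1
                trial_id = f"T{trial_no:03d}"
                failed = experiment == "equal_number" and pair.pair_id == failed_pair
                if failed:
                    n_larvae = 0
                elif (
                    cfg.short_trial_larvae is not None
                    and not short_used
                    and experiment == "equal_number"
                ):
                    n_larvae = min(cfg.short_trial_larvae, cfg.larvae_per_trial)
                    short_used = True
                else:
                    n_larvae = cfg.larvae_per_trial
                eta = (
                    alpha[0]
                    + alpha[1] * (eco == "LP")
                    + alpha[2] * (experiment == "equal_number")
                    + alpha[3] * vs_lp[i]
                    + alpha[4] * vs_lf[i]
                    + alpha[5] * (experiment == "equal_number") * vs_lp[i]
                    + alpha[6] * (experiment == "equal_number") * vs_lf[i]
                    + b_female[female.female_id]
                    + b_pair[pair.pair_id]
                )
                p = float(expit(eta))
                c = int(rng.binomial(n_larvae, p)) if n_larvae else 0
                trial_rows.append(
                    {
                        "trial_id": trial_id,
                        "pair_id": pair.pair_id,
                        "female_id": female.female_id,
                        "female_ecotype": eco,
                        "experiment": experiment,
                        "v_lf_ul": v_lf,
                        "v_lp_ul": v_lp,
                        "n_larvae": n_larvae,
                        "c_lp_true": c,
                        "p_true": p,
                    }
                )
                sires = np.array(["LF"] * (n_larvae - c) + ["LP"] * c)
                rng.shuffle(sires)
                for j, sire in enumerate(sires):
                    if female.genotype == "ff":
                        g = "pf" if sire == "LP" else "ff"
                    else:
                        g = "pp" if sire == "LP" else "pf"
                    geno_rows.append(
                        {
                            "trial_id": trial_id,
                            "larva_id": f"{trial_id}_L{j + 1:02d}",
                            "genotype": g,
                        }
                    )
    trials = pd.DataFrame(trial_rows)
    genotypes = pd.DataFrame(geno_rows, columns=["trial_id", "larva_id", "genotype"])
    return trials, genotypes


def write_dataset(
    cfg: TruthConfig,
    out_dir: str | Path,
    n_subsamples: int = 3,
    n_tracks: int = 116,
    fps: float = 60.0,
    duration: float = 3.0,
) -> dict:
    """Generate and write the full synthetic dataset to ``out_dir``.

    Writes males.csv, females.csv, trajectories/<male>_<sub>.csv, trials.csv,
    genotypes.csv and truth.json; returns a manifest of the paths written.
    """
    out = Path(out_dir)
    (out / "trajectories").mkdir(parents=True, exist_ok=True)
    males = simulate_males(cfg)
    females = make_females(cfg)
    trials, genotypes = simulate_competition(males, females, cfg)
    males.to_csv(out / "males.csv", index=False)
    females.to_csv(out / "females.csv", index=False)
    trials.to_csv(out / "trials.csv", index=False)
    genotypes.to_csv(out / "genotypes.csv", index=False)
    traj_rng = np.random.default_rng([cfg.seed, 3])
    traj_paths: List[str] = []
    for _, male in males.iterrows():
        for s in range(1, n_subsamples + 1):
            df = simulate_trajectories(
                male, n_tracks=n_tracks, fps=fps, duration=duration, rng=traj_rng
            )
            path = out / "trajectories" / f"{male.male_id}_{s}.csv"
            df.to_csv(path, index=False)
            traj_paths.append(str(path))
    truth = {
        "schema_version": SCHEMA_VERSION,
        "config": json.loads(cfg.model_dump_json()),
        "fps": fps,
        "duration": duration,
        "n_subsamples": n_subsamples,
        "n_tracks": n_tracks,
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return {
        "males": str(out / "males.csv"),
        "females": str(out / "females.csv"),
        "trials": str(out / "trials.csv"),
        "genotypes": str(out / "genotypes.csv"),
        "truth": str(out / "truth.json"),
        "trajectories": traj_paths,
    }
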