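"""Model definition: design matrix, priors, and the joint log posterior.

The observation model for competitive trial i is

    C_i ~ Binomial(N_i, p_i)
    logit(p_i) = a0 + a1*female_lp_i + a2*equal_number_i
               + a3*vsLP_i + a4*vsLF_i
               + a5*equal_number_i*vsLP_i + a6*equal_number_i*vsLF_i
               + b_female[i] + b_pair[i]

where C_i is the number of genotyped larvae sired by the LP (brook lamprey)
male out of N_i, female_lp and equal_number are 0/1 dummies (reference level:
LF female, equal-volume experiment), and vsLP / vsLF are the competing males'
sperm speeds standardized to zero mean and unit sample SD across the analysis
dataset (each ecotype's speed scaled separately, both experiments pooled).
b_female and b_pair are crossed Gaussian random intercepts for female identity
and male pair.

Priors: each fixed effect gets an independent Student-t(0, scale, df) prior
(default scale 2.5, df 1, i.e. Cauchy(0, 2.5)); random effects are
N(0, sd^2) with half-Cauchy(0, 2.5) hyperpriors on the two SDs.

``log_posterior`` is the plain-numpy reference density — every term written
out, including binomial normalizing constants — against which the compiled
sampler is validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FIXED_EFFECT_NAMES",
    "PriorSpec",
    "ModelParams",
    "CompetitionData",
    "scale_speeds",
    "build_design",
    "log_posterior",
]

FIXED_EFFECT_NAMES = (
    "intercept",
    "female_lp",
    "equal_number",
    "vs_lp",
    "vs_lf",
    "equal_number_x_vs_lp",
    "equal_number_x_vs_lf",
)


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the fixed-effect and variance priors."""

    fixed_scale: float = 2.5
    fixed_df: float = 1.0
    sd_scale: float = 2.5  # half-Cauchy scale for random-effect SDs

    def __post_init__(self) -> None:
        if not (self.fixed_scale > 0 and self.fixed_df > 0 and self.sd_scale > 0):
            raise ValueError("prior scales and df must be > 0")


@dataclass
class ModelParams:
    """One point in parameter space (logit scale throughout)."""

    alpha: np.ndarray
    b_female: np.ndarray = field(default_factory=lambda: np.zeros(0))
    b_pair: np.ndarray = field(default_factory=lambda: np.zeros(0))
    sd_female: float = 1.0
    sd_pair: float = 1.0


class CompetitionData:
    """Design container for the siring-success model.

    Attributes
    ----------
    c, n : int arrays, LP-sired count and total genotyped larvae per trial.
    x : (n_trials, k) float design matrix of fixed effects (incl. intercept).
    female_idx, pair_idx : optional int arrays mapping trials to random-effect
        levels; ``None`` disables that random effect (used by reduced models).
    """

    def __init__(
        self,
        c: Sequence[int],
        n: Sequence[int],
        x: np.ndarray,
        female_idx: Optional[Sequence[int]] = None,
        pair_idx: Optional[Sequence[int]] = None,
        female_levels: Optional[Sequence[str]] = None,
        pair_levels: Optional[Sequence[str]] = None,
        colnames: Optional[Sequence[str]] = None,
    ) -> None:
        self.c = np.asarray(c, dtype=np.int64)
        self.n = np.asarray(n, dtype=np.int64)
        self.x = np.asarray(x, dtype=float)
        if self.x.ndim != 2 or self.x.shape[0] != self.c.size:
            raise ValueError("design matrix shape mismatch")
        if self.c.size == 0:
            raise ValueError("data must be nonempty")
        if np.any(self.c < 0) or np.any(self.c > self.n):
            raise ValueError("need 0 <= C <= N for every trial")
        self.female_idx = None if female_idx is None else np.asarray(female_idx, np.int64)
        self.pair_idx = None if pair_idx is None else np.asarray(pair_idx, np.int64)
        self.female_levels = list(female_levels) if female_levels is not None else None
        self.pair_levels = list(pair_levels) if pair_levels is not None else None
        self.colnames = list(colnames) if colnames is not None else [
            f"x{j}" for j in range(self.x.shape[1])
        ]

    @property
    def n_trials(self) -> int:
        return int(self.c.size)

    @property
    def n_females(self) -> int:
        return 0 if self.female_idx is None else int(self.female_idx.max()) + 1

    @property
    def n_pairs(self) -> int:
        return 0 if self.pair_idx is None else int(self.pair_idx.max()) + 1

    # binomial coefficients are parameter-free; cache them once
    _log_binom: Optional[np.ndarray] = None

    @property
    def log_binom(self) -> np.ndarray:
        if self._log_binom is None:
            self._log_binom = np.array(
                [
                    lgamma(n + 1) - lgamma(c + 1) - lgamma(n - c + 1)
                    for c, n in zip(self.c, self.n)
                ]
            )
        return self._log_binom


def scale_speeds(values: Sequence[float]) -> np.ndarray:
    """Standardize speeds to zero mean and unit sample SD (n-1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values to scale")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot scale constant input")
    return (v - v.mean()) / sd


def build_design(
    tallies: pd.DataFrame,
    pair_speeds: pd.DataFrame,
    speed_col_lp: str = "vap_lp",
    speed_col_lf: str = "vap_lf",
) -> CompetitionData:
    """Assemble the full siring-success design from tallies and pair speeds.

    Parameters
    ----------
    tallies : one row per trial with columns trial_id, pair_id, female_id,
        female_ecotype ('LF'/'LP'), experiment ('equal_volume'/'equal_number'),
        c_lp, n.
    pair_speeds : one row per pair with columns pair_id plus the two speed
        columns (the LP and the LF male's speed, µm/s, unscaled).

    Speeds are standardized here, per ecotype, across the trials actually
    analyzed — so the scaling set matches the modeled dataset.
    """
    df = tallies.merge(pair_speeds, on="pair_id", how="left", validate="m:1")
    if df[[speed_col_lp, speed_col_lf]].isna().any().any():
        missing = df.loc[df[speed_col_lp].isna() | df[speed_col_lf].isna(), "pair_id"]
        raise ValueError(f"missing speeds for pairs {sorted(set(missing))}")
    female_lp = (df["female_ecotype"] == "LP").to_numpy(float)
    equal_number = (df["experiment"] == "equal_number").to_numpy(float)
    vs_lp = scale_speeds(df[speed_col_lp])
    vs_lf = scale_speeds(df[speed_col_lf])
    x = np.column_stack(
        [
            np.ones(len(df)),
            female_lp,
            equal_number,
            vs_lp,
            vs_lf,
            equal_number * vs_lp,
            equal_number * vs_lf,
        ]
    )
    females = sorted(df["female_id"].astype(str).unique())
    pairs = sorted(df["pair_id"].astype(str).unique())
    fmap = {f: i for i, f in enumerate(females)}
    pmap = {p: i for i, p in enumerate(pairs)}
    return CompetitionData(
        c=df["c_lp"].to_numpy(),
        n=df["n"].to_numpy(),
        x=x,
        female_idx=df["female_id"].astype(str).map(fmap).to_numpy(),
        pair_idx=df["pair_id"].astype(str).map(pmap).to_numpy(),
        female_levels=females,
        pair_levels=pairs,
        colnames=list(FIXED_EFFECT_NAMES),
    )


def _log1pexp(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    hi = eta > 35.0
    lo = eta < -35.0
    mid = ~(hi | lo)
    out[hi] = eta[hi]
    out[lo] = np.exp(eta[lo])
    out[mid] = np.log1p(np.exp(eta[mid]))
    return out


def _t_logpdf(x: np.ndarray, scale: float, df: float) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return (
        lgamma((df + 1) / 2)
        - lgamma(df / 2)
        - 0.5 * np.log(df * np.pi)
        - np.log(scale)
        - (df + 1) / 2 * np.log1p((x / scale) ** 2 / df)
    )


def _half_cauchy_logpdf(sd: float, scale: float) -> float:
    if sd <= 0:
        return -np.inf
    return float(np.log(2.0) - np.log(np.pi * scale) - np.log1p((sd / scale) ** 2))


def linear_predictor(params: ModelParams, data: CompetitionData) -> np.ndarray:
    eta = data.x @ params.alpha
    if data.female_idx is not None:
        eta = eta + params.b_female[data.female_idx]
    if data.pair_idx is not None:
        eta = eta + params.b_pair[data.pair_idx]
    return eta


def log_likelihood(params: ModelParams, data: CompetitionData) -> float:
    """Binomial log likelihood, including the C(N, C) constants."""
    eta = linear_predictor(params, data)
    return float(np.sum(data.log_binom + data.c * eta - data.n * _log1pexp(eta)))


def log_posterior(
    params: ModelParams, data: CompetitionData, prior: PriorSpec = PriorSpec()
) -> float:
    """Joint log posterior density (up to the marginal-likelihood constant).

    Returns -inf only when a random-effect SD is non-positive while that
    random effect is present; finite otherwise for finite parameters.
    """
    lp = log_likelihood(params, data)
    lp += float(np.sum(_t_logpdf(params.alpha, prior.fixed_scale, prior.fixed_df)))
    if data.female_idx is not None:
        if params.sd_female <= 0:
            return -np.inf
        lp += float(
            np.sum(
                -0.5 * np.log(2 * np.pi)
                - np.log(params.sd_female)
                - params.b_female**2 / (2 * params.sd_female**2)
            )
        )
        lp += _half_cauchy_logpdf(params.sd_female, prior.sd_scale)
    if data.pair_idx is not None:
        if params.sd_pair <= 0:
            return -np.inf
        lp += float(
            np.sum(
                -0.5 * np.log(2 * np.pi)
                - np.log(params.sd_pair)
                - params.b_pair**2 / (2 * params.sd_pair**2)
            )
        )
        lp += _half_cauchy_logpdf(params.sd_pair, prior.sd_scale)
    return lp
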