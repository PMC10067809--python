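"""Posterior summaries and convergence diagnostics for the siring model.

Implements the potential-scale-reduction statistic (R-hat), the posterior
sign-based "MCMC p-value", the posterior-predictive (Bayesian) p-value based
on squared Pearson residuals, and the per-cell Delta statistic measuring
departure from random paternity (0.5) in each female-ecotype x experiment
cell.
"""

from __future__ import annotations

import warnings
from typing import Dict, Optional

import numpy as np
from scipy.special import expit

from .model import CompetitionData
from .sampler import PosteriorSamples

__all__ = [
    "gelman_rubin",
    "mcmc_pvalue",
    "bayes_pvalue",
    "delta_stat",
    "summarize_fit",
]

DELTA_CELLS = (
    ("LF", "equal_volume"),
    ("LP", "equal_volume"),
    ("LF", "equal_number"),
    ("LP", "equal_number"),
)


def gelman_rubin(samples: PosteriorSamples, parameter: str) -> float:
    """Gelman-Rubin potential scale reduction for one parameter.

    R-hat = sqrt(((n-1)/n * W + B/n) / W) with W the mean within-chain
    variance and B the between-chain variance (n * variance of chain means).
    Returns NaN with a warning when the within-chain variance is zero.
    """
    chains = samples.get(parameter)
    m, n = chains.shape
    if m < 2:
        raise ValueError("need at least two chains")
    if n < 2:
        raise ValueError("need at least 2 retained draws per chain")
    w = chains.var(axis=1, ddof=1).mean()
    if w == 0:
        warnings.warn(
            f"zero within-chain variance for {parameter!r}; R-hat undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    b = n * chains.mean(axis=1).var(ddof=1)
    return float(np.sqrt(((n - 1) / n * w + b / n) / w))


def mcmc_pvalue(draws: np.ndarray, tail: str = "two") -> float:
    """Posterior sign-based p-value.

    ``two``: twice the fraction of draws whose sign opposes the posterior
    mean's sign, capped at 1 (zero draws, and sign(0), count with the mean).
    ``one_positive``: fraction of draws > 0; ``one_negative``: fraction < 0.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size == 0:
        raise ValueError("empty draws")
    if tail == "one_positive":
        return float(np.mean(draws > 0))
    if tail == "one_negative":
        return float(np.mean(draws < 0))
    if tail != "two":
        raise ValueError(f"unknown tail {tail!r}")
    if np.all(draws == 0):
        return 1.0  # point mass at zero: no evidence of departure
    mean = draws.mean()
    opposite = (draws < 0) if mean >= 0 else (draws > 0)
    return float(min(1.0, 2.0 * opposite.mean()))


def _per_draw_probs(samples: PosteriorSamples, data: CompetitionData) -> np.ndarray:
    """Fitted p_i for every retained draw; shape (n_draws, n_trials)."""
    flat = samples.flat_draws
    k = samples.meta["k_fixed"]
    nf = samples.meta["n_females"]
    npair = samples.meta["n_pairs"]
    eta = flat[:, :k] @ data.x.T
    if nf:
        bf = flat[:, k : k + nf]
        eta = eta + bf[:, data.female_idx]
    if npair:
        bp = flat[:, k + nf : k + nf + npair]
        eta = eta + bp[:, data.pair_idx]
    return expit(eta)


def bayes_pvalue(
    samples: PosteriorSamples,
    data: CompetitionData,
    seed: int = 0,
    max_draws: Optional[int] = 4000,
) -> float:
    """Posterior-predictive p-value from squared Pearson residuals.

    For each retained draw, replicate counts are simulated from the fitted
    binomial model and the discrepancy D = sum_i (C_i - N_i p_i)^2 /
    (N_i p_i (1 - p_i)) is computed for the observed and the replicated data.
    The p-value is the fraction of draws with D(replicate) > D(observed);
    values near 0.5 indicate adequate fit. ``max_draws`` thins the retained
    draws evenly to bound the simulation cost.
    """
    probs = _per_draw_probs(samples, data)
    if max_draws is not None and probs.shape[0] > max_draws:
        idx = np.linspace(0, probs.shape[0] - 1, max_draws).astype(int)
        probs = probs[idx]
    rng = np.random.default_rng(seed)
    n = data.n[None, :]
    var = np.clip(n * probs * (1 - probs), 1e-12, None)
    d_obs = (((data.c[None, :] - n * probs) ** 2) / var).sum(axis=1)
    c_rep = rng.binomial(np.broadcast_to(n, probs.shape), probs)
    d_rep = (((c_rep - n * probs) ** 2) / var).sum(axis=1)
    return float(np.mean(d_rep > d_obs))


def delta_stat(samples: PosteriorSamples) -> Dict[str, dict]:
    """Departure from random paternity in the four design cells.

    For each female-ecotype x experiment cell, the model-implied probability
    that the LP male sires a larva is evaluated per draw from the fixed
    effects alone (scaled speeds at their mean of 0, random effects at 0);
    Delta = 0.5 - p. Returns per-cell draws, posterior mean/SD, and the
    two-tailed MCMC p-value.
    """
    a0 = samples.flat("intercept")
    a1 = samples.flat("female_lp")
    a2 = samples.flat("equal_number")
    out: Dict[str, dict] = {}
    for female, experiment in DELTA_CELLS:
        eta = a0 + (a1 if female == "LP" else 0.0) + (a2 if experiment == "equal_number" else 0.0)
        delta = 0.5 - expit(eta)
        out[f"{female}_{experiment}"] = {
            "draws": delta,
            "mean": float(delta.mean()),
            "sd": float(delta.std(ddof=1)),
            "p_mcmc": mcmc_pvalue(delta, "two"),
        }
    return out


def summarize_fit(
    samples: PosteriorSamples,
    data: CompetitionData,
    one_tailed: tuple = ("equal_number_x_vs_lp", "equal_number_x_vs_lf"),
    seed: int = 0,
) -> dict:
    """Mean, SD, R-hat and MCMC p-value per fixed effect, plus fit checks.

    The two speed-by-experiment interactions use the one-tailed p-value
    (fraction of positive draws), reflecting the directional hypothesis that
    faster LF sperm should raise LF siring success at equal sperm number;
    all other effects are two-tailed.
    """
    fixed = {}
    for name in data.colnames:
        draws = samples.flat(name)
        tail = "one_positive" if name in one_tailed else "two"
        fixed[name] = {
            "mean": float(draws.mean()),
            "sd": float(draws.std(ddof=1)),
            "rhat": gelman_rubin(samples, name),
            "p_mcmc": mcmc_pvalue(draws, tail),
            "tail": tail,
            "ci95": [
                float(np.quantile(draws, 0.025)),
                float(np.quantile(draws, 0.975)),
            ],
        }
    summary = {"fixed_effects": fixed}
    for sd_name in ("sd_female", "sd_pair"):
        if sd_name in samples.names:
            draws = samples.flat(sd_name)
            summary[sd_name] = {
                "mean": float(draws.mean()),
                "sd": float(draws.std(ddof=1)),
                "rhat": gelman_rubin(samples, sd_name),
            }
    summary["bayes_pvalue"] = bayes_pvalue(samples, data, seed=seed)
    deltas = delta_stat(samples)
    summary["delta"] = {
        cell: {k: v for k, v in d.items() if k != "draws"} for cell, d in deltas.items()
    }
    summary["max_rhat_fixed"] = float(
        np.nanmax([fixed[nm]["rhat"] for nm in data.colnames])
    )
    return summary
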