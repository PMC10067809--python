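"""Adaptive random-walk Metropolis-within-Gibbs sampler for the siring model.

Each parameter (fixed effects, random-effect values, log random-effect SDs)
is updated in turn with a Gaussian random-walk proposal; proposal step sizes
adapt toward a 0.44 acceptance rate during burn-in only, so the retained
chain is a valid time-homogeneous Markov chain. SDs are sampled on the log
scale with the Jacobian correction and reported on the natural scale.

The default chain specification (4 chains x 200,000 iterations, 100,000
burn-in, thinning 10) matches the study's; every scale can be reduced via
``MCMCConfig`` for desk-scale runs. Chains are independently seeded from one
user seed and are bitwise reproducible.

The hot loop is compiled with numba; the pure-numpy ``log_posterior`` in
``model.py`` is the reference density the compiled code is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log, pi
from typing import Optional

import numpy as np
from numba import njit

from .model import CompetitionData, ModelParams, PriorSpec, log_posterior

__all__ = ["MCMCConfig", "PosteriorSamples", "fit"]

_ADAPT_INTERVAL = 50
_TARGET_ACCEPT = 0.44


@dataclass(frozen=True)
class MCMCConfig:
    """Chain specification; defaults match the study-scale run."""

    n_chains: int = 4
    n_iter: int = 200_000
    burnin: int = 100_000
    thin: int = 10
    seed: int = 0
    prior: PriorSpec = PriorSpec()

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not 0 <= self.burnin < self.n_iter:
            raise ValueError("burnin must satisfy 0 <= burnin < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if (self.n_iter - self.burnin) // self.thin < 1:
            raise ValueError("no draws would be retained")

    @property
    def n_retained(self) -> int:
        return (self.n_iter - self.burnin) // self.thin


@dataclass
class PosteriorSamples:
    """Retained MCMC draws: (chains, retained, parameters) plus metadata."""

    draws: np.ndarray
    names: list
    meta: dict

    def __post_init__(self) -> None:
        if self.draws.ndim != 3:
            raise ValueError("draws must be (chains, retained, parameters)")
        if self.draws.shape[2] != len(self.names):
            raise ValueError("parameter-name count mismatch")
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("non-finite draws")

    def index(self, name: str) -> int:
        return self.names.index(name)

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (chains, retained)."""
        return self.draws[:, :, self.index(name)]

    def flat(self, name: str) -> np.ndarray:
        """Pooled draws of one parameter across chains."""
        return self.get(name).reshape(-1)

    @property
    def flat_draws(self) -> np.ndarray:
        """(chains*retained, parameters) pooled draw matrix."""
        return self.draws.reshape(-1, self.draws.shape[2])


@njit(cache=True)
def _log1pexp(v):
    if v > 35.0:
        return v
    if v < -35.0:
        return np.exp(v)
    return np.log1p(np.exp(v))


@njit(cache=True)
def _loglik_delta(c, n, eta, delta_eta):
    """Log-likelihood change when eta shifts by delta_eta (kernel terms only)."""
    s = 0.0
    for i in range(eta.shape[0]):
        e0 = eta[i]
        e1 = e0 + delta_eta[i]
        s += c[i] * (e1 - e0) - n[i] * (_log1pexp(e1) - _log1pexp(e0))
    return s


@njit(cache=True)
def _t_logpdf1(x, scale, df):
    return (
        lgamma((df + 1.0) / 2.0)
        - lgamma(df / 2.0)
        - 0.5 * log(df * pi)
        - log(scale)
        - (df + 1.0) / 2.0 * np.log1p((x / scale) ** 2 / df)
    )


@njit(cache=True)
def _run_chain(
    c,
    n,
    x,
    fidx,
    pidx,
    nf,
    npair,
    n_iter,
    burnin,
    thin,
    seed,
    fixed_scale,
    fixed_df,
    sd_scale,
    init,
    step_init,
    adapt_interval,
    target_accept,
):
    np.random.seed(seed)
    ntr, k = x.shape
    has_f = nf > 0
    has_p = npair > 0
    d = k + nf + npair + (1 if has_f else 0) + (1 if has_p else 0)
    pos_bf = k
    pos_bp = k + nf
    pos_sdf = k + nf + npair  # valid only if has_f
    pos_sdp = pos_sdf + (1 if has_f else 0)  # valid only if has_p

    theta = init.copy()  # SDs stored as log(sd)
    step = step_init.copy()
    eta = np.zeros(ntr)
    for i in range(ntr):
        e = 0.0
        for j in range(k):
            e += x[i, j] * theta[j]
        if has_f:
            e += theta[pos_bf + fidx[i]]
        if has_p:
            e += theta[pos_bp + pidx[i]]
        eta[i] = e

    n_keep = (n_iter - burnin) // thin
    out = np.empty((n_keep, d))
    acc = np.zeros(d)
    acc_win = np.zeros(d)
    kept = 0
    delta_eta = np.zeros(ntr)

    for it in range(n_iter):
        # --- fixed effects ---
        for j in range(k):
            dlt = step[j] * np.random.normal()
            prop = theta[j] + dlt
            for i in range(ntr):
                delta_eta[i] = x[i, j] * dlt
            logr = _loglik_delta(c, n, eta, delta_eta)
            logr += _t_logpdf1(prop, fixed_scale, fixed_df) - _t_logpdf1(
                theta[j], fixed_scale, fixed_df
            )
            if np.log(np.random.random()) < logr:
                theta[j] = prop
                for i in range(ntr):
                    eta[i] += delta_eta[i]
                acc[j] += 1.0
                acc_win[j] += 1.0

        # --- female random effects ---
        if has_f:
            sd_f = np.exp(theta[pos_sdf])
            for j in range(nf):
                p = pos_bf + j
                dlt = step[p] * np.random.normal()
                prop = theta[p] + dlt
                logr = 0.0
                for i in range(ntr):
                    if fidx[i] == j:
                        e0 = eta[i]
                        e1 = e0 + dlt
                        logr += c[i] * dlt - n[i] * (_log1pexp(e1) - _log1pexp(e0))
                logr += (theta[p] ** 2 - prop**2) / (2.0 * sd_f * sd_f)
                if np.log(np.random.random()) < logr:
                    theta[p] = prop
                    for i in range(ntr):
                        if fidx[i] == j:
                            eta[i] += dlt
                    acc[p] += 1.0
                    acc_win[p] += 1.0

        # --- pair random effects ---
        if has_p:
            sd_p = np.exp(theta[pos_sdp])
            for j in range(npair):
                p = pos_bp + j
                dlt = step[p] * np.random.normal()
                prop = theta[p] + dlt
                logr = 0.0
                for i in range(ntr):
                    if pidx[i] == j:
                        e0 = eta[i]
                        e1 = e0 + dlt
                        logr += c[i] * dlt - n[i] * (_log1pexp(e1) - _log1pexp(e0))
                logr += (theta[p] ** 2 - prop**2) / (2.0 * sd_p * sd_p)
                if np.log(np.random.random()) < logr:
                    theta[p] = prop
                    for i in range(ntr):
                        if pidx[i] == j:
                            eta[i] += dlt
                    acc[p] += 1.0
                    acc_win[p] += 1.0

        # --- random-effect SDs (log scale; prior + Jacobian: half-Cauchy(sd)*sd) ---
        if has_f:
            p = pos_sdf
            prop = theta[p] + step[p] * np.random.normal()
            sd0 = np.exp(theta[p])
            sd1 = np.exp(prop)
            logr = 0.0
            for j in range(nf):
                b = theta[pos_bf + j]
                logr += -np.log(sd1) - b * b / (2.0 * sd1 * sd1)
                logr -= -np.log(sd0) - b * b / (2.0 * sd0 * sd0)
            logr += -np.log1p((sd1 / sd_scale) ** 2) + np.log(sd1)
            logr -= -np.log1p((sd0 / sd_scale) ** 2) + np.log(sd0)
            if np.log(np.random.random()) < logr:
                theta[p] = prop
                acc[p] += 1.0
                acc_win[p] += 1.0
        if has_p:
            p = pos_sdp
            prop = theta[p] + step[p] * np.random.normal()
            sd0 = np.exp(theta[p])
            sd1 = np.exp(prop)
            logr = 0.0
            for j in range(npair):
                b = theta[pos_bp + j]
                logr += -np.log(sd1) - b * b / (2.0 * sd1 * sd1)
                logr -= -np.log(sd0) - b * b / (2.0 * sd0 * sd0)
            logr += -np.log1p((sd1 / sd_scale) ** 2) + np.log(sd1)
            logr -= -np.log1p((sd0 / sd_scale) ** 2) + np.log(sd0)
            if np.log(np.random.random()) < logr:
                theta[p] = prop
                acc[p] += 1.0
                acc_win[p] += 1.0

        # --- step-size adaptation, burn-in only ---
        if it < burnin and (it + 1) % adapt_interval == 0:
            for p in range(d):
                rate = acc_win[p] / adapt_interval
                step[p] *= np.exp(rate - target_accept)
                if step[p] < 1e-4:
                    step[p] = 1e-4
                elif step[p] > 10.0:
                    step[p] = 10.0
                acc_win[p] = 0.0

        # --- storage ---
        if it >= burnin and (it - burnin) % thin == 0 and kept < n_keep:
            for p in range(d):
                out[kept, p] = theta[p]
            kept += 1

    return out, acc / n_iter


def _param_names(data: CompetitionData) -> list:
    names = list(data.colnames)
    if data.female_idx is not None:
        levels = data.female_levels or [str(i) for i in range(data.n_females)]
        names += [f"b_female[{lv}]" for lv in levels]
    if data.pair_idx is not None:
        levels = data.pair_levels or [str(i) for i in range(data.n_pairs)]
        names += [f"b_pair[{lv}]" for lv in levels]
    if data.female_idx is not None:
        names.append("sd_female")
    if data.pair_idx is not None:
        names.append("sd_pair")
    return names


def _check_init(data: CompetitionData, prior: PriorSpec) -> None:
    params = ModelParams(
        alpha=np.zeros(data.x.shape[1]),
        b_female=np.zeros(data.n_females),
        b_pair=np.zeros(data.n_pairs),
        sd_female=0.5,
        sd_pair=0.5,
    )
    if not np.isfinite(log_posterior(params, data, prior)):
        raise RuntimeError("non-finite posterior at initial values")


def fit(data: CompetitionData, config: Optional[MCMCConfig] = None) -> PosteriorSamples:
    """Sample the posterior of the siring-success model.

    Chains are seeded as ``(seed * 1_000_003 + chain) mod 2^31`` so runs with
    the same configuration reproduce identical draws.
    """
    config = config or MCMCConfig()
    _check_init(data, config.prior)
    k = data.x.shape[1]
    nf, npair = data.n_females, data.n_pairs
    d = k + nf + npair + (1 if nf else 0) + (1 if npair else 0)
    init = np.zeros(d)
    if nf:
        init[k + nf + npair] = np.log(0.5)
    if npair:
        init[k + nf + npair + (1 if nf else 0)] = np.log(0.5)
    step0 = np.full(d, 0.3)
    fidx = data.female_idx if nf else np.zeros(data.n_trials, np.int64)
    pidx = data.pair_idx if npair else np.zeros(data.n_trials, np.int64)

    chains = []
    accs = []
    for chain in range(config.n_chains):
        seed = (config.seed * 1_000_003 + chain) % 2**31
        draws, acc = _run_chain(
            data.c,
            data.n,
            data.x,
            fidx,
            pidx,
            nf,
            npair,
            config.n_iter,
            config.burnin,
            config.thin,
            seed,
            config.prior.fixed_scale,
            config.prior.fixed_df,
            config.prior.sd_scale,
            init,
            step0,
            _ADAPT_INTERVAL,
            _TARGET_ACCEPT,
        )
        chains.append(draws)
        accs.append(acc)

    draws = np.stack(chains)  # (chains, retained, d)
    # report SDs on the natural scale
    if nf:
        draws[:, :, k + nf + npair] = np.exp(draws[:, :, k + nf + npair])
    if npair:
        pos = k + nf + npair + (1 if nf else 0)
        draws[:, :, pos] = np.exp(draws[:, :, pos])
    meta = {
        "n_chains": config.n_chains,
        "n_iter": config.n_iter,
        "burnin": config.burnin,
        "thin": config.thin,
        "seed": config.seed,
        "acceptance": np.stack(accs).mean(axis=0).tolist(),
        "n_females": nf,
        "n_pairs": npair,
        "k_fixed": k,
    }
    return PosteriorSamples(draws=draws, names=_param_names(data), meta=meta)
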