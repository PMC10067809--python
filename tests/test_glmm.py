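"""Bayesian siring model: density oracle, diagnostics, sampler behavior."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit

from spermcomp.glmm import (
    CompetitionData,
    MCMCConfig,
    ModelParams,
    PosteriorSamples,
    bayes_pvalue,
    build_design,
    delta_stat,
    fit,
    gelman_rubin,
    log_posterior,
    mcmc_pvalue,
    scale_speeds,
)
from spermcomp.glmm.model import FIXED_EFFECT_NAMES, PriorSpec

from conftest import pair_speed_table, simulate_study
from spermcomp.synthetic import TruthConfig


class TestScaleSpeeds:
    def test_three_point_example(self):
        assert np.allclose(scale_speeds([1, 2, 3]), [-1, 0, 1])

    def test_idempotent(self, rng):
        z = scale_speeds(rng.normal(size=20))
        assert np.allclose(scale_speeds(z), z)

    def test_contract(self, rng):
        z = scale_speeds(rng.lognormal(size=37))
        assert abs(z.mean()) < 1e-12
        assert abs(z.std(ddof=1) - 1) < 1e-12

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            scale_speeds([2.0, 2.0, 2.0])


class TestLogPosterior:
    def test_single_trial_closed_form(self):
        data = CompetitionData([1], [2], np.ones((1, 1)))
        lp = log_posterior(ModelParams(alpha=np.zeros(1)), data)
        # binomial: log C(2,1) + 2 log 0.5 = log 0.5; prior: Cauchy(0, 2.5) at 0
        assert lp == pytest.approx(np.log(0.5) - np.log(np.pi * 2.5))

    def test_trial_ordering_invariance(self, rng):
        c = np.array([3, 7, 12, 0]); n = np.array([10, 20, 27, 5])
        x = rng.normal(size=(4, 2)); x[:, 0] = 1
        fidx = np.array([0, 1, 0, 1]); pidx = np.array([0, 0, 1, 1])
        params = ModelParams(
            alpha=rng.normal(size=2), b_female=rng.normal(size=2),
            b_pair=rng.normal(size=2), sd_female=0.7, sd_pair=0.4,
        )
        perm = np.array([2, 0, 3, 1])
        a = log_posterior(params, CompetitionData(c, n, x, fidx, pidx))
        b = log_posterior(params, CompetitionData(c[perm], n[perm], x[perm], fidx[perm], pidx[perm]))
        assert a == pytest.approx(b, rel=1e-12)

    def test_matches_naive_scipy_evaluator(self, rng):
        """Independent oracle: every term via scipy.stats distributions."""
        n_tr, nf, npair = 6, 3, 2
        c = rng.integers(0, 15, n_tr); n = c + rng.integers(1, 15, n_tr)
        x = np.column_stack([np.ones(n_tr), rng.normal(size=(n_tr, 2))])
        fidx = rng.integers(0, nf, n_tr); pidx = rng.integers(0, npair, n_tr)
        data = CompetitionData(c, n, x, fidx, pidx)
        prior = PriorSpec(fixed_scale=2.5, fixed_df=1.0, sd_scale=2.5)
        for _ in range(5):
            params = ModelParams(
                alpha=rng.normal(size=3), b_female=rng.normal(size=nf),
                b_pair=rng.normal(size=npair),
                sd_female=float(rng.uniform(0.1, 2)), sd_pair=float(rng.uniform(0.1, 2)),
            )
            eta = x @ params.alpha + params.b_female[fidx] + params.b_pair[pidx]
            naive = (
                stats.binom.logpmf(c, n, expit(eta)).sum()
                + stats.t.logpdf(params.alpha, df=1, scale=2.5).sum()
                + stats.norm.logpdf(params.b_female, scale=params.sd_female).sum()
                + stats.norm.logpdf(params.b_pair, scale=params.sd_pair).sum()
                + stats.halfcauchy.logpdf(params.sd_female, scale=2.5)
                + stats.halfcauchy.logpdf(params.sd_pair, scale=2.5)
            )
            assert log_posterior(params, data, prior) == pytest.approx(naive, rel=1e-9)

    def test_nonpositive_sd_gives_neg_inf(self):
        data = CompetitionData([1], [2], np.ones((1, 1)), [0], [0])
        params = ModelParams(np.zeros(1), np.zeros(1), np.zeros(1), sd_female=-1.0)
        assert log_posterior(params, data) == -np.inf


class TestBuildDesign:
    def test_coding_and_scaling(self, study):
        _, _, _, _, tallies, data = study
        assert data.colnames == list(FIXED_EFFECT_NAMES)
        assert np.all(np.isin(data.x[:, 1], [0, 1]))  # female_lp dummy
        assert np.all(np.isin(data.x[:, 2], [0, 1]))  # equal_number dummy
        for col in (3, 4):  # scaled speeds
            assert abs(data.x[:, col].mean()) < 0.5  # scaled per pair, repeated per trial
        assert np.allclose(data.x[:, 5], data.x[:, 2] * data.x[:, 3])
        assert np.allclose(data.x[:, 6], data.x[:, 2] * data.x[:, 4])
        assert data.n_trials == len(tallies)
        assert data.n_pairs == tallies.pair_id.nunique()
        assert data.n_females == tallies.female_id.nunique()


class TestGelmanRubin:
    @staticmethod
    def _samples(chains):
        arr = np.asarray(chains, float)[:, :, None]
        return PosteriorSamples(arr, ["x"], {})

    def test_identical_chains_hand_formula(self):
        # W=1, B=0, n=3 -> sqrt((n-1)/n) = sqrt(2/3)
        s = self._samples([[1, 2, 3], [1, 2, 3]])
        assert gelman_rubin(s, "x") == pytest.approx(np.sqrt(2 / 3))

    def test_zero_within_variance_warns_nan(self):
        s = self._samples([[0, 0, 0], [10, 10, 10]])
        with pytest.warns(RuntimeWarning):
            assert np.isnan(gelman_rubin(s, "x"))

    def test_disjoint_chains_flagged(self):
        s = self._samples([[0.0, 0.1, -0.1, 0.05], [10.0, 10.1, 9.9, 10.05]])
        assert gelman_rubin(s, "x") > 1.1


class TestMcmcPvalue:
    def test_all_positive(self):
        assert mcmc_pvalue(np.ones(100)) == 0.0

    def test_one_quarter_opposite(self):
        assert mcmc_pvalue(np.array([-1.0, 1.0, 1.0, 1.0])) == pytest.approx(0.5)

    def test_symmetric_edge_capped_at_one(self):
        assert mcmc_pvalue(np.array([-1.0, 1.0])) == 1.0

    def test_zeros_count_with_mean_sign(self):
        assert mcmc_pvalue(np.array([0.0, 0.0, 1.0])) == 0.0

    def test_one_tailed(self):
        draws = np.array([-1.0, 2.0, 3.0, 4.0])
        assert mcmc_pvalue(draws, "one_positive") == 0.75
        assert mcmc_pvalue(draws, "one_negative") == 0.25


class TestDelta:
    @staticmethod
    def _samples(a0, a1, a2, n=200):
        draws = np.zeros((1, n, 3))
        draws[0, :, 0] = a0
        draws[0, :, 1] = a1
        draws[0, :, 2] = a2
        return PosteriorSamples(draws, ["intercept", "female_lp", "equal_number"], {})

    def test_all_zero_alphas(self):
        cells = delta_stat(self._samples(0.0, 0.0, 0.0))
        assert len(cells) == 4
        for d in cells.values():
            assert d["mean"] == 0.0
            assert d["p_mcmc"] == 1.0

    def test_intercept_only_closed_form(self):
        logit06 = np.log(0.6 / 0.4)
        cells = delta_stat(self._samples(logit06, 0.0, 0.0))
        for d in cells.values():
            assert d["mean"] == pytest.approx(-0.1, abs=1e-12)

    def test_cellwise_additivity(self):
        cells = delta_stat(self._samples(0.0, 0.4, -0.6))
        assert cells["LF_equal_volume"]["mean"] == pytest.approx(0.0)
        assert cells["LP_equal_volume"]["mean"] == pytest.approx(0.5 - expit(0.4))
        assert cells["LF_equal_number"]["mean"] == pytest.approx(0.5 - expit(-0.6))
        assert cells["LP_equal_number"]["mean"] == pytest.approx(0.5 - expit(-0.2))


SMALL_MCMC = MCMCConfig(n_chains=2, n_iter=4000, burnin=2000, thin=2, seed=7)


class TestFit:
    def test_same_seed_identical_draws(self, study):
        *_, data = study
        a = fit(data, SMALL_MCMC)
        b = fit(data, SMALL_MCMC)
        assert np.array_equal(a.draws, b.draws)
        assert a.names == b.names

    def test_different_seed_differs(self, study):
        *_, data = study
        a = fit(data, SMALL_MCMC)
        c = fit(data, MCMCConfig(n_chains=2, n_iter=4000, burnin=2000, thin=2, seed=8))
        assert not np.array_equal(a.draws, c.draws)

    def test_retained_shape_and_sd_positivity(self, study):
        *_, data = study
        s = fit(data, SMALL_MCMC)
        assert s.draws.shape == (2, 1000, 7 + data.n_females + data.n_pairs + 2)
        assert (s.flat("sd_female") > 0).all()
        assert (s.flat("sd_pair") > 0).all()

    def test_invalid_chain_spec_rejected(self):
        with pytest.raises(ValueError):
            MCMCConfig(burnin=300_000)
        with pytest.raises(ValueError):
            MCMCConfig(thin=0)

    def test_label_swap_symmetry(self):
        """Relabeling the ecotypes (C -> N-C, speeds swapped, female ecotype
        flipped) negates the experiment-effect posterior mean within MC error."""
        cfg = TruthConfig(seed=17)
        males, females, trials, genotypes, tallies, data = simulate_study(cfg)
        speeds = pair_speed_table(males)
        swapped = tallies.copy()
        swapped["c_lp"] = swapped["n"] - swapped["c_lp"]
        swapped["female_ecotype"] = swapped["female_ecotype"].map({"LF": "LP", "LP": "LF"})
        speeds_sw = speeds.rename(columns={"vap_lf": "vap_lp", "vap_lp": "vap_lf"})
        data_sw = build_design(swapped, speeds_sw)
        mc = MCMCConfig(n_chains=4, n_iter=12_000, burnin=6_000, thin=3, seed=5)
        m1 = fit(data, mc).flat("equal_number").mean()
        m2 = fit(data_sw, mc).flat("equal_number").mean()
        assert m1 + m2 == pytest.approx(0.0, abs=0.05)


class TestBayesPvalue:
    def test_gross_overdispersion_detected(self):
        # same design cell, half the trials all-LF and half all-LP sired:
        # far more variable than any binomial fit -> tiny p
        c = np.array([0, 0, 0, 0, 27, 27, 27, 27])
        n = np.full(8, 27)
        data = CompetitionData(c, n, np.ones((8, 1)), colnames=["intercept"])
        s = fit(data, MCMCConfig(n_chains=2, n_iter=6000, burnin=3000, thin=3, seed=1))
        assert bayes_pvalue(s, data, seed=0) < 0.05
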