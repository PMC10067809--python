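"""Synthetic-data generator: determinism, design structure, known-truth limits."""

import numpy as np
import pandas as pd
import pytest
from pydantic import ValidationError

from spermcomp import kinematics as kin
from spermcomp.synthetic import (
    TruthConfig,
    make_females,
    simulate_competition,
    simulate_males,
    simulate_trajectories,
    turning_sd_for_vap,
    write_dataset,
)


class TestConfig:
    def test_defaults_give_study_design(self):
        cfg = TruthConfig()
        assert cfg.n_males_per_ecotype == 13
        assert cfg.larvae_per_trial == 27
        assert len(cfg.alpha) == 7

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValidationError):
            TruthConfig(conc_mean_LF=-1)
        with pytest.raises(ValidationError):
            TruthConfig(vcl_mean_LF=200.0, vap_mean_LF=250.0)
        with pytest.raises(ValidationError):
            TruthConfig(larvae_per_trial=0)
        with pytest.raises(ValidationError):
            TruthConfig(unknown_knob=3)


class TestMales:
    def test_counts_per_ecotype(self, default_cfg):
        males = simulate_males(default_cfg)
        assert males.ecotype.value_counts().to_dict() == {"LF": 13, "LP": 13}

    def test_zero_cv_collapses_concentrations(self):
        males = simulate_males(TruthConfig(conc_cv=0, seed=4))
        lp = males[males.ecotype == "LP"]
        assert np.allclose(lp.concentration, TruthConfig().conc_mean_LP)

    def test_same_seed_reproduces_table(self, default_cfg):
        pd.testing.assert_frame_equal(
            simulate_males(default_cfg), simulate_males(default_cfg)
        )

    def test_vap_never_exceeds_vcl(self, default_cfg):
        males = simulate_males(default_cfg)
        assert (males.vap_true <= males.vcl_true).all()


class TestTrajectories:
    def test_point_count_matches_recording_settings(self, default_cfg):
        male = simulate_males(default_cfg).iloc[0]
        df = simulate_trajectories(male, n_tracks=2, fps=60, duration=3.0)
        assert (df.groupby("track").size() == 180).all()

    def test_zero_turning_sd_gives_straight_tracks(self, default_cfg):
        male = simulate_males(default_cfg).iloc[0].copy()
        male["vap_true"] = male["vcl_true"]  # ratio 1 -> sigma 0
        df = simulate_trajectories(male, n_tracks=1, rng=np.random.default_rng(0))
        t = kin.Trajectory("t", df.frame.to_numpy(), df.x_um.to_numpy(),
                           df.y_um.to_numpy(), 60.0)
        assert kin.vap(t, 5) == pytest.approx(kin.vcl(t), rel=1e-9)
        assert kin.vcl(t) == pytest.approx(male["vcl_true"], rel=1e-9)

    def test_speed_recovery_with_many_tracks(self, default_cfg):
        male = simulate_males(default_cfg).iloc[0]
        df = simulate_trajectories(male, n_tracks=116, rng=np.random.default_rng(3))
        trajs = [
            kin.Trajectory(tid, g.frame.to_numpy(), g.x_um.to_numpy(), g.y_um.to_numpy(), 60.0)
            for tid, g in df.groupby("track")
        ]
        s = kin.summarize_subsample(trajs)
        assert abs(s.mean_vcl - male.vcl_true) / male.vcl_true < 0.05
        assert abs(s.mean_vap - male.vap_true) / male.vap_true < 0.10

    def test_turning_calibration_monotone(self):
        # slower average path (lower VAP/VCL) needs more turning
        sd_wiggly = turning_sd_for_vap(300.0, 180.0)
        sd_smooth = turning_sd_for_vap(300.0, 280.0)
        assert sd_wiggly > sd_smooth > 0
        assert turning_sd_for_vap(300.0, 300.0) == 0.0

    def test_invalid_recording_params(self, default_cfg):
        male = simulate_males(default_cfg).iloc[0]
        with pytest.raises(ValueError):
            simulate_trajectories(male, n_tracks=1, fps=0)
        with pytest.raises(ValueError):
            simulate_trajectories(male, n_tracks=1, duration=-1)


class TestCompetition:
    def test_structure_and_bounds(self, study):
        _, _, trials, genotypes, _, _ = study
        assert len(trials) == 52  # 13 pairs x 2 experiments x 2 female ecotypes
        assert (trials.c_lp_true <= trials.n_larvae).all()
        assert (trials.c_lp_true >= 0).all()
        assert len(genotypes) == trials.n_larvae.sum() == 1345

    def test_mendelian_consistency(self, study):
        _, females, trials, genotypes, _, _ = study
        mother = trials.merge(females, left_on="female_id", right_on="female_id")
        geno = genotypes.merge(
            mother[["trial_id", "genotype"]].rename(columns={"genotype": "mother"}),
            on="trial_id",
        )
        ff = geno[geno.mother == "ff"]
        pp = geno[geno.mother == "pp"]
        assert set(ff.genotype) <= {"ff", "pf"}
        assert set(pp.genotype) <= {"pp", "pf"}

    def test_seed_reproducibility(self, default_cfg):
        males = simulate_males(default_cfg)
        females = make_females(default_cfg)
        t1, g1 = simulate_competition(males, females, default_cfg)
        t2, g2 = simulate_competition(males, females, default_cfg)
        pd.testing.assert_frame_equal(t1, t2)
        pd.testing.assert_frame_equal(g1, g2)

    def test_fair_raffle_pooled_share(self):
        # all alphas zero, no random effects: LP share converges to 1/2
        cfg = TruthConfig(
            alpha=(0, 0, 0, 0, 0, 0, 0), sd_female=0, sd_pair=0,
            n_males_per_ecotype=25, larvae_per_trial=120,
            include_failed_pair=False, short_trial_larvae=None, seed=21,
        )
        males = simulate_males(cfg)
        trials, _ = simulate_competition(males, make_females(cfg), cfg)
        n = trials.n_larvae.sum()
        assert n >= 10_000
        share = trials.c_lp_true.sum() / n
        se = 0.5 / np.sqrt(n)
        assert abs(share - 0.5) < 3 * se

    def test_saturating_intercept_gives_all_lp(self):
        cfg = TruthConfig(alpha=(20, 0, 0, 0, 0, 0, 0), sd_female=0, sd_pair=0, seed=2)
        males = simulate_males(cfg)
        trials, genotypes = simulate_competition(males, make_females(cfg), cfg)
        live = trials[trials.n_larvae > 0]
        assert (live.c_lp_true == live.n_larvae).all()
        assert set(genotypes.genotype) <= {"pf", "pp"}

    def test_negative_experiment_effect_lowers_equal_number_share(self):
        # Monte Carlo over many pairs: mean LP share must drop in the
        # equal-number arm when the experiment coefficient is negative
        cfg = TruthConfig(
            alpha=(0, 0, -0.7, 0, 0, 0, 0), sd_female=0.3, sd_pair=0.3,
            n_males_per_ecotype=250, larvae_per_trial=27,
            include_failed_pair=False, short_trial_larvae=None, seed=33,
        )
        males = simulate_males(cfg)
        trials, _ = simulate_competition(males, make_females(cfg), cfg)
        share = trials.assign(s=trials.c_lp_true / trials.n_larvae).groupby("experiment").s.mean()
        assert share["equal_number"] < share["equal_volume"] - 0.05

    def test_heterozygous_female_rejected(self, default_cfg):
        males = simulate_males(default_cfg)
        females = make_females(default_cfg)
        females.loc[0, "genotype"] = "pf"
        with pytest.raises(ValueError):
            simulate_competition(males, females, default_cfg)


def test_write_dataset_reproducible_bytes(tmp_path):
    cfg = TruthConfig(n_males_per_ecotype=2, seed=9)
    a, b = tmp_path / "a", tmp_path / "b"
    write_dataset(cfg, a, n_subsamples=1, n_tracks=2)
    write_dataset(cfg, b, n_subsamples=1, n_tracks=2)
    for name in ("males.csv", "females.csv", "trials.csv", "genotypes.csv", "truth.json"):
        assert (a / name).read_bytes() == (b / name).read_bytes()
    assert (a / "trajectories" / "LF01_1.csv").read_bytes() == (
        b / "trajectories" / "LF01_1.csv"
    ).read_bytes()
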