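import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from spermcomp.glmm import build_design
from spermcomp.paternity import tally_trials
from spermcomp.synthetic import (
    TruthConfig,
    make_females,
    simulate_competition,
    simulate_males,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


def pair_speed_table(males: pd.DataFrame) -> pd.DataFrame:
    """True VAPs of the i-th LF / i-th LP male as the pair's speed covariates."""
    lf = males[males.ecotype == "LF"].reset_index(drop=True)
    lp = males[males.ecotype == "LP"].reset_index(drop=True)
    return pd.DataFrame(
        {
            "pair_id": [f"P{i + 1:02d}" for i in range(len(lf))],
            "vap_lf": lf.vap_true.to_numpy(),
            "vap_lp": lp.vap_true.to_numpy(),
        }
    )


def simulate_study(cfg: TruthConfig):
    """Males, females, trials, genotypes, tallies and the model design."""
    males = simulate_males(cfg)
    females = make_females(cfg)
    trials, genotypes = simulate_competition(males, females, cfg)
    tallies = tally_trials(
        genotypes, trials, dict(zip(females.female_id, females.genotype))
    )
    data = build_design(tallies, pair_speed_table(males))
    return males, females, trials, genotypes, tallies, data


@pytest.fixture(scope="session")
def default_cfg() -> TruthConfig:
    return TruthConfig(seed=11)


@pytest.fixture(scope="session")
def study(default_cfg):
    return simulate_study(default_cfg)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
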