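"""Sire assignment from a diagnostic biallelic locus and per-trial tallies.

The two ecotypes are fixed for alternative alleles at one diagnostic locus
(diagLpf): river lamprey (LF) individuals are *ff*, brook lamprey (LP) are
*pp*, and F1 hybrids are *pf*. With a homozygous mother of known genotype,
each offspring genotype identifies the sire's ecotype uniquely:

=============  ==========  ====
mother         offspring   sire
=============  ==========  ====
ff (LF female) ff          LF
ff (LF female) pf          LP
pp (LP female) pp          LP
pp (LP female) pf          LF
=============  ==========  ====

The remaining combinations (ff mother with pp offspring, or vice versa) are
Mendelian violations: the larva is flagged, logged and excluded from both the
numerator and denominator of the trial tally rather than aborting the run,
since real genotyping has dropouts and miscalls.

A trial tally records C (larvae sired by the LP male) out of N assignable
larvae; trials with zero assignable larvae are excluded, mirroring the
exclusion of a failed fertilization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "GENOTYPES",
    "GenotypeCall",
    "TrialTally",
    "MendelianViolationError",
    "assign_sire",
    "tally",
    "tally_trials",
]

logger = logging.getLogger(__name__)

GENOTYPES = ("ff", "pp", "pf")
LOCUS = "diagLpf"


class MendelianViolationError(ValueError):
    """Offspring genotype impossible given a homozygous mother."""


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    genotype: str
    locus: str = LOCUS

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"genotype must be one of {GENOTYPES}, got {self.genotype!r}")


@dataclass(frozen=True)
class TrialTally:
    """C of N genotyped larvae in one competitive trial sired by the LP male."""

    trial_id: str
    experiment: str
    female_ecotype: str
    c_lp: int
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.c_lp <= self.n:
            raise ValueError(f"need 0 <= C <= N, got C={self.c_lp}, N={self.n}")


def assign_sire(mother_genotype: str, offspring: GenotypeCall) -> str:
    """Sire ecotype ('LF' or 'LP') implied by mother and offspring genotypes."""
    if mother_genotype not in ("ff", "pp"):
        raise ValueError(
            f"mother must be homozygous ('ff' or 'pp'), got {mother_genotype!r}"
        )
    g = offspring.genotype
    if g == "pf":
        return "LP" if mother_genotype == "ff" else "LF"
    if g == mother_genotype:
        return "LF" if mother_genotype == "ff" else "LP"
    raise MendelianViolationError(
        f"larva {offspring.sample_id!r}: genotype {g!r} impossible with "
        f"{mother_genotype!r} mother"
    )


def tally(
    larvae: Iterable[GenotypeCall],
    mother_genotype: str,
    trial_id: str,
    experiment: str,
    female_ecotype: str,
) -> TrialTally:
    """Tally one trial: C = LP-sired larvae, N = assignable larvae.

    Mendelian violations are excluded from C and N and logged.
    """
    c = n = violations = 0
    for larva in larvae:
        try:
            sire = assign_sire(mother_genotype, larva)
        except MendelianViolationError as err:
            violations += 1
            logger.warning("trial %s: excluded larva (%s)", trial_id, err)
            continue
        n += 1
        c += sire == "LP"
    if n == 0:
        raise ValueError(f"trial {trial_id!r}: no assignable larvae; trial excluded")
    if violations:
        logger.info("trial %s: %d Mendelian violation(s) excluded", trial_id, violations)
    return TrialTally(trial_id, experiment, female_ecotype, c, n)


def tally_trials(
    genotypes: pd.DataFrame,
    trials: pd.DataFrame,
    mother_genotypes: Mapping[str, str],
) -> pd.DataFrame:
    """Tally every trial of a competition experiment.

    Parameters
    ----------
    genotypes : DataFrame with columns trial_id, larva_id, genotype.
    trials : DataFrame with columns trial_id, pair_id, female_id, female_ecotype,
        experiment (one row per trial; trials absent from ``genotypes`` — e.g.
        failed fertilizations with no larvae — are dropped).
    mother_genotypes : mapping female_id -> 'ff' | 'pp'.

    Returns
    -------
    DataFrame with one row per retained trial: trial_id, pair_id, female_id,
    female_ecotype, experiment, c_lp, n.
    """
    by_trial = dict(tuple(genotypes.groupby("trial_id", sort=False)))
    rows = []
    for t in trials.itertuples(index=False):
        calls_df = by_trial.get(t.trial_id)
        if calls_df is None or len(calls_df) == 0:
            logger.info("trial %s: no genotyped larvae; excluded", t.trial_id)
            continue
        calls = [
            GenotypeCall(str(r.larva_id), str(r.genotype))
            for r in calls_df.itertuples(index=False)
        ]
        tt = tally(
            calls,
            mother_genotypes[t.female_id],
            str(t.trial_id),
            str(t.experiment),
            str(t.female_ecotype),
        )
        rows.append(
            {
                "trial_id": tt.trial_id,
                "pair_id": t.pair_id,
                "female_id": t.female_id,
                "female_ecotype": tt.female_ecotype,
                "experiment": tt.experiment,
                "c_lp": tt.c_lp,
                "n": tt.n,
            }
        )
    return pd.DataFrame(rows)
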