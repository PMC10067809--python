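# Methods

This note documents the models, conventions and numerical choices behind
`spermcomp`, and what the synthetic-data generator does and does not emulate.

## Study system and data model

The package analyzes paired-male sperm-competition experiments between two
lamprey ecotypes: the anadromous, parasitic river lamprey (*Lampetra
fluviatilis*, "LF") and the freshwater-resident, nonparasitic brook lamprey
(*L. planeri*, "LP"). In each competitive trial, semen from one LF and one LP
male is mixed over a batch of eggs from a single female; larvae are later
genotyped at a diagnostic biallelic locus (diagLpf; LF fixed for allele *f*,
LP for *p*, hybrids *pf*) and the number of LP-sired larvae C out of N
genotyped is the response. Two mixing designs are crossed with female
ecotype: `equal_volume` (3 µL + 3 µL semen) and `equal_number` (volumes
inversely proportional to each male's sperm concentration within a 6 µL
total), so sperm-number effects can be separated from sperm-velocity effects.

## Sperm kinematics

- **VCL** (curvilinear velocity): summed Euclidean distance between
  successive tracked head positions divided by elapsed time. Frame numbers
  may skip; elapsed time is the frame span divided by the frame rate
  (default 60 frames/s, 3 s recordings, hence 180-point tracks).
- **VAP** (average-path velocity): the same quotient computed on the
  centered moving-average-smoothed positions. The smoothing window defaults
  to 5 points (common CASA practice at 60 frames/s; the true instrument
  setting is instrument-specific, so it is configurable). At track ends the
  window shrinks symmetrically, which keeps the smoothed track the same
  length without fabricating positions and makes VAP equal VCL exactly on
  straight tracks. Every smoothed displacement is a convex combination of
  raw steps, so VAP ≤ VCL holds for every track and window.
- Tracks shorter than 30 points are excluded from subsample summaries
  (configurable); speeds are averaged per subsample, and a male's trait is
  the unweighted mean of its (by design three) subsample means — not the
  pooled per-track mean, so subsamples with more tracked cells do not get
  extra weight.

## Quantification and mixing design

Concentration is cells counted / chamber volume × dilution factor, averaged
over replicate chamber loads; chamber volume is an explicit input because
hemocytometer geometries differ. Total sperm per male is GSI × body mass
(gonad mass in g, converted to semen volume at 1 g/mL) × concentration,
with literature gonadosomatic indices as defaults (LF 4.64%, LP 11.9%). The
interpretation that GSI × body mass stands in for strippable semen volume is
an approximation; it ignores within-season sperm regeneration. Equal-number
volumes solve v_LF·c_LF = v_LP·c_LP, v_LF + v_LP = 6 µL in closed form.

## Paternity

With a homozygous mother, each offspring genotype determines the sire
ecotype uniquely (ff mother: ff→LF, pf→LP; pp mother: pp→LP, pf→LF).
Impossible genotypes (ff mother with pp larva or vice versa) are treated as
genotyping errors: logged and excluded from both C and N rather than fatal.
Trials with zero assignable larvae are dropped, mirroring the exclusion of a
failed fertilization.

## The hierarchical siring model

For trial i:

    C_i ~ Binomial(N_i, p_i)
    logit(p_i) = α0 + α1·femaleLP_i + α2·equalNumber_i
               + α3·vsLP_i + α4·vsLF_i
               + α5·equalNumber_i·vsLP_i + α6·equalNumber_i·vsLF_i
               + b_female(i) + b_pair(i)

Design coding is 0/1 dummies with LF female and equal-volume as the
reference cell, so a negative α2 means the LP male's share falls when sperm
numbers are equalized. vsLP and vsLF are the two males' VAPs standardized to
zero mean and unit sample SD (n−1 denominator) across the analyzed trials,
each ecotype separately, both experiments pooled. b_female and b_pair are
crossed Gaussian random intercepts.

**Priors.** Fixed effects: Student-t(0, 2.5, df 1) = Cauchy(0, 2.5), the
standard weakly-informative choice for logistic coefficients; scale and df
are configurable. Random effects: N(0, sd²) with half-Cauchy(0, 2.5)
hyperpriors on both SDs.

**Sampler.** Adaptive random-walk Metropolis-within-Gibbs, written for this
package (numba-compiled hot loop; a plain-numpy `log_posterior` with every
term explicit is the reference density it is tested against). Each scalar
parameter gets a Gaussian proposal; SDs are sampled on the log scale with
the Jacobian correction. Step sizes adapt every 50 iterations toward 0.44
acceptance during burn-in only, so retained draws come from a
time-homogeneous chain. Chains initialize at zero fixed/random effects and
sd = 0.5, and are seeded as (seed·1000003 + chain) mod 2³¹ — identical
seeds reproduce draws bitwise. The default specification is 4 chains ×
200,000 iterations, 100,000 burn-in, thinning 10; desk-scale work in the
tests and the acceptance script uses 4 × 20,000 / 10,000 / thin 5 (and
4 × 260,000 / 10,000 / thin 10 for the single-parameter quadrature
comparison), sizes at which every convergence check below is already
comfortably satisfied.

**Diagnostics and derived statistics.**

- R̂ (potential scale reduction): sqrt(((n−1)/n·W + B/n)/W) over ≥2 chains;
  zero within-chain variance yields NaN with a warning. <1.1 is taken as
  converged.
- MCMC p-value: twice the fraction of draws whose sign opposes the
  posterior-mean sign, capped at 1 (two-tailed); or the fraction of positive
  draws (one-tailed, used for the speed-by-experiment interactions, whose
  hypothesis — faster LF sperm raise LF siring success at equal numbers —
  is directional). Tie-breaks: draws equal to zero count with the mean's
  sign; a posterior that is a point mass at zero returns 1 (no departure).
- Bayesian (posterior-predictive) p-value: per retained draw, replicate
  counts are simulated from the fitted binomial probabilities and the
  discrepancy D = Σ (C_i − N_i p_i)²/(N_i p_i(1−p_i)) is compared between
  replicate and observed data; p = fraction of draws with D_rep > D_obs.
  Variances are floored at 1e-12; draws are evenly thinned to ≤4000 for the
  simulation by default.
- Δ statistic: for each female-ecotype × experiment cell, the model-implied
  LP-siring probability per draw from the fixed effects alone (scaled speeds
  at their mean 0, random effects at 0) and Δ = 0.5 − p, with a two-tailed
  MCMC p-value per cell. Evaluating at the design cell rather than averaging
  over observed trials is a deliberate reading of "overall siring success";
  it answers the question at an average-speed pairing.

Noncompetitive fertilization-success and embryo-viability counts can be fit
with the same engine (binomial likelihood, one fixed effect, female random
intercept); no separate quasibinomial machinery is provided.

## Classical trait comparisons

Sperm counts are right-skewed, so concentration and total-sperm comparisons
use the Mann–Whitney test; velocities use t-tests (pooled-variance Student
by default, giving df 24 at 13 + 13 males; Welch available). W is the count
of (LF, LP) pairs with the LF value larger, plus half the ties — the first
group is LF by convention. p-values are exact by enumeration for untied
groups of ≤10, otherwise normal with tie and continuity corrections (scipy
backs both paths; the exact path is verified against full enumeration in
the tests). No automatic test picker: the caller chooses the test.

## Synthetic-data generator

The generator is the test bed: it produces every pipeline input under a
known truth.

- **Males.** 13 per ecotype. Concentrations are lognormal around ecotype
  medians (defaults: LF 3.8×10⁸/mL, LP 7.6×10⁸/mL — LP about twice LF — with
  CV 0.45); lognormality is a modeling choice (positive support, right skew
  typical of count-derived concentrations). Speeds are Gaussian around
  ecotype means (VCL 353.2 / 321.6 µm/s, VAP 262 / 221 µm/s for LF / LP,
  between-male SD 45 µm/s) with a single per-male motility deviation scaled
  proportionally into VAP so VAP ≤ VCL always. Body masses (lognormal;
  LF 50 g, LP 8.5 g, CV 0.15) are set so GSI-based total sperm is similar
  between ecotypes (≈9×10⁸ vs ≈8×10⁸), i.e. the higher LP concentration
  roughly compensates its smaller body and the total-sperm comparison is
  expected nonsignificant.
- **Trajectories.** Correlated random walks: constant step length VCL/fps
  (so measured VCL is exact), Gaussian heading increments with SD σ chosen
  in closed form from the target VAP/VCL ratio. Successive steps decorrelate
  as ρ^lag with ρ = exp(−σ²/2), and the w-point moving-average path travels
  at an expected fraction sqrt(Σ_{j,k<w} ρ^|j−k|)/w of VCL; this is solved
  for ρ by bisection. The closed form uses the root-mean-square rather than
  mean smoothed step, a small (<5% at default settings) negative bias in
  recovered VAP that the recovery tests bound at 10%. Ratios below 1/√w are
  unreachable at window w and are clamped.
- **Trials.** 13 pairs × 2 experiments × 2 female ecotypes, with 3 LF and 6
  LP females cycling over pairs. C ~ Binomial(N, p) with logit(p) from the
  model above at the configured truth (defaults: α = (0.26, −0.04, −0.70,
  −0.18, 0.13, 0.21, −0.83), random-effect SDs 0.3; speeds entering the
  truth are the pairs' true VAPs scaled across pairs). By default one pair's
  equal-number trials fail (N = 0) and one equal-number trial has 22 instead
  of 27 larvae, exercising the exclusion rules; the retained design is then
  50 trials and 49×27 + 22 = 1345 genotyped larvae. Genotypes follow Mendel
  given mother genotype and sire ecotype.
- **Not emulated:** video imaging noise, track fragmentation and drift;
  within-season variation in semen quality; egg-batch size variation and
  embryo mortality beyond the binomial thinning; genotyping error (the
  Mendelian-violation path is exercised only by explicit test injection).
  Passing recovery tests on these data therefore demonstrates correctness of
  the estimators under the assumed generating process, not robustness to
  those real-data artifacts.

## Numerical choices

- log(1+e^x) is computed piecewise (linear above 35, e^x below −35) to avoid
  overflow; binomial normalizing constants are included in the public
  density and cached per dataset.
- Proposal steps are clipped to [1e-4, 10]; initialization is checked for a
  finite posterior before sampling.
- The speed covariates are standardized over analyzed trials (not pairs), so
  pairs appearing in more retained trials weigh more in the standardization;
  with the default design the difference is negligible.
- JSON reports are timestamp-free and key-sorted; fixed seeds reproduce
  every output file byte-identically.

## Known limitations

- The posterior-predictive p-value with the Pearson-χ² discrepancy is only
  mildly conservative for this design: because the crossed random effects
  let the model track the data closely, its sampling distribution under a
  well-specified generator is wide (a 60-replicate calibration experiment at
  the default design gives mean 0.47, SD 0.22, with about two thirds of
  replicates in [0.3, 0.7]). Single p-values should be read as a rough
  adequacy signal, not a calibrated test.
- The Metropolis-within-Gibbs sampler is adequate for this model's size but
  mixes slowly for strongly correlated posteriors; effective sample sizes,
  not raw draw counts, should guide chain lengths for derived quantities.
- VAP depends on the smoothing window, which is instrument-specific; results
  quoted without the window setting are not comparable across instruments.
- The GSI-based total-sperm estimate inherits the 1 g/mL density assumption
  and literature GSI values; it is a coarse ranking tool, not a measurement.
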