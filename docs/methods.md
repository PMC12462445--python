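# Methods

## Scope and shape

`prsmed` covers the analysis chain linking a polygenic liability to a
disease outcome through a clinical mediator in an admixed, survey-sampled
cohort: PRS construction/combination, survey-weighted GLM association,
quasi-Bayesian causal mediation, and two-sample (multivariable) Mendelian
randomization, plus a generative module that produces all inputs with
known ground truth. The public surface follows the Model/Results idiom:
`SurveyGLM(...).fit() -> SurveyGLMResults`, `MediationModel(...).fit() ->
MediationResults`, `MRModel(harmonized).fit(method) -> MRResults`, each
with a `summary()` table; module-level functions expose the individual
operations.

## The synthetic cohort generator

The generator emulates a three-ancestry admixed community cohort with a
multi-stage survey design. It is the reference experiment for every
estimator, so its defaults are fixed, documented conditions — not tuning
knobs.

**Genetics.** Per-variant ancestral allele frequencies follow a
Balding-Nichols construction: a shared base frequency `p0 ~ U(0.1, 0.9)`
and per-ancestry frequencies `Beta(p0(1-F)/F, (1-p0)(1-F)/F)` with
divergence `F = 0.1`. Individual ancestry proportions are
`Dirichlet(3.0, 0.5, 1.5)` over (EUR, AFR, AMR), giving mean proportions
of roughly 60/10/30% as in US Hispanic/Latino cohorts. Dosages are
`Binomial(2, Σ_a q_ia f_am)` — distributionally identical to drawing each
allele copy by first sampling an ancestry from the individual's
proportions and then an allele from that ancestry's frequency. True
per-allele effects are `N(0, 0.05²)`; the latent genetic score
`G = Σ_m dosage·β_m` is standardized within the cohort. The three
ancestry weight tables are the true effects plus `N(0, 0.02²)` noise,
with per-ancestry EAF and imputation-quality columns.

**Covariates and design.** Age `N(41.5, 15.05²)` truncated to 18–76, 50.9%
female, BMI `N(29.4, 6.13²)`, four field centers. PCs 1–2 are noisy linear
images of the ancestry proportions. Survey weights are inverse sampling
probabilities over age-band × center strata (older strata oversampled);
follow-up weights divide by an age-dependent retention probability.

**Sleep.** `log1p(REI)` is Gaussian: intercept 1.09, 0.12 per SD of G,
0.06 per BMI unit, 0.03 per year of age (centered covariates), residual SD
1.4, with 11% missingness. The intercept/SD pair places the OSA category
shares near 61/17/10% of the cohort (none/mild/moderate-severe, REI cut
points 5 and 15) with ~11% unclassified; the G coefficient corresponds to
a mild-to-severe OSA odds ratio of ≈1.15 per SD. WHIIRS/ESS scores and
bed/wake clock times are generated so the secondary sleep phenotypes
exercise their thresholds.

**Diabetes.** Prevalent diabetes at baseline is logistic with log-OR 0.98
(= log 2.67) per SD of G, 0.06 per BMI unit, 0.03 per year; the intercept
(-2.2) yields ≈15% prevalence, and 36.6%/48.4% hyperglycemic/normal among
the rest. Incident events among the non-diabetic are Poisson with log-rate
intercept -4.5 (per person-year), log 2.0 per SD of G, log 1.3 for
mild-to-severe OSA, 0.05 per BMI unit, 0.01 per year, with individual
follow-up `N(6, 0.7²)` years as exposure — about 8% cumulative incidence.
Laboratory values (fasting glucose, medication flags) are then generated
consistently with the intended classes so the ADA classifier is exercised
end to end; configs whose incidence rate would exceed 1/year are rejected.

**What the generator does not emulate.** No LD beyond independent
variants (an explicit r² matrix drives clumping tests instead), no
relatedness, no PSU/stratum variance components (weights-only design), no
item nonresponse except in REI, and visit-2 status changes only through
the incident-event channel. Passing tests therefore demonstrate estimator
correctness under the stated model, not robustness to those real-data
features.

**Ground truth.** `oracle_truths` evaluates the counterfactual mediation
quantities by Monte Carlo: it draws covariates and G, removes prevalent
cases (so the estimand matches the at-risk analysis population), and uses
the closed-form mediator law (probit probability that log1p-REI exceeds
log 6) and outcome mixture `λ·(p·e^{η_m} + 1 - p)·t̄` to compute ACME,
total effect, and their ratio. It is deterministic given the seed; the
default contrast is the 25th vs 75th percentile of the score (∓0.6745).

## Two-sample GWAS generator

True exposure effects are half-normal `|N(0, 0.03²)|` — effect alleles are
oriented exposure-increasing, the convention under which directional
pleiotropy has a well-defined sign. Observed betas add sampling noise of
SE `1/sqrt(2·n·eaf(1-eaf))` per study (n = 200,000 each by default);
outcome betas are `θ·β_X + α + noise` with `α ~ N(μ_α, σ_α²)`. A third of
the outcome rows are stored with swapped alleles so harmonization is
exercised on every run.

## Survey GLM

The weighted pseudo-likelihood `Σ w_i ℓ_i(β)` is maximized by statsmodels
GLM with `var_weights`; the reported covariance is the weights-only
sandwich `A⁻¹BA⁻¹` with `A` the weighted Hessian and `B = Σ w_i² s_i s_iᵀ`
(identical to statsmodels' HC0 under `var_weights`, an identity kept under
test against the explicit formula). Stratum/PSU design components are
deliberately out of scope: the sampling design enters through weights
only, a documented limitation. Inference is 1-df Wald with normal
reference; `exp(β)` with `exp(β ± 1.96·se)` CIs is reported as OR (logistic)
or IRR (Poisson). Estimates and robust SEs are invariant to rescaling all
weights. The incident-disease AUC uses repeated 90/10 train/test splits
(default 500), fitting with survey weights on the training fold and
computing the unweighted AUC of predicted risk on the test fold — for
the Poisson model the risk is the event probability `1 - exp(-rate·t)`.
Degenerate splits (one outcome class in a fold) are redrawn up to 10
times, then discarded with a log message. The 95% CI is the 2.5/97.5
percentile of the split AUCs.

## Mediation

The estimator is the quasi-Bayesian counterfactual algorithm: draw both
model parameter vectors from `N(θ̂, V̂)`, and per draw compute each
individual's potential-outcome expected counts. One deliberate deviation
from simulation-based reference implementations: instead of sampling
Bernoulli mediators and Poisson outcomes, the mediator's conditional
distribution is plugged into the outcome rate analytically — a two-point
mixture `p·e^{β_m} + (1-p)` for a binary mediator, the lognormal moment
`exp(β_m·m̄ + β_m²σ̂²/2)` for a Gaussian one. This removes a Monte-Carlo
layer (verified in tests against a brute-force simulation oracle) and
makes ACME + ADE = total exact within each draw. Effects are reported on
the expected-count scale averaged over the survey-weighted covariate
distribution of the at-risk sample — weights enter both the model fits
and the averaging, since the estimand targets the survey population.
ACME and ADE average the two exposure arms (the arm convention is recorded
in the result). Point estimates are medians over draws, CIs are
percentile, p-values are two-sided Monte-Carlo sign tests, and the
proportion mediated is the per-draw ratio ACME/total summarized by its
median — flagged as unreliable when the total effect is indistinguishable
from zero. Quantile-contrast grids evaluate all C(5,2) = 10 ordered pairs
of the (0, .25, .5, .75, 1) exposure quantiles; degenerate contrasts
(equal cut points) are skipped. No exposure–mediator interaction terms are
modeled, and sensitivity analysis to sequential-ignorability violations is
out of scope.

## Mendelian randomization

Harmonization matches SNPs by id, flips swapped allele pairs (negating
the other study's beta, complementing strand representations where
needed), and handles palindromic A/T–C/G SNPs by frequency: dropped when
`min(eaf, 1-eaf) > 0.42` (a configurable, conventional threshold) or when
frequency is missing, otherwise oriented by which side of 0.5 the two
studies' frequencies fall on. Instrument selection intersects exposure
and outcome SNPs, filters at the exposure p-value threshold, restricts to
MAF > 0.01, and greedily clumps by ascending p (ties broken toward the
lower genomic position, for determinism) with r² ≤ 0.001 within 10,000 kb
against a user-supplied LD matrix — absent pairs are treated as unlinked;
no remote reference panels are fetched.

Estimators: IVW is the origin-constrained WLS with weights `1/se_Y²`;
the multiplicative random-effects SE multiplies the fixed-effect SE by
`max(1, sqrt(Q/(k-1)))` — the inflation never shrinks it. MR-Egger adds an
intercept after re-orienting exposure betas positive, inflating both SEs
by `max(1, residual SD)`. The weighted median interpolates the
inverse-variance-weighted 50th percentile of the Wald ratios with
parametric-bootstrap SEs; the mode estimators maximize a
Silverman-bandwidth Gaussian kernel density of the ratios. MR-RAPS
maximizes the profile likelihood `-½ Σ (β_Yj - b·β_Xj)²/(se_Yj² +
b²·se_Xj²)` (optionally with an additive overdispersion component whose
log-determinant term keeps it finite), with SE from the observed
information. MR-PRESSO computes the observed RSS from leave-one-out IVW
predictions, simulates the null RSS distribution parametrically around the
leave-one-out fits (10,000 draws by default; the global p is floored at
1/n_dist), and flags outliers by Bonferroni-corrected per-SNP tails —
the per-SNP test is not gated on the global test, and the distortion test
is omitted. MVMR-IVW regresses outcome betas jointly on two exposures'
betas without intercept, raising a condition-number error on collinear
exposures; only the focal exposure's estimate is surfaced in reports.
All estimators are invariant to SNP order and to joint allele recoding.

## Numerical and design choices

* Standardization uses unweighted sample moments with `ddof=1`; a
  survey-weighted variant was rejected because the scores are defined
  "in the dataset", not in the target population.
* Variants absent from the dosage matrix are skipped with a logged count
  (no frequency imputation); zero overlap is an error.
* Negative external-regression combination weights are used as-is.
* Quantile bin ties go to the lower bin; REI exactly 15 is
  moderate-severe so the categories partition.
* Bed/wake durations are computed modulo 24 h with a 3–20 h plausibility
  window; outside it the sleep phenotypes are missing.
* Diabetes "missing" policy: labs absent with an explicit no-medication
  record counts as normoglycemic; labs and medication information all
  absent is missing.
* All randomness flows through `numpy.random.default_rng` seeded per call;
  repeated runs are bit-identical.

## Problem sizes

The shipped experiments use a 5,000-person cohort with 200 variants,
10-instrument GWAS simulations at 200,000 samples per study, 1,000
quasi-Bayesian draws, 100–200 replicates for operating-characteristic
checks, and 10,000 MR-PRESSO null draws — sizes at which every
recovery check resolves its target while the full suite runs in minutes
on a single CPU.

## Known limitations

Weights-only variance (no PSU/strata), no finite-population corrections or
weight calibration; mediation assumes sequential ignorability and no
exposure–mediator interaction; MR-PRESSO omits the distortion test; LD
handling is limited to a supplied r² matrix; the generator's simplifications
listed above. The external-regression combination weights are treated as
frozen inputs rather than re-estimated per target cohort.
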