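# prsmed

Multi-ancestry polygenic risk scores, survey-weighted association, causal
mediation, and two-sample Mendelian randomization — an integrated toolkit
for studying how a genetic liability (e.g. type-2 diabetes risk) relates to
a clinical mediator (e.g. obstructive sleep apnea) in admixed,
survey-sampled cohorts.

## The scientific problem

Admixed populations — such as Hispanic/Latino communities whose genomes mix
European (EUR), African (AFR), and Amerindian (AMR) ancestry segments — are
poorly served by polygenic risk scores (PRS) trained in single-ancestry
GWAS. A practical remedy is to build one PRS per ancestry and combine them.
Given ancestry-specific standardized scores `z_EUR, z_AFR, z_AMR`, the
package implements three combinations, each re-standardized to mean 0 / SD 1:

* **PRSsum** — the unweighted sum `Σ_a z_a`;
* **gapPRSsum** — the per-individual weighted sum `Σ_a q_ia z_ia` where
  `q_ia` are the individual's estimated global ancestry proportions;
* **mgbPRSsum** — `Σ_a w_a z_ia` with a single weight per ancestry, taken
  from the coefficients of a logistic regression of disease on the three
  scores (plus age, sex, genetic PCs) in an external biobank cohort.

Downstream, the toolkit estimates (all with survey weights and the
weights-only sandwich covariance `A⁻¹BA⁻¹`, `B = Σ w_i² s_i s_iᵀ`):

* **prevalence association** — survey logistic regression, OR per SD of PRS;
* **incidence association** — survey Poisson regression with a log
  follow-up-time offset, IRR per SD; stratified and interaction analyses by
  OSA severity (REI < 5 none, 5 ≤ REI < 15 mild, REI ≥ 15 moderate-severe);
* **mediation** — quasi-Bayesian counterfactual mediation of the PRS effect
  on incident disease through OSA: ACME, ADE, total effect, and proportion
  mediated at PRS-quantile contrasts;
* **Mendelian randomization** — the two-sample estimator family on
  harmonized GWAS summary statistics: IVW (multiplicative random effects),
  MR-Egger, weighted median, simple/weighted mode, MR-RAPS, MR-PRESSO
  outlier detection, and multivariable MVMR-IVW, with instrument selection
  (p < 5e-8, greedy clumping at r² ≤ 0.001 within 10,000 kb) and allele
  harmonization (strand correction, palindromic-SNP handling).

Because the cohort data this kind of study uses are access-restricted, the
package ships a first-class synthetic-data module: an admixed cohort with a
known genetic-score → OSA → incident-diabetes causal chain, survey weights,
and two-sample GWAS tables with a known causal effect — so every stage is
testable against ground truth.

## Worked example

```python
import numpy as np
from prsmed import (CohortSimConfig, simulate_admixed_cohort, SurveyGLM,
                    MediationModel)
from prsmed.phenotypes import add_derived_phenotypes

sim = simulate_admixed_cohort(CohortSimConfig(seed=1))          # n = 5000
cohort = add_derived_phenotypes(sim.cohort)
cohort["dm_v1"] = (cohort["dm_status_v1"] == "diabetic").astype(float)
covs = ["age", "sex", "bmi", "pc1", "pc2", "pc3", "pc4", "pc5"]

fit = SurveyGLM(cohort["dm_v1"], cohort[["true_g"] + covs],
                cohort["weight_v1"], family="logistic").fit()
print(fit.summary().loc["true_g", ["OR", "OR_ci_low", "OR_ci_high", "p"]])

at_risk = cohort[cohort["incident_dm_count"].notna()].dropna(
    subset=["osa_mild_severe"]).copy()
at_risk["osa_mild_severe"] = at_risk["osa_mild_severe"].astype(float)
med = MediationModel(at_risk, "true_g", "osa_mild_severe",
                     "incident_dm_count", covs, "weight_v2", "followup_years")
print(med.fit(n_draws=1000, seed=1).summary().round(4))
print("oracle proportion mediated:", round(sim.truth.true_prop_mediated, 4))
```

Output:

```
OR            2.745007e+00
OR_ci_low     2.475934e+00
OR_ci_high    3.043322e+00
p             5.031040e-82

               estimate  ci_low  ci_high      p signif
effect
ACME             0.0011  0.0001   0.0026  0.026      *
ADE              0.0768  0.0644   0.0913    NaN
total            0.0782  0.0655   0.0925  0.002     **
prop_mediated    0.0141  0.0016   0.0327  0.026      *
oracle proportion mediated: 0.0123
```

The survey-logistic fit recovers the generative odds ratio of 2.67 per SD
of the true genetic score (the generator's default prevalence effect), and
the mediation estimator attributes ~1.4% (CI 0.2–3.3%) of the PRS effect on
incident diabetes to the OSA pathway, covering the Monte-Carlo oracle value
of 1.2% computed directly from the generative model. Effects are on the
expected incident-count scale, so ACME + ADE = total holds exactly within
every quasi-Bayesian draw.

A command-line interface wraps the same operations:

```bash
prsmed simulate --n 5000 --seed 1 --out sim/
prsmed score --dosages sim/dosages.tsv --weights sim/weights_EUR.tsv
prsmed mr --exposure exp.tsv --outcome out.tsv --methods ivw,egger,median,raps
prsmed pipeline --seed 1 --out-dir run1
```

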