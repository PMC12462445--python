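"""Synthetic admixed cohorts and two-sample GWAS with known ground truth.

The cohort generator emulates a three-way admixed (EUR/AFR/AMR)
population-based survey cohort with a genetic-score -> obstructive sleep
apnea -> incident diabetes causal chain:

* individual ancestry proportions are Dirichlet; each variant's allele
  frequencies diverge across ancestries Balding-Nichols style and dosages
  are binomial in the individual's mixture frequency;
* a true per-allele effect vector defines the latent genetic score G
  (standardized within the cohort);
* log1p(REI) is Gaussian around a linear predictor in (G, BMI, age), and
  OSA categories follow from the usual 5/15 events/hour thresholds;
* incident diabetes counts are Poisson with a log-rate linear in
  (G, OSA, BMI, age) and a follow-up-time offset;
* three ancestry-specific variant weight tables are noisy estimates of the
  true effects, and survey weights are inverse sampling probabilities over
  age x field-center strata.

Marginal summaries are calibrated to a Hispanic/Latino community cohort:
about 51% female, age 41.5 (SD 15), BMI 29.4 (SD 6.1), OSA category
shares roughly 61/17/10% (with ~11% unclassified), ~15% prevalent
diabetes, ~8% incident diabetes over an average six-year follow-up.

``simulate_two_sample_gwas`` produces exposure/outcome summary-statistic
tables with a known causal effect and optional (directional) pleiotropy
for exercising the MR estimators.  ``oracle_truths`` evaluates the
counterfactual mediation quantities of the generative model by Monte
Carlo and is the reference the mediation estimator is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .prs import DosageMatrix

__all__ = [
    "CohortSimConfig", "GwasSimConfig", "TruthRecord", "SimulatedCohort",
    "simulate_admixed_cohort", "simulate_two_sample_gwas", "oracle_truths",
]

_CENTERS = ("bronx", "chicago", "miami", "san_diego")
_LOG6 = float(np.log(6.0))  # REI 5 on the log1p scale
_LOG16 = float(np.log(16.0))  # REI 15


@dataclass
class CohortSimConfig:
    """Generative settings for the admixed cohort.

    ``gamma_osa`` are (intercept, genetic score, BMI, age) coefficients on
    the log1p-REI scale (BMI/age centered); ``eta_dm`` are (intercept,
    genetic score, OSA indicator, BMI, age) on the log incident-rate scale
    (events per person-year); ``beta_dm_prev`` the analogous logistic
    coefficients (intercept, G, BMI, age) for prevalent diabetes at the
    baseline visit.  Defaults target OR ~2.67 per SD for prevalent
    diabetes, IRR ~2 per SD for incidence, OSA OR ~1.15 per SD, and an
    OSA->diabetes rate ratio of ~1.3.
    """

    n_individuals: int = 5000
    n_variants: int = 200
    ancestry_labels: tuple = ("EUR", "AFR", "AMR")
    dirichlet_alpha: tuple = (3.0, 0.5, 1.5)
    fst: float = 0.1
    effect_sd: float = 0.05
    gamma_osa: tuple = (1.09, 0.12, 0.06, 0.03)
    sigma_rei: float = 1.4
    rei_missing_frac: float = 0.11
    eta_dm: tuple = (-4.5, float(np.log(2.0)), float(np.log(1.3)), 0.05, 0.01)
    beta_dm_prev: tuple = (-2.2, float(np.log(2.67)), 0.06, 0.03)
    followup_mean_years: float = 6.0
    followup_sd_years: float = 0.7
    weight_table_noise_sd: float = 0.02
    weight_model: dict | None = None  # (age_band, center) -> sampling probability
    seed: int = 0

    def validate(self):
        if self.n_individuals <= 0 or self.n_variants < 1:
            raise ValueError("sample sizes must be positive")
        if len(self.dirichlet_alpha) != len(self.ancestry_labels):
            raise ValueError("dirichlet_alpha must match ancestry_labels")
        if any(a <= 0 for a in self.dirichlet_alpha):
            raise ValueError("dirichlet_alpha entries must be > 0")
        if self.followup_mean_years <= 0:
            raise ValueError("followup_mean_years must be > 0")
        if not (0 <= self.rei_missing_frac < 1):
            raise ValueError("rei_missing_frac must be in [0, 1)")
        # the Poisson incidence model must stay a (sub-unit) probability
        # per year in the bulk of the covariate space
        if self.eta_dm[0] > 0:
            raise ValueError("eta_dm intercept implies baseline rate > 1/year")
        return self


@dataclass
class GwasSimConfig:
    """Two-sample GWAS generator: known causal effect plus optional pleiotropy."""

    n_instruments: int = 10
    causal_theta: float = float(np.log(2.34))
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    n_exposure: int = 200_000
    n_outcome: int = 200_000
    eaf_range: tuple = (0.1, 0.9)
    beta_sd: float = 0.03
    seed: int = 0

    def validate(self):
        if self.n_instruments < 1:
            raise ValueError("n_instruments must be >= 1")
        lo, hi = self.eaf_range
        if not (0 < lo < hi < 1):
            raise ValueError("eaf_range must lie within (0, 1)")
        return self


@dataclass(eq=False)
class TruthRecord:
    """Ground-truth quantities the estimators are judged against.

    Equality is field-wise with NaN == NaN (unset slots compare equal).
    """

    def __eq__(self, other):
        if not isinstance(other, TruthRecord):
            return NotImplemented
        for f in self.__dataclass_fields__:
            a, b = getattr(self, f), getattr(other, f)
            if a != b and not (np.isnan(a) and np.isnan(b)):
                return False
        return True

    true_or_per_sd: float = float("nan")
    true_irr_per_sd: float = float("nan")
    true_prop_mediated: float = float("nan")
    true_acme: float = float("nan")
    true_total: float = float("nan")
    true_theta: float = float("nan")


@dataclass
class SimulatedCohort:
    """Bundle returned by :func:`simulate_admixed_cohort`."""

    dosages: DosageMatrix
    proportions: pd.DataFrame
    cohort: pd.DataFrame
    weight_tables: dict
    truth: TruthRecord
    ancestral_freqs: pd.DataFrame = field(repr=False, default=None)
    true_effects: pd.Series = field(repr=False, default=None)


_BANDS = ((18, 40), (40, 60), (60, 77))
_DEFAULT_SAMPLING = {}
for _bi, _band in enumerate(_BANDS):
    for _ci, _c in enumerate(_CENTERS):
        # older strata oversampled, as in multi-stage community designs
        _DEFAULT_SAMPLING[(_bi, _c)] = 0.35 - 0.08 * _bi + 0.02 * _ci


def _nonambiguous_allele_pairs(rng, m):
    pairs = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
             ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
    idx = rng.integers(0, len(pairs), size=m)
    ea = np.array([pairs[i][0] for i in idx])
    oa = np.array([pairs[i][1] for i in idx])
    return ea, oa


def _clock(rng, mean, sd, n):
    h = rng.normal(mean, sd, n) % 24
    return [f"{int(x):02d}:{int((x % 1) * 60):02d}" for x in h]


def simulate_admixed_cohort(cfg: CohortSimConfig | None = None) -> SimulatedCohort:
    """Simulate the admixed cohort; see the module docstring for the model."""
    cfg = (cfg or CohortSimConfig()).validate()
    rng = np.random.default_rng(cfg.seed)
    n, m = cfg.n_individuals, cfg.n_variants
    labels = list(cfg.ancestry_labels)
    ids = [f"ind{i:05d}" for i in range(n)]
    vids = [f"rs{100000 + j}" for j in range(m)]

    # --- genetics ----------------------------------------------------------
    base = rng.uniform(0.1, 0.9, m)
    a = base * (1 - cfg.fst) / cfg.fst
    b = (1 - base) * (1 - cfg.fst) / cfg.fst
    freqs = pd.DataFrame(
        {anc: np.clip(rng.beta(a, b), 0.01, 0.99) for anc in labels}, index=vids
    )
    props = pd.DataFrame(rng.dirichlet(cfg.dirichlet_alpha, size=n),
                         index=ids, columns=labels)
    mix_p = props.to_numpy() @ freqs.to_numpy().T  # n x m
    dos = rng.binomial(2, mix_p).astype(float)
    ea, oa = _nonambiguous_allele_pairs(rng, m)
    # half the dosage columns count the other allele, to exercise flipping
    flip = rng.random(m) < 0.5
    coded = np.where(flip, oa, ea)
    other = np.where(flip, ea, oa)
    stored = np.where(flip[None, :], 2.0 - dos, dos)
    dosages = DosageMatrix(
        pd.DataFrame(stored, index=ids, columns=vids),
        coded_alleles=pd.Series(coded, index=vids),
        other_alleles=pd.Series(other, index=vids),
    )

    beta = rng.normal(0.0, cfg.effect_sd, m)
    g_raw = dos @ beta
    g = (g_raw - g_raw.mean()) / g_raw.std(ddof=1)

    # --- covariates --------------------------------------------------------
    age = np.clip(rng.normal(41.51, 15.05, n), 18, 76)
    sex = (rng.random(n) < 0.509).astype(float)  # 1 = female
    bmi = np.clip(rng.normal(29.4, 6.13, n), 15, 60)
    whr = np.clip(rng.normal(0.92, 0.08, n), 0.6, 1.3)
    center = rng.choice(_CENTERS, n)
    bmi_c, age_c = bmi - 29.4, age - 41.5
    pcs = np.column_stack([
        props["EUR"] - props["AFR"] + rng.normal(0, 0.05, n),
        props["AMR"] - 1 / 3 + rng.normal(0, 0.05, n),
        rng.normal(0, 0.1, (n, 3)),
    ])

    # --- survey weights ----------------------------------------------------
    band = np.digitize(age, [b[1] for b in _BANDS[:-1]])
    sampling = cfg.weight_model or _DEFAULT_SAMPLING
    p_samp = np.array([sampling[(b_, c_)] for b_, c_ in zip(band, center)])
    weight_v1 = 1.0 / p_samp
    retention = 0.85 - 0.05 * band  # younger participants retained better
    weight_v2 = weight_v1 / retention

    # --- sleep -------------------------------------------------------------
    g0, gg, gb, ga = cfg.gamma_osa
    lp_rei = g0 + gg * g + gb * bmi_c + ga * age_c
    log1p_rei = lp_rei + rng.normal(0, cfg.sigma_rei, n)
    rei = np.expm1(np.clip(log1p_rei, None, 5.0))
    rei = np.clip(rei, 0.0, None)
    rei_missing = rng.random(n) < cfg.rei_missing_frac
    osa = (rei >= 5.0).astype(float)  # mild-to-severe indicator (truth)
    whiirs = np.clip(rng.poisson(7.0, n), 0, 20)
    ess = np.clip(rng.poisson(6.0, n), 0, 24)

    # --- diabetes ----------------------------------------------------------
    p0, pg, pb, pa = cfg.beta_dm_prev
    p_dm1 = 1.0 / (1.0 + np.exp(-(p0 + pg * g + pb * bmi_c + pa * age_c)))
    dm_v1 = rng.random(n) < p_dm1
    p_hyper = 1.0 / (1.0 + np.exp(-(-0.28 + 0.3 * g)))
    hyper_v1 = ~dm_v1 & (rng.random(n) < p_hyper)

    e0, eg, eo, eb, ea_ = cfg.eta_dm
    followup = np.clip(rng.normal(cfg.followup_mean_years, cfg.followup_sd_years, n),
                       1.0, None)
    rate = np.exp(e0 + eg * g + eo * osa + eb * bmi_c + ea_ * age_c)
    if np.any(rate > 1.0):
        raise ValueError("incidence rate exceeds 1/year for some individuals; "
                         "reduce eta_dm coefficients")
    counts = rng.poisson(rate * followup)
    incident = (counts > 0) & ~dm_v1
    dm_v2 = dm_v1 | incident

    # --- labs consistent with the intended classes -------------------------
    def _labs(dm, hyper):
        fg = np.where(dm, rng.uniform(127, 200, n),
                      np.where(hyper, rng.uniform(101, 124, n),
                               rng.uniform(80, 99, n)))
        med = dm & (rng.random(n) < 0.5)
        return fg, med

    fg1, med1 = _labs(dm_v1, hyper_v1)
    hyper_v2 = ~dm_v2 & hyper_v1
    fg2, med2 = _labs(dm_v2, hyper_v2)

    cohort = pd.DataFrame({
        "id": ids, "age": age, "sex": sex, "bmi": bmi, "whr": whr,
        "center": center,
        **{f"pc{i+1}": pcs[:, i] for i in range(5)},
        "weight_v1": weight_v1, "weight_v2": weight_v2,
        "fasting_time_h_v1": 10.0, "fasting_glucose_v1": fg1,
        "dm_med_v1": med1,
        "fasting_time_h_v2": 10.0, "fasting_glucose_v2": fg2,
        "dm_med_v2": med2,
        "rei": np.where(rei_missing, np.nan, rei),
        "whiirs": whiirs, "ess": ess,
        "bed_wd": _clock(rng, 23.0, 1.0, n), "wake_wd": _clock(rng, 6.5, 1.0, n),
        "bed_we": _clock(rng, 23.8, 1.2, n), "wake_we": _clock(rng, 7.8, 1.2, n),
        "followup_years": followup,
        "true_g": g, "true_osa": osa,
        "incident_dm_count": np.where(dm_v1, np.nan, counts.astype(float)),
    }).set_index("id")

    # --- ancestry weight tables: noisy estimates of the true effects -------
    weight_tables = {}
    for anc in labels:
        weight_tables[anc] = pd.DataFrame({
            "variant_id": vids,
            "chr": rng.integers(1, 23, m),
            "pos": rng.integers(1, 2_000_000_000, m),
            "effect_allele": ea, "other_allele": oa,
            "weight": beta + rng.normal(0, cfg.weight_table_noise_sd, m),
            "eaf": freqs[anc].to_numpy(),
            "imputation_r2": rng.uniform(0.85, 1.0, m),
        })

    truth = oracle_truths(cfg, n_mc=200_000)
    return SimulatedCohort(dosages, props, cohort, weight_tables, truth,
                           ancestral_freqs=freqs,
                           true_effects=pd.Series(beta, index=vids))


def oracle_truths(
    cfg: CohortSimConfig | None = None,
    n_mc: int = 1_000_000,
    control_value: float | None = None,
    treat_value: float | None = None,
    seed: int | None = None,
) -> TruthRecord:
    """Monte-Carlo counterfactual mediation truths of the generative model.

    Draws covariates and the genetic score from the generative
    distribution, restricts to the at-risk (no prevalent diabetes)
    population, and evaluates closed-form potential-outcome expected
    counts: the mediator distribution under an exposure value ``a`` is
    Bernoulli with the probit probability the REI model implies, and the
    expected incident count mixes the Poisson rate over that distribution.
    ACME and the total effect are averages over the two exposure arms on
    the expected-count scale; the default contrast is the 0.25 vs 0.75
    quantile of the (standard normal) score.  Deterministic given the
    seed (defaults to ``cfg.seed``).
    """
    cfg = (cfg or CohortSimConfig()).validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    cv = -stats.norm.ppf(0.75) if control_value is None else control_value
    tv = stats.norm.ppf(0.75) if treat_value is None else treat_value

    g = rng.normal(0, 1, n_mc)
    bmi_c = np.clip(rng.normal(29.4, 6.13, n_mc), 15, 60) - 29.4
    age_c = np.clip(rng.normal(41.51, 15.05, n_mc), 18, 76) - 41.5

    p0, pg, pb, pa = cfg.beta_dm_prev
    p_dm1 = 1.0 / (1.0 + np.exp(-(p0 + pg * g + pb * bmi_c + pa * age_c)))
    at_risk = rng.random(n_mc) >= p_dm1
    g, bmi_c, age_c = g[at_risk], bmi_c[at_risk], age_c[at_risk]

    g0, gg, gb, ga = cfg.gamma_osa
    e0, eg, eo, eb, ea_ = cfg.eta_dm
    t = cfg.followup_mean_years

    def p_osa(a):
        lp = g0 + gg * a + gb * bmi_c + ga * age_c
        return stats.norm.sf((_LOG6 - lp) / cfg.sigma_rei)

    def mu(a, a_mediator):
        lam0 = np.exp(e0 + eg * a + eb * bmi_c + ea_ * age_c)
        pm = p_osa(a_mediator)
        return lam0 * (pm * np.exp(eo) + (1.0 - pm)) * t

    acme = 0.5 * float(np.mean(mu(tv, tv) - mu(tv, cv)) + np.mean(mu(cv, tv) - mu(cv, cv)))
    total = float(np.mean(mu(tv, tv) - mu(cv, cv)))
    prop = acme / total if total != 0 else float("nan")
    return TruthRecord(
        true_or_per_sd=float(np.exp(pg)),
        true_irr_per_sd=float(np.exp(eg)),
        true_prop_mediated=prop,
        true_acme=acme,
        true_total=total,
        true_theta=float("nan"),
    )


def simulate_two_sample_gwas(cfg: GwasSimConfig | None = None):
    """Simulate exposure and outcome GWAS summary statistics.

    True per-SNP exposure effects ``b_j ~ N(0, beta_sd^2)`` are observed
    with sampling noise of SE ``1/sqrt(2 * n * eaf * (1 - eaf))`` in each
    study; outcome effects are ``theta * b_j + alpha_j + noise`` with the
    pleiotropy term ``alpha_j ~ N(pleiotropy_mean, pleiotropy_sd^2)``.
    Both tables share SNP ids; about a third of the outcome rows carry the
    swapped allele representation so harmonization has real work to do.
    Returns ``(exposure, outcome, TruthRecord)``.
    """
    cfg = (cfg or GwasSimConfig()).validate()
    rng = np.random.default_rng(cfg.seed)
    k = cfg.n_instruments
    snp = [f"rs{200000 + j}" for j in range(k)]
    chrom = rng.integers(1, 23, k)
    pos = rng.integers(1, 200_000_000, k)
    eaf = rng.uniform(*cfg.eaf_range, k)
    ea, oa = _nonambiguous_allele_pairs(rng, k)

    # effect alleles are oriented exposure-increasing (half-normal effects),
    # the convention under which directional pleiotropy is well defined
    b_true = np.abs(rng.normal(0, cfg.beta_sd, k))
    se_x = 1.0 / np.sqrt(2 * cfg.n_exposure * eaf * (1 - eaf))
    se_y = 1.0 / np.sqrt(2 * cfg.n_outcome * eaf * (1 - eaf))
    bx = b_true + rng.normal(0, se_x)
    alpha = rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, k)
    by = cfg.causal_theta * b_true + alpha + rng.normal(0, se_y)

    exposure = pd.DataFrame({
        "snp": snp, "chr": chrom, "pos": pos,
        "effect_allele": ea, "other_allele": oa, "eaf": eaf,
        "beta": bx, "se": se_x,
        "p": 2 * stats.norm.sf(np.abs(bx) / se_x),
        "n": cfg.n_exposure,
    })
    swap = rng.random(k) < 1 / 3
    outcome = pd.DataFrame({
        "snp": snp, "chr": chrom, "pos": pos,
        "effect_allele": np.where(swap, oa, ea),
        "other_allele": np.where(swap, ea, oa),
        "eaf": np.where(swap, 1 - eaf, eaf),
        "beta": np.where(swap, -by, by), "se": se_y,
        "p": 2 * stats.norm.sf(np.abs(by) / se_y),
        "n": cfg.n_outcome,
    })
    truth = TruthRecord(true_theta=cfg.causal_theta)
    return exposure, outcome, truth
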