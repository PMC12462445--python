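"""Quasi-Bayesian causal mediation: how much of a PRS effect flows through OSA.

The estimand follows the counterfactual mediation framework: with a
continuous exposure (a standardized PRS) contrasted at a control value
``a0`` and a treatment value ``a1``, a mediator M (binary OSA, or
continuous log-REI) and an incident-count outcome with a follow-up offset,

* ACME(a)  = E[ Y(a, M(a1)) - Y(a, M(a0)) ]
* ADE(m)   = E[ Y(a1, M(m)) - Y(a0, M(m)) ]
* total    = E[ Y(a1, M(a1)) - Y(a0, M(a0)) ]

on the expected-count scale, averaged over the (survey-weighted) observed
covariate distribution, with the two arms of ACME/ADE averaged.  The
proportion mediated is ACME/total.

Inference is quasi-Bayesian: the mediator and outcome model parameters
are drawn from the normal approximation N(theta_hat, V_hat) of their
survey-weighted fits; for each draw the potential-outcome means are
computed by plugging the mediator's conditional distribution into the
outcome rate (a two-point mixture for a binary mediator, a lognormal
moment for a Gaussian one) rather than simulating mediators and outcomes,
which removes a layer of Monte-Carlo noise.  Point estimates are medians
over draws and confidence intervals are percentile intervals, so
ACME + ADE = total holds exactly within every draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .survey import SurveyGLM, SurveyGLMResults

__all__ = ["MediationModel", "MediationResults", "fit_mediation_models",
           "estimate_mediation", "mediation_quantile_grid", "significance_code"]


def significance_code(p: float) -> str:
    """Star code: '***' < 0.001 <= '**' < 0.01 <= '*' < 0.05 <= '.' < 0.1."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "."
    return ""


def _percentile_pvalue(draws: np.ndarray) -> float:
    """Two-sided Monte-Carlo sign test of the draw distribution against 0."""
    n = len(draws)
    lo = (np.sum(draws <= 0) + 1) / (n + 1)
    hi = (np.sum(draws >= 0) + 1) / (n + 1)
    return float(min(1.0, 2.0 * min(lo, hi)))


@dataclass
class MediationResults:
    """ACME/ADE/total/proportion-mediated with percentile CIs.

    Effects are on the expected incident-count scale (rate x follow-up),
    averaged over the weighted covariate distribution; ``prop_mediated``
    is the per-draw ratio ACME/total summarized by its median.
    """

    acme: float
    ade: float
    total: float
    prop_mediated: float
    ci_level: float
    acme_ci: tuple
    ade_ci: tuple
    total_ci: tuple
    prop_ci: tuple
    acme_p: float
    total_p: float
    prop_p: float
    contrast: tuple
    n_draws: int
    arm_convention: str = "average-of-both-arms"
    draws: dict = field(default_factory=dict, repr=False)

    @property
    def prop_undefined(self) -> bool:
        return self.total_p > 0.5

    def summary(self) -> pd.DataFrame:
        rows = [
            ("ACME", self.acme, *self.acme_ci, self.acme_p),
            ("ADE", self.ade, *self.ade_ci, np.nan),
            ("total", self.total, *self.total_ci, self.total_p),
            ("prop_mediated", self.prop_mediated, *self.prop_ci, self.prop_p),
        ]
        tab = pd.DataFrame(rows, columns=["effect", "estimate", "ci_low", "ci_high", "p"])
        tab["signif"] = [significance_code(p) if np.isfinite(p) else "" for p in tab["p"]]
        return tab.set_index("effect")


class MediationModel:
    """Mediation of a continuous exposure's effect on an incident-count outcome.

    Parameters
    ----------
    data : DataFrame
        One row per at-risk individual (no prevalent disease at baseline).
    exposure_col : str
        Standardized PRS column.
    mediator_col : str
        Binary mediator (0/1, e.g. mild-to-severe OSA) or continuous
        mediator (e.g. log-REI) per ``mediator_type``.
    outcome_col : str
        Incident event count.
    covariate_cols : list of str
        Confounders entering both models (age, sex, BMI, PCs ...).
    weights_col : str
        Follow-up-visit survey weights; used in fitting and averaging.
    followup_col : str
        Follow-up time in years; log enters the outcome model as offset.
    mediator_type : {"binary", "continuous"}
    control_value, treat_value : float
        Exposure contrast (control < treat).
    """

    def __init__(self, data, exposure_col, mediator_col, outcome_col,
                 covariate_cols, weights_col, followup_col,
                 mediator_type="binary",
                 control_value=-0.6744897501960817, treat_value=0.6744897501960817):
        if not control_value < treat_value:
            raise ValueError("control_value must be < treat_value")
        if mediator_type not in ("binary", "continuous"):
            raise ValueError("mediator_type must be 'binary' or 'continuous'")
        need = [exposure_col, mediator_col, outcome_col, weights_col, followup_col] + covariate_cols
        self.data = data.dropna(subset=need).copy()
        if self.data.empty:
            raise ValueError("no complete-case rows for mediation")
        self.exposure_col = exposure_col
        self.mediator_col = mediator_col
        self.outcome_col = outcome_col
        self.covariate_cols = list(covariate_cols)
        self.weights_col = weights_col
        self.followup_col = followup_col
        self.mediator_type = mediator_type
        self.contrast = (float(control_value), float(treat_value))

    # -- component fits -----------------------------------------------------

    def fit_models(self) -> tuple[SurveyGLMResults, SurveyGLMResults]:
        """Fit the mediator and outcome survey regressions.

        Mediator: M ~ exposure + covariates (survey logistic for a binary
        mediator, survey linear otherwise).  Outcome: count ~ exposure +
        M + covariates, survey Poisson with log follow-up offset.
        """
        d = self.data
        w = d[self.weights_col]
        med_family = "logistic" if self.mediator_type == "binary" else "gaussian"
        med_fit = SurveyGLM(
            d[self.mediator_col], d[[self.exposure_col] + self.covariate_cols],
            w, family=med_family,
        ).fit()
        out_fit = SurveyGLM(
            d[self.outcome_col],
            d[[self.exposure_col, self.mediator_col] + self.covariate_cols],
            w, family="poisson", offset=np.log(d[self.followup_col].to_numpy(float)),
        ).fit()
        return med_fit, out_fit

    # -- quasi-Bayesian estimation ------------------------------------------

    def fit(self, n_draws: int = 1000, ci_level: float = 0.95,
            seed: int = 0, fits=None) -> MediationResults:
        """Run the quasi-Bayesian mediation algorithm; see the module docstring."""
        if n_draws < 100:
            raise ValueError("n_draws must be >= 100")
        med_fit, out_fit = self.fit_models() if fits is None else fits
        rng = np.random.default_rng(seed)
        d = self.data
        n = len(d)
        w = d[self.weights_col].to_numpy(float)
        w = w / w.sum()
        t = d[self.followup_col].to_numpy(float)
        a0, a1 = self.contrast

        # design pieces with the exposure (and mediator) columns factored out
        med_X = med_fit.model.exog
        out_X = out_fit.model.exog
        med_exp_col = self.exposure_col
        med_other = med_X.drop(columns=[med_exp_col])
        out_other = out_X.drop(columns=[med_exp_col, self.mediator_col])

        med_draws = rng.multivariate_normal(
            med_fit.params.to_numpy(), med_fit.cov_params.to_numpy(), size=n_draws)
        out_draws = rng.multivariate_normal(
            out_fit.params.to_numpy(), out_fit.cov_params.to_numpy(), size=n_draws)
        med_cols = list(med_X.columns)
        out_cols = list(out_X.columns)
        i_me = med_cols.index(med_exp_col)
        i_oe = out_cols.index(med_exp_col)
        i_om = out_cols.index(self.mediator_col)
        i_mo = [j for j in range(len(med_cols)) if j != i_me]
        i_oo = [j for j in range(len(out_cols)) if j not in (i_oe, i_om)]
        med_other_arr = med_other.to_numpy(float)
        out_other_arr = out_other.to_numpy(float)
        if self.mediator_type == "continuous":
            resid = med_fit.model.endog - med_fit.predict()
            sigma2 = float(np.average(resid**2, weights=d[self.weights_col]))

        acme = np.empty(n_draws)
        ade = np.empty(n_draws)
        total = np.empty(n_draws)
        for b in range(n_draws):
            mth, oth = med_draws[b], out_draws[b]
            med_base = med_other_arr @ mth[i_mo]
            out_base = out_other_arr @ oth[i_oo]

            def mu(a, am):
                """weighted mean expected count with exposure a, mediator from arm am"""
                lp_m = med_base + mth[i_me] * am
                lam0 = np.exp(out_base + oth[i_oe] * a) * t
                bm = oth[i_om]
                if self.mediator_type == "binary":
                    p = 1.0 / (1.0 + np.exp(-lp_m))
                    factor = p * np.exp(bm) + (1.0 - p)
                else:
                    factor = np.exp(bm * lp_m + 0.5 * bm**2 * sigma2)
                return float(np.sum(w * lam0 * factor))

            m_tt, m_tc = mu(a1, a1), mu(a1, a0)
            m_ct, m_cc = mu(a0, a1), mu(a0, a0)
            acme[b] = 0.5 * ((m_tt - m_tc) + (m_ct - m_cc))
            ade[b] = 0.5 * ((m_tt - m_ct) + (m_tc - m_cc))
            total[b] = m_tt - m_cc

        prop = np.divide(acme, total, out=np.full_like(acme, np.nan),
                         where=total != 0)
        alpha = 1 - ci_level
        qs = [100 * alpha / 2, 100 * (1 - alpha / 2)]

        def ci(x):
            lo, hi = np.nanpercentile(x, qs)
            return (float(lo), float(hi))

        total_p = _percentile_pvalue(total)
        res = MediationResults(
            acme=float(np.median(acme)), ade=float(np.median(ade)),
            total=float(np.median(total)),
            prop_mediated=float(np.nanmedian(prop)),
            ci_level=ci_level,
            acme_ci=ci(acme), ade_ci=ci(ade), total_ci=ci(total), prop_ci=ci(prop),
            acme_p=_percentile_pvalue(acme), total_p=total_p,
            prop_p=_percentile_pvalue(prop[np.isfinite(prop)]),
            contrast=self.contrast, n_draws=n_draws,
            draws={"acme": acme, "ade": ade, "total": total, "prop": prop},
        )
        if res.prop_undefined:
            import logging
            logging.getLogger(__name__).warning(
                "total effect indistinguishable from 0; proportion mediated unreliable")
        return res


def fit_mediation_models(model: MediationModel):
    """Functional alias for :meth:`MediationModel.fit_models`."""
    return model.fit_models()


def estimate_mediation(model: MediationModel, fits=None, n_draws=1000,
                       ci_level=0.95, seed=0) -> MediationResults:
    """Functional alias for :meth:`MediationModel.fit`."""
    return model.fit(n_draws=n_draws, ci_level=ci_level, seed=seed, fits=fits)


def mediation_quantile_grid(
    data, exposure_col, mediator_col, outcome_col, covariate_cols,
    weights_col, followup_col, mediator_type="binary",
    probs=(0.0, 0.25, 0.5, 0.75, 1.0), n_draws=1000, seed=0,
) -> pd.DataFrame:
    """Mediation over every ordered pair of exposure quantiles.

    Computes the exposure quantiles Q0..Qk at ``probs`` and runs the
    mediation estimator for each contrast (Q_i control, Q_j treat, i < j);
    for 5 probabilities that is C(5,2) = 10 contrasts.  Returns a tidy
    frame with the proportion mediated, its CI and significance stars per
    contrast (mirroring a control-quantile x treat-quantile grid).
    """
    qvals = np.quantile(data[exposure_col].dropna().to_numpy(), probs)
    rows = []
    for (i, qi), (j, qj) in combinations(enumerate(qvals), 2):
        if qj <= qi:  # degenerate contrast (ties in the PRS tails)
            continue
        model = MediationModel(
            data, exposure_col, mediator_col, outcome_col, covariate_cols,
            weights_col, followup_col, mediator_type=mediator_type,
            control_value=qi, treat_value=qj,
        )
        res = model.fit(n_draws=n_draws, seed=seed + 97 * i + j)
        rows.append({
            "control_q": probs[i], "treat_q": probs[j],
            "control_value": qi, "treat_value": qj,
            "acme": res.acme, "total": res.total,
            "prop_mediated": res.prop_mediated,
            "prop_ci_low": res.prop_ci[0], "prop_ci_high": res.prop_ci[1],
            "prop_p": res.prop_p, "signif": significance_code(res.prop_p),
        })
    return pd.DataFrame(rows)
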