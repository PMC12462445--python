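"""Survey-weighted generalized linear models with sandwich variance.

``SurveyGLM`` maximizes the weighted pseudo-log-likelihood
``sum_i w_i * l_i(beta)`` for a logistic or Poisson family (the Poisson
family accepts a log exposure-time offset for incidence analysis) and
reports the weights-only sandwich covariance ``A^-1 B A^-1`` with
``A = sum_i w_i H_i`` (weighted Hessian) and ``B = sum_i w_i^2 s_i s_i'``
(squared-weight outer score products).  This matches a survey design with
sampling weights but no stratum/PSU variance components.  Inference uses
1-degree-of-freedom Wald statistics with normal reference.

Helpers provide stratified fits, PRS-by-stratum interaction tests, and
repeated train/test-split AUC evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

__all__ = ["SurveyGLM", "SurveyGLMResults", "AucResult", "stratified_association",
           "interaction_analysis", "auc_repeated_split"]

_FAMILIES = {
    "logistic": sm.families.Binomial,
    "binomial": sm.families.Binomial,
    "poisson": sm.families.Poisson,
    "gaussian": sm.families.Gaussian,  # survey linear regression (continuous mediators)
}


class SurveyGLM:
    """Weighted GLM with weights-only sandwich (robust) covariance.

    Parameters
    ----------
    endog : array-like
        Outcome (binary for logistic, counts for Poisson).
    exog : DataFrame
        Design matrix; a constant is appended when absent.
    weights : array-like
        Positive survey weights. Estimates are invariant to their scale.
    family : {"logistic", "poisson"}
    offset : array-like, optional
        Log exposure time; Poisson only.
    """

    def __init__(self, endog, exog, weights, family="logistic", offset=None):
        fam = family.lower()
        if fam not in _FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        if offset is not None and fam not in ("poisson",):
            raise ValueError("offset is only supported with the poisson family")
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0) or not np.all(np.isfinite(w)):
            raise ValueError("survey weights must be positive and finite")
        X = sm.add_constant(pd.DataFrame(exog).astype(float), has_constant="skip")
        self._check_collinear(X)
        self.family_name = "logistic" if fam == "binomial" else fam
        self.endog = np.asarray(endog, dtype=float)
        self.exog = X
        self.weights = w
        self.offset = None if offset is None else np.asarray(offset, dtype=float)

    @staticmethod
    def _check_collinear(X: pd.DataFrame):
        arr = X.to_numpy()
        rank = np.linalg.matrix_rank(arr)
        if rank < arr.shape[1]:
            # name the culprits: columns whose removal restores full rank
            bad = [c for c in X.columns
                   if np.linalg.matrix_rank(X.drop(columns=[c]).to_numpy()) == rank]
            raise ValueError(f"collinear design matrix; implicated columns: {bad}")

    @classmethod
    def from_formula(cls, formula, data, weights, family="logistic", offset=None):
        """Build from a model formula evaluated against ``data``."""
        mod = smf.glm(formula, data=data)
        idx = mod.data.orig_endog.index
        w = np.asarray(pd.Series(np.asarray(weights, dtype=float),
                                 index=data.index).loc[idx])
        off = None
        if offset is not None:
            off = np.asarray(pd.Series(np.asarray(offset, dtype=float),
                                       index=data.index).loc[idx])
        return cls(mod.data.orig_endog, mod.data.orig_exog, w, family=family, offset=off)

    def fit(self, **kwargs) -> "SurveyGLMResults":
        fam = _FAMILIES[self.family_name]()
        model = sm.GLM(self.endog, self.exog, family=fam,
                       var_weights=self.weights, offset=self.offset)
        res = model.fit(cov_type="HC0", **kwargs)
        if not res.converged:
            raise RuntimeError("survey GLM did not converge (possible separation)")
        return SurveyGLMResults(self, res)


@dataclass
class SurveyGLMResults:
    """Fitted survey GLM: coefficients, sandwich covariance, Wald inference."""

    model: SurveyGLM
    _res: object

    @property
    def params(self) -> pd.Series:
        return self._res.params

    @property
    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self._res.cov_params(),
                            index=self.params.index, columns=self.params.index)

    @property
    def bse(self) -> pd.Series:
        return self._res.bse

    @property
    def nobs(self) -> int:
        return int(self._res.nobs)

    def wald_pvalues(self) -> pd.Series:
        """Two-sided 1-df Wald p-values, 2*(1 - Phi(|b/se|))."""
        z = self.params / self.bse
        return pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def predict(self, exog=None, offset=None) -> np.ndarray:
        X = (self.model.exog if exog is None
             else sm.add_constant(pd.DataFrame(exog).astype(float), has_constant="skip"))
        return self._res.predict(X, offset=offset)

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        """Tidy per-term table with exponentiated effects (OR / IRR) and CIs."""
        zc = stats.norm.ppf(1 - alpha / 2)
        eff = {"logistic": "OR", "poisson": "IRR"}.get(self.model.family_name, "exp_estimate")
        tab = pd.DataFrame({
            "term": self.params.index,
            "estimate": self.params.values,
            "se": self.bse.values,
            eff: np.exp(self.params.values),
            f"{eff}_ci_low": np.exp(self.params.values - zc * self.bse.values),
            f"{eff}_ci_high": np.exp(self.params.values + zc * self.bse.values),
            "p": self.wald_pvalues().values,
        })
        return tab.set_index("term")


def fit_survey_glm(y, X, weights, family="logistic", offset=None) -> SurveyGLMResults:
    """Functional wrapper: construct and fit a :class:`SurveyGLM`."""
    return SurveyGLM(y, X, weights, family=family, offset=offset).fit()


def stratified_association(
    data: pd.DataFrame,
    stratum_var: str,
    formula: str,
    weights_col: str,
    family: str = "logistic",
    offset_col: str | None = None,
    min_cases: int = 10,
) -> dict:
    """Fit the same survey GLM independently within each stratum.

    Strata with fewer than ``min_cases`` outcome events (or that are empty)
    are flagged and skipped.
    """
    fits: dict[str, SurveyGLMResults | None] = {}
    outcome = formula.split("~")[0].strip()
    for level, sub in data.groupby(stratum_var, dropna=True):
        sub = sub.dropna(subset=[outcome])
        n_cases = float(pd.to_numeric(sub[outcome], errors="coerce").fillna(0).astype(bool).sum())
        if len(sub) == 0 or n_cases < min_cases:
            logger.warning("stratum %r skipped (%d rows, %.0f cases)", level, len(sub), n_cases)
            fits[str(level)] = None
            continue
        off = None if offset_col is None else sub[offset_col]
        fits[str(level)] = SurveyGLM.from_formula(
            formula, sub, sub[weights_col], family=family, offset=off,
        ).fit()
    return fits


def interaction_analysis(
    data: pd.DataFrame,
    prs_col: str,
    stratum_var: str,
    base_formula: str,
    weights_col: str,
    family: str = "logistic",
    offset_col: str | None = None,
    reference: str | None = None,
) -> tuple[SurveyGLMResults, pd.Series]:
    """Survey GLM with PRS x stratum product terms and per-product Wald p.

    The stratum is dummy-coded against ``reference`` (default: first level);
    the model holds main effects plus one PRS x dummy product per non-
    reference level.  Returns the fit and the Wald p-value per product term.
    """
    levels = sorted(data[stratum_var].dropna().unique(), key=str)
    ref = reference if reference is not None else levels[0]
    sub = data.dropna(subset=[stratum_var]).copy()
    prod_terms = []
    for lev in levels:
        if lev == ref:
            continue
        dcol = f"{stratum_var}_{lev}"
        sub[dcol] = (sub[stratum_var] == lev).astype(float)
        pcol = f"{prs_col}_x_{lev}"
        sub[pcol] = sub[dcol] * sub[prs_col]
        prod_terms.append((dcol, pcol))
    formula = base_formula + "".join(f" + {d} + {p}" for d, p in prod_terms)
    off = None if offset_col is None else sub[offset_col]
    fit = SurveyGLM.from_formula(formula, sub, sub[weights_col],
                                 family=family, offset=off).fit()
    pvals = fit.wald_pvalues()
    return fit, pvals[[p for _, p in prod_terms]]


@dataclass
class AucResult:
    """Mean AUC with percentile CI over repeated train/test splits."""

    mean_auc: float
    ci_low: float
    ci_high: float
    n_repeats: int
    train_frac: float
    aucs: np.ndarray = field(repr=False, default=None)


def _risk_score(fit: SurveyGLMResults, X_test, followup=None) -> np.ndarray:
    if fit.model.family_name == "logistic":
        return fit.predict(X_test)
    # Poisson incidence model: event probability over follow-up 1 - exp(-rate*t)
    rate = fit.predict(X_test, offset=np.zeros(len(X_test)))
    t = np.ones(len(X_test)) if followup is None else np.asarray(followup, dtype=float)
    return 1.0 - np.exp(-rate * t)


def auc_repeated_split(
    data: pd.DataFrame,
    outcome_col: str,
    covariate_cols: list[str],
    prs_col: str | None,
    weights_col: str,
    family: str = "logistic",
    offset_col: str | None = None,
    n_repeats: int = 500,
    train_frac: float = 0.9,
    seed: int = 0,
    max_retries: int = 10,
) -> AucResult:
    """Repeated random-split AUC of a survey GLM risk model.

    Per repeat the data are split train (``train_frac``) / test, the model
    (covariates, optionally plus the PRS) is fitted on the training fold
    with survey weights, and the unweighted AUC of the predicted risk is
    computed on the test fold.  Splits whose test fold has a single outcome
    class are re-drawn up to ``max_retries`` times, then discarded with a
    log message.  Reports the mean AUC and the 2.5/97.5 percentile CI.
    """
    cols = covariate_cols + ([prs_col] if prs_col else [])
    need = [outcome_col, weights_col] + cols + ([offset_col] if offset_col else [])
    d = data.dropna(subset=need).reset_index(drop=True)
    y = d[outcome_col].astype(float).to_numpy()
    rng = np.random.default_rng(seed)
    n = len(d)
    n_train = int(round(train_frac * n))
    aucs = []
    for _ in range(n_repeats):
        for _retry in range(max_retries + 1):
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            if len(np.unique(y[te])) == 2 and len(np.unique(y[tr])) == 2:
                break
        else:
            logger.warning("degenerate split discarded after %d retries", max_retries)
            continue
        off_tr = d.loc[tr, offset_col] if offset_col else None
        fit = SurveyGLM(y[tr], d.loc[tr, cols], d.loc[tr, weights_col],
                        family=family, offset=off_tr).fit()
        followup = np.exp(d.loc[te, offset_col].to_numpy()) if offset_col else None
        risk = _risk_score(fit, d.loc[te, cols], followup=followup)
        aucs.append(roc_auc_score(y[te], risk))
    aucs = np.asarray(aucs)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return AucResult(float(aucs.mean()), float(lo), float(hi),
                     n_repeats=len(aucs), train_frac=train_frac, aucs=aucs)
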