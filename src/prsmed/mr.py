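"""Two-sample and multivariable Mendelian randomization from GWAS summary statistics.

The module covers the full summary-statistic workflow: fixed-effect
meta-analysis of two GWAS, instrument selection (genome-wide significance
filter plus greedy LD clumping), allele harmonization across traits, and
the estimator family: Wald ratio, inverse-variance weighted (IVW) with
multiplicative random effects, MR-Egger, weighted median, simple/weighted
mode, MR-RAPS (robust adjusted profile score), MR-PRESSO outlier
detection, and multivariable IVW (MVMR).

Summary statistics are plain DataFrames with columns
``snp, chr, pos, effect_allele, other_allele, eaf, beta, se, p, n``
(``chr``/``pos``/``eaf``/``n`` optional where noted).  ``MRModel`` wraps a
harmonized set and dispatches estimators; each estimator returns an
:class:`MRResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "MRResults", "MRModel", "ivw_meta_analyze", "select_instruments", "harmonize",
    "mr_wald_ratio", "mr_ivw", "mr_egger", "mr_weighted_median", "mr_mode",
    "mr_raps", "mr_presso", "mvmr_ivw",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}

Z95 = stats.norm.ppf(0.975)


@dataclass
class MRResults:
    """A causal-effect estimate on the log-odds scale with Wald inference."""

    method: str
    estimate: float
    se: float
    k: int
    q: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    global_p: float | None = None
    outliers: list = field(default_factory=list)
    exposure: str = "exposure"

    @property
    def ci(self) -> tuple[float, float]:
        return (self.estimate - Z95 * self.se, self.estimate + Z95 * self.se)

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.estimate))

    @property
    def pvalue(self) -> float:
        return float(2 * stats.norm.sf(abs(self.estimate) / self.se)) if self.se > 0 else 0.0

    def summary(self) -> pd.DataFrame:
        lo, hi = self.ci
        row = {
            "method": self.method, "exposure": self.exposure, "k": self.k,
            "estimate": self.estimate, "se": self.se,
            "ci_low": lo, "ci_high": hi, "p": self.pvalue,
            "OR": self.odds_ratio, "OR_ci_low": float(np.exp(lo)),
            "OR_ci_high": float(np.exp(hi)),
        }
        if self.q is not None:
            row["cochran_q"] = self.q
        if self.egger_intercept is not None:
            row["egger_intercept"] = self.egger_intercept
            row["egger_intercept_se"] = self.egger_intercept_se
        if self.global_p is not None:
            row["presso_global_p"] = self.global_p
            row["n_outliers"] = len(self.outliers)
        return pd.DataFrame([row])


def _validate_sumstats(df: pd.DataFrame, need_pos=False) -> pd.DataFrame:
    req = ["snp", "effect_allele", "other_allele", "beta", "se"]
    if need_pos:
        req += ["chr", "pos"]
    missing = [c for c in req if c not in df.columns]
    if missing:
        raise ValueError(f"summary statistics missing columns: {missing}")
    if (df["se"] <= 0).any():
        raise ValueError("summary statistics contain non-positive SEs")
    return df


def ivw_meta_analyze(gwas_a: pd.DataFrame, gwas_b: pd.DataFrame) -> pd.DataFrame:
    """Fixed-effect inverse-variance meta-analysis of two GWAS, per shared SNP.

    Study b's effects are aligned to study a's effect allele (sign flipped
    when the allele pair is swapped, complement strand accepted); SNPs
    absent from either study, or with incompatible alleles, are dropped.
    """
    a = _validate_sumstats(gwas_a).set_index("snp")
    b = _validate_sumstats(gwas_b).set_index("snp")
    shared = a.index.intersection(b.index)
    rows = []
    for snp in shared:
        ra, rb = a.loc[snp], b.loc[snp]
        sign = _align_sign(ra["effect_allele"], ra["other_allele"],
                           rb["effect_allele"], rb["other_allele"])
        if sign == 0:
            continue
        w = np.array([1.0 / ra["se"] ** 2, 1.0 / rb["se"] ** 2])
        betas = np.array([ra["beta"], sign * rb["beta"]])
        beta = float(np.sum(w * betas) / np.sum(w))
        se = float(np.sqrt(1.0 / np.sum(w)))
        row = {"snp": snp, "effect_allele": ra["effect_allele"],
               "other_allele": ra["other_allele"], "beta": beta, "se": se,
               "p": float(2 * stats.norm.sf(abs(beta) / se))}
        for c in ("chr", "pos", "eaf"):
            if c in a.columns:
                row[c] = ra[c]
        if "n" in a.columns and "n" in b.columns:
            row["n"] = ra["n"] + rb["n"]
        rows.append(row)
    return pd.DataFrame(rows)


def _align_sign(ea1, oa1, ea2, oa2) -> int:
    """+1 if (ea2, oa2) matches (ea1, oa1), -1 if swapped, 0 if incompatible.

    Complement-strand representations are accepted in both orientations.
    """
    c = _COMPLEMENT
    if (ea2, oa2) == (ea1, oa1) or (c[ea2], c[oa2]) == (ea1, oa1):
        return 1
    if (ea2, oa2) == (oa1, ea1) or (c[ea2], c[oa2]) == (oa1, ea1):
        return -1
    return 0


def select_instruments(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    p_thresh: float = 5e-8,
    ld: pd.DataFrame | None = None,
    clump_kb: float = 10_000,
    clump_r2: float = 0.001,
    min_maf: float = 0.01,
) -> list[str]:
    """Select MR instruments from the exposure GWAS.

    Pipeline: (1) intersect SNPs present in exposure and outcome; (2) keep
    exposure p < ``p_thresh``; (3) keep biallelic SNPs with MAF >
    ``min_maf``; (4) greedy clumping — scan SNPs by ascending p (ties
    broken by lower genomic position) and keep a SNP iff its r^2 with every
    already-kept SNP within ``clump_kb`` kilobases is <= ``clump_r2``.
    ``ld`` is a symmetric r^2 matrix indexed by SNP id; SNP pairs absent
    from it are treated as unlinked.  Raises when any step empties the set.
    """
    exp = _validate_sumstats(exposure, need_pos=True).set_index("snp")
    out = _validate_sumstats(outcome).set_index("snp")
    snps = exp.index.intersection(out.index)
    if len(snps) == 0:
        raise ValueError("instrument selection failed: no shared SNPs")
    cand = exp.loc[snps]
    cand = cand[cand["p"] < p_thresh]
    if cand.empty:
        raise ValueError(f"instrument selection failed: no SNP with exposure p < {p_thresh}")
    if "eaf" in cand.columns:
        maf = np.minimum(cand["eaf"], 1 - cand["eaf"])
        cand = cand[maf > min_maf]
        if cand.empty:
            raise ValueError("instrument selection failed: MAF filter removed all SNPs")
    cand = cand.sort_values(["p", "pos"], kind="mergesort")
    kept: list[str] = []
    for snp, row in cand.iterrows():
        ok = True
        for ksnp in kept:
            krow = cand.loc[ksnp]
            if krow["chr"] != row["chr"]:
                continue
            if abs(float(krow["pos"]) - float(row["pos"])) > clump_kb * 1000:
                continue
            r2 = 0.0
            if ld is not None and snp in ld.index and ksnp in ld.columns:
                r2 = float(ld.loc[snp, ksnp])
            if r2 > clump_r2:
                ok = False
                break
        if ok:
            kept.append(snp)
    if not kept:
        raise ValueError("instrument selection failed: clumping removed all SNPs")
    return kept


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    exposure2: pd.DataFrame | None = None,
    snps: list[str] | None = None,
    palindromic_maf: float = 0.42,
) -> pd.DataFrame:
    """Align outcome (and second exposure) effects to the exposure's effect allele.

    Per SNP matched by id: identical allele pairs pass through; swapped
    pairs flip the other study's beta sign (and eaf -> 1 - eaf);
    complement-strand representations are mapped through the complement and
    re-tried.  Palindromic (A/T, C/G) SNPs are dropped when
    ``min(eaf, 1-eaf) > palindromic_maf`` or the eaf is missing; otherwise
    they are oriented by allele frequency (flip when the exposure and
    outcome frequencies sit on opposite sides of 0.5).  Returns one row per
    retained SNP with provenance flags ``flipped``, ``strand_corrected``.
    """
    exp = _validate_sumstats(exposure).set_index("snp")
    others = {"outcome": _validate_sumstats(outcome).set_index("snp")}
    if exposure2 is not None:
        others["exposure2"] = _validate_sumstats(exposure2).set_index("snp")
    ids = exp.index
    for o in others.values():
        ids = ids.intersection(o.index)
    if snps is not None:
        ids = pd.Index([s for s in snps if s in ids])
    rows = []
    for snp in ids:
        re_ = exp.loc[snp]
        ea, oa = re_["effect_allele"], re_["other_allele"]
        rec = {"snp": snp, "effect_allele": ea, "other_allele": oa,
               "beta_exposure": float(re_["beta"]), "se_exposure": float(re_["se"]),
               "flipped": False, "strand_corrected": False}
        for c in ("chr", "pos"):
            if c in exp.columns:
                rec[c] = re_[c]
        if "eaf" in exp.columns:
            rec["eaf_exposure"] = float(re_["eaf"])
        palindromic = frozenset((ea, oa)) in _PALINDROMIC
        if palindromic:
            eaf = re_.get("eaf", np.nan)
            if pd.isna(eaf) or min(eaf, 1 - eaf) > palindromic_maf:
                continue
        keep = True
        for name, table in others.items():
            ro = table.loc[snp]
            if palindromic:
                eaf_o = ro.get("eaf", np.nan)
                if pd.isna(eaf_o):
                    keep = False
                    break
                # orient by frequency: flip when the two studies' eafs
                # disagree about which allele is the minor one
                sign = 1 if (re_["eaf"] - 0.5) * (eaf_o - 0.5) >= 0 else -1
            else:
                sign = _align_sign(ea, oa, ro["effect_allele"], ro["other_allele"])
                if sign == 0:
                    keep = False
                    break
                if (ro["effect_allele"], ro["other_allele"]) not in ((ea, oa), (oa, ea)):
                    rec["strand_corrected"] = True
            if sign == -1:
                rec["flipped"] = True
            rec[f"beta_{name}"] = sign * float(ro["beta"])
            rec[f"se_{name}"] = float(ro["se"])
        if keep:
            rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# estimators


def _hcols(h: pd.DataFrame):
    return (h["beta_exposure"].to_numpy(float), h["se_exposure"].to_numpy(float),
            h["beta_outcome"].to_numpy(float), h["se_outcome"].to_numpy(float))


def mr_wald_ratio(h: pd.DataFrame) -> MRResults:
    """Single-instrument causal estimate: beta_outcome / beta_exposure."""
    if len(h) != 1:
        raise ValueError("Wald ratio requires exactly one SNP")
    bx, sx, by, sy = _hcols(h)
    return MRResults("wald_ratio", float(by[0] / bx[0]), float(sy[0] / abs(bx[0])), k=1)


def mr_ivw(h: pd.DataFrame, random_effects: bool = True) -> MRResults:
    """Inverse-variance weighted estimate (multiplicative random effects).

    Weighted regression of outcome on exposure betas through the origin
    with weights 1/se_outcome^2.  Under random effects the SE is inflated
    by ``max(1, sqrt(Q/(k-1)))`` where Q is Cochran's heterogeneity
    statistic; the inflation never shrinks the SE below its fixed-effect
    value.
    """
    bx, sx, by, sy = _hcols(h)
    k = len(bx)
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    b = float(np.sum(w * bx * by) / denom)
    se = float(np.sqrt(1.0 / denom))
    q = float(np.sum(w * (by - b * bx) ** 2))
    if random_effects and k > 1:
        se *= max(1.0, np.sqrt(q / (k - 1)))
    return MRResults("ivw" if random_effects else "ivw_fe", b, se, k=k,
                     q=q if k > 1 else None)


def mr_egger(h: pd.DataFrame) -> MRResults:
    """MR-Egger regression: weighted fit of by = alpha + b*bx.

    Exposure effects are re-oriented to positive sign first (with the
    matching outcome sign flips), weights are 1/se_outcome^2, and both SEs
    are inflated by ``max(1, residual SD)``.  The intercept alpha estimates
    directional pleiotropy.  Requires at least three instruments.
    """
    bx, sx, by, sy = _hcols(h)
    k = len(bx)
    if k < 3:
        raise ValueError("MR-Egger requires at least 3 instruments")
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    XtW = X.T * w
    A = XtW @ X
    coef = np.linalg.solve(A, XtW @ by)
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    cov_unscaled = np.linalg.inv(A)
    infl = max(1.0, np.sqrt(sigma2))
    ses = np.sqrt(np.diag(cov_unscaled)) * infl
    return MRResults("egger", float(coef[1]), float(ses[1]), k=k,
                     q=float(np.sum(w * resid**2)),
                     egger_intercept=float(coef[0]), egger_intercept_se=float(ses[0]))


def _ratio_stats(h: pd.DataFrame):
    bx, sx, by, sy = _hcols(h)
    r = by / bx
    # first-order variance of the ratio
    var = sy**2 / bx**2
    return r, var


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    s = np.cumsum(w) - 0.5 * w
    s = s / np.sum(w)
    if s[0] >= 0.5:
        return float(v[0])
    if s[-1] <= 0.5:
        return float(v[-1])
    j = int(np.searchsorted(s, 0.5))
    # linear interpolation between bracketing ratio estimates
    f = (0.5 - s[j - 1]) / (s[j] - s[j - 1])
    return float(v[j - 1] + f * (v[j] - v[j - 1]))


def mr_weighted_median(h: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> MRResults:
    """Weighted median of per-SNP Wald ratios (inverse-variance weights).

    Consistent when instruments carrying at least half the weight are
    valid.  SE by parametric bootstrap of the summary betas.
    """
    if len(h) == 1:
        r = mr_wald_ratio(h)
        return MRResults("weighted_median", r.estimate, r.se, k=1)
    r, var = _ratio_stats(h)
    w = 1.0 / var
    est = _weighted_median(r, w)
    bx, sx, by, sy = _hcols(h)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        rs = bys / bxs
        boots[i] = _weighted_median(rs, bxs**2 / sy**2)
    return MRResults("weighted_median", est, float(np.std(boots, ddof=1)), k=len(r))


def _mode_estimate(r: np.ndarray, w: np.ndarray, bandwidth_factor: float) -> float:
    if np.ptp(r) == 0:
        return float(r[0])
    sd = np.std(r, ddof=1)
    mad = stats.median_abs_deviation(r, scale="normal")
    s = 0.9 * min(sd, mad if mad > 0 else sd) * len(r) ** (-1 / 5)
    hbw = max(bandwidth_factor * s, 1e-8 * max(abs(np.max(r)), 1.0))
    grid = np.linspace(np.min(r) - 3 * hbw, np.max(r) + 3 * hbw, 2048)
    dens = np.zeros_like(grid)
    for rj, wj in zip(r, w):
        dens += wj * np.exp(-0.5 * ((grid - rj) / hbw) ** 2)
    return float(grid[np.argmax(dens)])


def mr_mode(h: pd.DataFrame, mode: str = "simple", bandwidth_factor: float = 1.0,
            n_boot: int = 1000, seed: int = 0) -> MRResults:
    """Mode of the kernel-smoothed Wald-ratio density (simple or weighted).

    The weighted variant weights each ratio by its inverse first-order
    variance.  SE by parametric bootstrap.
    """
    if mode not in ("simple", "weighted"):
        raise ValueError("mode must be 'simple' or 'weighted'")
    if len(h) == 1:
        r = mr_wald_ratio(h)
        return MRResults(f"{mode}_mode", r.estimate, r.se, k=1)
    r, var = _ratio_stats(h)
    w = np.ones_like(r) if mode == "simple" else 1.0 / var
    est = _mode_estimate(r, w / np.sum(w), bandwidth_factor)
    bx, sx, by, sy = _hcols(h)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        rs = bys / bxs
        ws = np.ones_like(rs) if mode == "simple" else bxs**2 / sy**2
        boots[i] = _mode_estimate(rs, ws / np.sum(ws), bandwidth_factor)
    return MRResults(f"{mode}_mode", est, float(np.std(boots, ddof=1)), k=len(r))


def mr_raps(h: pd.DataFrame, overdispersion: bool = False) -> MRResults:
    """Robust adjusted profile score estimate.

    Maximizes the profile log-likelihood
    ``-1/2 * sum (by_j - b*bx_j)^2 / (sy_j^2 + b^2 * sx_j^2)`` which
    accounts for measurement error in the exposure betas (useful with weak
    instruments).  With ``overdispersion`` an additive variance component
    tau^2 is profiled jointly (a log-determinant term then keeps tau^2
    finite).  SE from the observed information at the optimum.
    """
    bx, sx, by, sy = _hcols(h)

    if not overdispersion:
        def negll(b):
            v = sy**2 + b**2 * sx**2
            return 0.5 * np.sum((by - b * bx) ** 2 / v)

        res = optimize.minimize_scalar(negll, bounds=(-20, 20), method="bounded")
        b = float(res.x)
        se = _se_from_information(lambda t: -negll(t), b)
        return MRResults("raps", b, se, k=len(bx))

    def negll2(theta):
        b, log_tau2 = theta
        v = sy**2 + b**2 * sx**2 + np.exp(log_tau2)
        return 0.5 * np.sum((by - b * bx) ** 2 / v + np.log(v))

    start = np.array([mr_ivw(h, random_effects=False).estimate, np.log(np.var(by) + 1e-6)])
    res = optimize.minimize(negll2, start, method="Nelder-Mead")
    b = float(res.x[0])
    se = _se_from_information(lambda t: -negll2([t, res.x[1]]), b)
    return MRResults("raps_od", b, se, k=len(bx))


def _se_from_information(ll, b, eps=1e-4):
    d2 = (ll(b + eps) - 2 * ll(b) + ll(b - eps)) / eps**2
    if d2 >= 0:
        return float("nan")
    return float(1.0 / np.sqrt(-d2))


def _loo_ivw_terms(bx, by, w):
    """Leave-one-out fixed-effect IVW estimates, vectorised."""
    num = np.sum(w * bx * by) - w * bx * by
    den = np.sum(w * bx**2) - w * bx**2
    return num / den


def mr_presso(h: pd.DataFrame, n_dist: int = 10_000, signif: float = 0.05,
              seed: int = 0) -> MRResults:
    """MR-PRESSO global pleiotropy test and outlier detection.

    The observed residual sum of squares uses leave-one-out IVW
    predictions; the null RSS distribution is simulated parametrically by
    redrawing both studies' betas from their standard errors around the
    leave-one-out fits.  The global p is the fraction of simulated RSS at
    or above the observed one (floored at 1/n_dist); per-SNP outlier
    p-values are Bonferroni-corrected against ``signif``.  When outliers
    are found the returned estimate is the outlier-corrected IVW; the
    distortion test is not performed.
    """
    bx, sx, by, sy = _hcols(h)
    k = len(bx)
    if k < 3:
        raise ValueError("MR-PRESSO requires at least 3 instruments")
    rng = np.random.default_rng(seed)
    w = 1.0 / sy**2
    b_loo = _loo_ivw_terms(bx, by, w)
    obs_comp = w * (by - b_loo * bx) ** 2
    rss_obs = float(np.sum(obs_comp))

    # parametric null: redraw betas around the LOO predictions
    bxs = rng.normal(bx, sx, size=(n_dist, k))
    bys = rng.normal(b_loo * bx, sy, size=(n_dist, k))
    num = np.sum(w * bxs * bys, axis=1, keepdims=True) - w * bxs * bys
    den = np.sum(w * bxs**2, axis=1, keepdims=True) - w * bxs**2
    b_loo_sim = num / den
    comp = w * (bys - b_loo_sim * bxs) ** 2
    rss_sim = comp.sum(axis=1)

    global_p = float(max(np.sum(rss_sim >= rss_obs), 1) / n_dist)
    p_snp = np.maximum(np.mean(comp >= obs_comp, axis=0), 1.0 / n_dist)
    outliers = [int(i) for i in np.where(p_snp * k < signif)[0]]
    if outliers:
        keep = np.setdiff1d(np.arange(k), outliers)
        sub = h.iloc[keep]
        corrected = mr_ivw(sub)
        return MRResults("presso", corrected.estimate, corrected.se, k=len(keep),
                         q=corrected.q, global_p=global_p, outliers=outliers)
    raw = mr_ivw(h)
    return MRResults("presso", raw.estimate, raw.se, k=k, q=raw.q,
                     global_p=global_p, outliers=[])


def mvmr_ivw(h: pd.DataFrame, focal: str = "exposure") -> list[MRResults]:
    """Multivariable IVW: joint weighted regression on two exposures.

    Regresses outcome betas on ``(beta_exposure, beta_exposure2)`` with no
    intercept and weights 1/se_outcome^2; SEs carry a multiplicative
    random-effects inflation floored at 1.  Returns one result per
    exposure (reports typically surface only the focal exposure's).
    Raises on a near-collinear exposure design, naming the condition
    number.
    """
    if "beta_exposure2" not in h.columns:
        raise ValueError("MVMR requires a harmonized set with a second exposure")
    bx1 = h["beta_exposure"].to_numpy(float)
    bx2 = h["beta_exposure2"].to_numpy(float)
    by = h["beta_outcome"].to_numpy(float)
    sy = h["se_outcome"].to_numpy(float)
    k = len(by)
    X = np.column_stack([bx1, bx2])
    w = 1.0 / sy**2
    Xw = X * np.sqrt(w)[:, None]
    cond = np.linalg.cond(Xw)
    if cond > 1e8:
        raise ValueError(f"collinear exposures in MVMR (condition number {cond:.3g})")
    A = X.T @ (X * w[:, None])
    coef = np.linalg.solve(A, X.T @ (w * by))
    resid = by - X @ coef
    q = float(np.sum(w * resid**2))
    infl = max(1.0, np.sqrt(q / max(k - 2, 1)))
    ses = np.sqrt(np.diag(np.linalg.inv(A))) * infl
    names = ["exposure", "exposure2"]
    return [MRResults("mvmr_ivw", float(coef[i]), float(ses[i]), k=k, q=q,
                      exposure=names[i]) for i in range(2)]


class MRModel:
    """Dispatcher over MR estimators for a harmonized SNP set.

    ``MRModel(harmonized).fit("ivw")`` returns an :class:`MRResults`;
    ``fit_all`` runs a list of methods and stacks their summaries.
    """

    _METHODS = {
        "wald_ratio": mr_wald_ratio,
        "ivw": mr_ivw,
        "egger": mr_egger,
        "median": mr_weighted_median,
        "weighted_median": mr_weighted_median,
        "simple_mode": lambda h, **kw: mr_mode(h, mode="simple", **kw),
        "weighted_mode": lambda h, **kw: mr_mode(h, mode="weighted", **kw),
        "raps": mr_raps,
        "presso": mr_presso,
    }

    def __init__(self, harmonized: pd.DataFrame):
        if harmonized.empty:
            raise ValueError("empty harmonized set")
        self.harmonized = harmonized.reset_index(drop=True)

    def fit(self, method: str = "ivw", **kwargs) -> MRResults:
        if method == "mvmr":
            return mvmr_ivw(self.harmonized, **kwargs)
        if method == "ivw" and len(self.harmonized) == 1:
            return mr_wald_ratio(self.harmonized)
        if method not in self._METHODS:
            raise ValueError(f"unknown MR method {method!r}")
        return self._METHODS[method](self.harmonized, **kwargs)

    def fit_all(self, methods=("ivw", "egger", "weighted_median", "raps")) -> pd.DataFrame:
        return pd.concat([self.fit(m).summary() for m in methods], ignore_index=True)
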