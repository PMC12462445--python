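"""Polygenic risk score construction and multi-ancestry combination.

A PRS is a weighted sum of effect-allele dosages over a variant weight
table.  For admixed cohorts three ancestry-specific scores (EUR, AFR, AMR)
are standardized and combined three ways:

* ``combine_prssum`` — unweighted sum of the standardized scores;
* ``combine_gapprssum`` — per-individual weighted sum using each person's
  estimated global ancestry proportions as weights;
* ``combine_weighted`` — weighted sum with a single weight per ancestry,
  typically the coefficients of the ancestry scores in an external logistic
  regression of disease status (the "external-regression" provenance).

Every combination is re-standardized (mean 0, variance 1, ddof=1) before
use, so any overall positive scaling of the weights is irrelevant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

WEIGHT_COLUMNS = ["variant_id", "chr", "pos", "effect_allele", "other_allele", "weight"]
_VALID_ALLELES = {"A", "C", "G", "T"}
_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}

__all__ = [
    "DosageMatrix",
    "StandardizedPRS",
    "CombinationWeights",
    "validate_weight_table",
    "filter_variants",
    "score_prs",
    "standardize_prs",
    "combine_prssum",
    "combine_gapprssum",
    "estimate_combination_weights",
    "combine_weighted",
    "prs_quantile_bins",
]


@dataclass
class DosageMatrix:
    """Genotype dosages (0-2) with the allele each column's dosage counts.

    ``values`` is individuals x variants; ``coded_alleles``/``other_alleles``
    give, per variant, the counted allele and the alternative.
    """

    values: pd.DataFrame  # index: individual ids, columns: variant ids
    coded_alleles: pd.Series  # per variant
    other_alleles: pd.Series

    def __post_init__(self):
        v = self.values.to_numpy(dtype=float)
        if np.nanmin(v, initial=0) < 0 or np.nanmax(v, initial=0) > 2:
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def individuals(self) -> pd.Index:
        return self.values.index

    @property
    def variants(self) -> pd.Index:
        return self.values.columns


@dataclass
class StandardizedPRS:
    """A per-individual score standardized to mean 0 / SD 1 in its reference sample."""

    scores: pd.Series
    mean: float
    sd: float
    label: str = ""

    def reindex(self, ids) -> pd.Series:
        return self.scores.reindex(ids)


@dataclass
class CombinationWeights:
    """One weight per ancestry-specific PRS, with provenance."""

    weights: dict[str, float]
    provenance: str = "external-regression"  # unit | ancestry-proportion | external-regression
    se: dict[str, float] = field(default_factory=dict)


def validate_weight_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a variant weight table's columns, alleles, and uniqueness."""
    missing = [c for c in ("variant_id", "effect_allele", "other_allele", "weight") if c not in table.columns]
    if missing:
        raise ValueError(f"weight table missing columns: {missing}")
    if table["variant_id"].duplicated().any():
        dups = table.loc[table["variant_id"].duplicated(), "variant_id"].tolist()
        raise ValueError(f"duplicate variant ids in weight table: {dups[:5]}")
    alleles = set(table["effect_allele"]) | set(table["other_allele"])
    bad = alleles - _VALID_ALLELES
    if bad:
        raise ValueError(f"invalid alleles in weight table: {sorted(bad)}")
    if not np.isfinite(table["weight"].to_numpy(dtype=float)).all():
        raise ValueError("non-finite weights in weight table")
    return table


def filter_variants(
    table: pd.DataFrame,
    min_r2: float | None = 0.8,
    min_maf: float | None = 0.01,
    drop_ambiguous: bool = True,
) -> pd.DataFrame:
    """Apply the standard pre-scoring variant filters.

    Keeps variants with imputation quality R^2 >= ``min_r2`` (inclusive),
    minor allele frequency >= ``min_maf`` (inclusive, computed as
    min(eaf, 1-eaf)), and a non-strand-ambiguous allele pair (not A/T or
    C/G).  Thresholds are skipped when the corresponding column is absent
    and the threshold is None.
    """
    keep = pd.Series(True, index=table.index)
    if min_r2 is not None:
        if "imputation_r2" not in table.columns:
            raise ValueError("min_r2 requested but 'imputation_r2' column absent")
        keep &= table["imputation_r2"] >= min_r2
    if min_maf is not None:
        if "eaf" not in table.columns:
            raise ValueError("min_maf requested but 'eaf' column absent")
        maf = np.minimum(table["eaf"], 1.0 - table["eaf"])
        keep &= maf >= min_maf
    if drop_ambiguous:
        ambiguous = [
            frozenset((ea, oa)) in _AMBIGUOUS_PAIRS
            for ea, oa in zip(table["effect_allele"], table["other_allele"])
        ]
        keep &= ~pd.Series(ambiguous, index=table.index)
    out = table.loc[keep].reset_index(drop=True)
    if out.empty:
        logger.warning("variant filter removed every variant")
    return out


def score_prs(dosages: DosageMatrix, weights: pd.DataFrame, label: str = "") -> pd.Series:
    """Score individuals: sum of weight x effect-allele dosage over variants.

    When the dosage matrix counts the *other* allele for a variant, the
    effect-allele dosage is ``2 - d``.  Variants absent from the dosage
    matrix, or whose allele pair is incompatible with the dosage coding,
    are skipped with a log message.  Scoring with zero overlapping variants
    is an error.
    """
    validate_weight_table(weights)
    score = np.zeros(len(dosages.individuals))
    used = skipped_missing = skipped_mismatch = 0
    for row in weights.itertuples(index=False):
        vid = row.variant_id
        if vid not in dosages.values.columns:
            skipped_missing += 1
            continue
        coded = dosages.coded_alleles[vid]
        other = dosages.other_alleles[vid]
        d = dosages.values[vid].to_numpy(dtype=float)
        if row.effect_allele == coded and row.other_allele == other:
            eff = d
        elif row.effect_allele == other and row.other_allele == coded:
            eff = 2.0 - d
        else:
            skipped_mismatch += 1
            continue
        score += row.weight * eff
        used += 1
    if used == 0:
        raise ValueError("no overlapping variants between weights and dosages")
    if skipped_missing or skipped_mismatch:
        logger.info(
            "score_prs: used %d variants, skipped %d missing, %d allele-incompatible",
            used, skipped_missing, skipped_mismatch,
        )
    return pd.Series(score, index=dosages.individuals, name=label or "prs")


def standardize_prs(prs: pd.Series, reference_ids=None, label: str = "") -> StandardizedPRS:
    """Standardize to mean 0 / SD 1 over the reference sample (ddof=1).

    The reference defaults to all scored individuals; the transform learnt
    there is applied to everyone.  Standardizing an already-standardized
    score is (numerically) the identity.
    """
    ref = prs if reference_ids is None else prs.loc[reference_ids]
    if len(ref) < 2:
        raise ValueError("need at least two individuals to standardize")
    mean = float(ref.mean())
    sd = float(ref.std(ddof=1))
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero or non-finite variance; cannot standardize")
    return StandardizedPRS((prs - mean) / sd, mean, sd, label=label or str(prs.name))


def _common_index(std_prs: dict[str, StandardizedPRS]) -> pd.Index:
    idx = None
    for s in std_prs.values():
        idx = s.scores.index if idx is None else idx.intersection(s.scores.index)
    if idx is None or len(idx) == 0:
        raise ValueError("no individuals shared by the ancestry PRSs")
    return idx


def combine_prssum(std_prs: dict[str, StandardizedPRS], label: str = "PRSsum") -> StandardizedPRS:
    """Unweighted sum of standardized ancestry PRSs, re-standardized."""
    idx = _common_index(std_prs)
    total = sum(s.scores.reindex(idx) for s in std_prs.values())
    return standardize_prs(total.rename(label), label=label)


def combine_gapprssum(
    std_prs: dict[str, StandardizedPRS],
    proportions: pd.DataFrame,
    tol: float = 1e-8,
    label: str = "gapPRSsum",
) -> StandardizedPRS:
    """Global-ancestry-proportion weighted sum, re-standardized.

    ``proportions`` has one column per ancestry (matching ``std_prs`` keys)
    and one row per individual; rows must sum to 1 within ``tol``.
    Individuals without proportions are excluded.
    """
    idx = _common_index(std_prs).intersection(proportions.dropna().index)
    props = proportions.loc[idx, list(std_prs.keys())]
    rowsum = props.sum(axis=1)
    if (np.abs(rowsum - 1.0) > tol).any():
        bad = rowsum.index[np.abs(rowsum - 1.0) > tol][:5].tolist()
        raise ValueError(f"ancestry proportions do not sum to 1 for: {bad}")
    total = pd.Series(0.0, index=idx)
    for anc, s in std_prs.items():
        total += props[anc] * s.scores.reindex(idx)
    return standardize_prs(total.rename(label), label=label)


def estimate_combination_weights(
    external: pd.DataFrame,
    prs_cols: list[str],
    outcome_col: str = "dm",
    covariate_cols: list[str] | None = None,
    n_pcs: int = 10,
) -> CombinationWeights:
    """Estimate ancestry-PRS combination weights in an external cohort.

    Fits an unweighted logistic regression of the binary outcome on the
    ancestry-specific standardized PRSs plus age, sex, and genetic PCs
    (``pc1..pc<n_pcs>`` when present), and returns the PRS coefficients as
    combination weights.  Negative coefficients are retained as-is.
    """
    covs = list(covariate_cols) if covariate_cols is not None else [
        c for c in ["age", "sex"] + [f"pc{i}" for i in range(1, n_pcs + 1)]
        if c in external.columns
    ]
    cols = prs_cols + covs
    X = sm.add_constant(external[cols].astype(float))
    y = external[outcome_col].astype(float)
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    return CombinationWeights(
        weights={c: float(res.params[c]) for c in prs_cols},
        provenance="external-regression",
        se={c: float(res.bse[c]) for c in prs_cols},
    )


def combine_weighted(
    std_prs: dict[str, StandardizedPRS],
    weights: CombinationWeights,
    label: str = "mgbPRSsum",
) -> StandardizedPRS:
    """Fixed-weight sum of standardized ancestry PRSs, re-standardized."""
    idx = _common_index(std_prs)
    total = pd.Series(0.0, index=idx)
    for anc, s in std_prs.items():
        total += weights.weights[anc] * s.scores.reindex(idx)
    return standardize_prs(total.rename(label), label=label)


def prs_quantile_bins(prs: pd.Series, probs=(0.0, 0.25, 0.5, 0.75, 1.0)):
    """Quantile cut points and bin labels for a PRS.

    Returns ``(labels, cuts)`` where ``cuts`` are the quantiles Q0..Qk of
    the observed scores and ``labels`` assigns each individual the
    1-based bin index; values tied with an interior cut point fall in the
    lower bin (intervals are (Q_{j-1}, Q_j], with Q0 included in bin 1).
    """
    x = prs.dropna()
    cuts = np.quantile(x.to_numpy(), probs)
    labels = pd.Series(
        np.searchsorted(cuts[1:-1], x.to_numpy(), side="left") + 1,
        index=x.index,
        name="prs_bin",
    )
    return labels.reindex(prs.index), cuts
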