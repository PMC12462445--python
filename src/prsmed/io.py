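"""File formats, run configuration, and the end-to-end pipeline driver.

Formats
-------
* GWAS summary statistics: tab-delimited with header
  ``SNP CHR POS EA OA EAF BETA SE P N``; the reader tolerates the common
  column synonyms (BETA/b/Effect, SE/StdErr, EA/A1/effect_allele, ...) and
  accepts an explicit column map for anything else.
* Variant weight tables: PGS-catalog harmonized dialect, tab-delimited
  with ``rsID chr pos effect_allele other_allele effect_weight``
  (plus optional ``eaf``, ``imputation_r2``).
* Cohort tables as CSV; dosage matrices as TSV with individuals in rows
  and two leading header lines naming each variant's coded/other allele.

``run_pipeline`` ties simulate -> score -> combine -> phenotype ->
associate -> mediate -> MR into one seeded, reproducible run directory
with tidy CSV outputs, a log, and a config echo.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mediation as med
from . import mr as mrmod
from . import prs as prsmod
from . import survey as surv
from .phenotypes import add_derived_phenotypes
from .prs import DosageMatrix
from .synthetic import CohortSimConfig, GwasSimConfig, simulate_admixed_cohort, simulate_two_sample_gwas

logger = logging.getLogger(__name__)

__all__ = ["read_gwas", "write_gwas", "read_weight_table", "write_weight_table",
           "write_dosages", "read_dosages", "RunConfig", "run_pipeline"]

_GWAS_SYNONYMS = {
    "snp": {"snp", "rsid", "id", "markername", "variant_id"},
    "chr": {"chr", "chrom", "chromosome"},
    "pos": {"pos", "bp", "position", "base_pair_location"},
    "effect_allele": {"ea", "a1", "effect_allele", "allele1"},
    "other_allele": {"oa", "a2", "nea", "other_allele", "allele2", "non_effect_allele"},
    "eaf": {"eaf", "frq", "freq", "effect_allele_frequency", "af"},
    "beta": {"beta", "b", "effect", "effect_size"},
    "se": {"se", "stderr", "standard_error"},
    "p": {"p", "pval", "pvalue", "p_value"},
    "n": {"n", "samplesize", "sample_size"},
}
_GWAS_OUT_COLS = {"snp": "SNP", "chr": "CHR", "pos": "POS", "effect_allele": "EA",
                  "other_allele": "OA", "eaf": "EAF", "beta": "BETA", "se": "SE",
                  "p": "P", "n": "N"}


def read_gwas(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a GWAS summary-statistics table, mapping header synonyms.

    ``column_map`` maps raw column names to canonical ones and overrides
    the synonym table.  Rows with non-positive SE or a p-value outside
    (0, 1] are rejected with their row numbers logged.
    """
    raw = pd.read_csv(path, sep=None, engine="python")
    rename = {}
    cmap = {k.lower(): v for k, v in (column_map or {}).items()}
    for col in raw.columns:
        low = col.strip().lower()
        if low in cmap:
            rename[col] = cmap[low]
            continue
        for canon, syns in _GWAS_SYNONYMS.items():
            if low in syns:
                rename[col] = canon
                break
    df = raw.rename(columns=rename)
    missing = [c for c in ("snp", "effect_allele", "other_allele", "beta", "se")
               if c not in df.columns]
    if missing:
        raise ValueError(f"GWAS table {path} missing columns: {missing}")
    bad = pd.Series(False, index=df.index)
    bad |= ~np.isfinite(df["se"]) | (df["se"] <= 0)
    if "p" in df.columns:
        bad |= ~((df["p"] > 0) & (df["p"] <= 1))
    if bad.any():
        logger.warning("%s: rejected %d malformed rows (rows %s)", path,
                       int(bad.sum()), (df.index[bad] + 2).tolist()[:10])
    return df.loc[~bad].reset_index(drop=True)


def write_gwas(df: pd.DataFrame, path) -> None:
    """Write summary statistics in the canonical tab-delimited layout."""
    cols = [c for c in _GWAS_OUT_COLS if c in df.columns]
    out = df[cols].rename(columns=_GWAS_OUT_COLS)
    out.to_csv(path, sep="\t", index=False)


_WEIGHT_SYNONYMS = {"rsid": "variant_id", "variant_id": "variant_id",
                    "chr_name": "chr", "chr": "chr",
                    "chr_position": "pos", "pos": "pos",
                    "effect_allele": "effect_allele", "other_allele": "other_allele",
                    "effect_weight": "weight", "weight": "weight",
                    "eaf": "eaf", "allelefrequency_effect": "eaf",
                    "imputation_r2": "imputation_r2"}


def read_weight_table(path) -> pd.DataFrame:
    """Read a PGS-catalog-style variant weight table (tab-delimited)."""
    raw = pd.read_csv(path, sep="\t", comment="#")
    df = raw.rename(columns={c: _WEIGHT_SYNONYMS[c.lower()]
                             for c in raw.columns if c.lower() in _WEIGHT_SYNONYMS})
    for col in ("variant_id", "effect_allele", "other_allele", "weight"):
        if col not in df.columns:
            raise ValueError(f"weight table {path} missing column {col!r}")
    return prsmod.validate_weight_table(df)


def write_weight_table(df: pd.DataFrame, path) -> None:
    out = df.rename(columns={"variant_id": "rsID", "weight": "effect_weight"})
    out.to_csv(path, sep="\t", index=False)


def write_dosages(dosages: DosageMatrix, path) -> None:
    """Dosage TSV: two allele header rows, then one row per individual."""
    with open(path, "w") as fh:
        fh.write("id\t" + "\t".join(dosages.variants) + "\n")
        fh.write("#coded\t" + "\t".join(dosages.coded_alleles[v] for v in dosages.variants) + "\n")
        fh.write("#other\t" + "\t".join(dosages.other_alleles[v] for v in dosages.variants) + "\n")
        dosages.values.to_csv(fh, sep="\t", header=False)


def read_dosages(path) -> DosageMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
        coded = fh.readline().rstrip("\n").split("\t")[1:]
        other = fh.readline().rstrip("\n").split("\t")[1:]
        values = pd.read_csv(fh, sep="\t", header=None, index_col=0)
    values.columns = header
    values.index.name = "id"
    return DosageMatrix(values,
                        pd.Series(coded, index=header),
                        pd.Series(other, index=header))


@dataclass
class RunConfig:
    """Declarative pipeline configuration (YAML-serializable)."""

    out_dir: str = "prsmed_run"
    seed: int = 0
    n_individuals: int = 5000
    n_variants: int = 200
    n_instruments: int = 10
    causal_theta: float = float(np.log(2.34))
    n_draws: int = 1000
    min_r2: float = 0.8
    min_maf: float = 0.01
    p_thresh: float = 5e-8
    clump_kb: float = 10_000
    clump_r2: float = 0.001
    auc_repeats: int = 100
    covariates: tuple = ("age", "sex", "bmi", "pc1", "pc2", "pc3", "pc4", "pc5")
    paths: dict = field(default_factory=dict)  # optional external inputs

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for key, p in cfg.paths.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"config path {key!r} does not exist: {p}")
        if not (0 < cfg.min_maf < 0.5 and 0 < cfg.min_r2 <= 1 and 0 < cfg.p_thresh < 1):
            raise ValueError("thresholds out of documented ranges")
        return cfg


def run_pipeline(cfg: RunConfig) -> Path:
    """Run simulate -> score -> combine -> associate -> mediate -> MR.

    Every stage writes a tidy CSV into the run directory; the seed and
    the full configuration are echoed so a re-run with the same config is
    bit-identical.  Returns the run directory path.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    logging.getLogger().addHandler(fh)
    (out / "config_echo.yaml").write_text(yaml.safe_dump(asdict(cfg)))

    try:
        # ---- simulate ----------------------------------------------------
        sim = simulate_admixed_cohort(CohortSimConfig(
            n_individuals=cfg.n_individuals, n_variants=cfg.n_variants,
            seed=cfg.seed))
        sim.cohort.to_csv(out / "cohort.csv")
        write_dosages(sim.dosages, out / "dosages.tsv")
        for anc, tab in sim.weight_tables.items():
            write_weight_table(tab, out / f"weights_{anc}.tsv")
        logger.info("simulated cohort n=%d, m=%d, seed=%d",
                    cfg.n_individuals, cfg.n_variants, cfg.seed)

        # ---- score + combine ---------------------------------------------
        std = {}
        for anc, tab in sim.weight_tables.items():
            filt = prsmod.filter_variants(tab, cfg.min_r2, cfg.min_maf)
            std[anc] = prsmod.standardize_prs(
                prsmod.score_prs(sim.dosages, filt, label=anc))
        prssum = prsmod.combine_prssum(std)
        gap = prsmod.combine_gapprssum(std, sim.proportions)
        cohort = add_derived_phenotypes(sim.cohort)
        ext = cohort.copy()
        for anc in std:
            ext[f"prs_{anc}"] = std[anc].scores
        ext["dm"] = (ext["dm_status_v1"] == "diabetic").astype(float)
        wts = prsmod.estimate_combination_weights(
            ext, [f"prs_{anc}" for anc in std], outcome_col="dm")
        mgb = prsmod.combine_weighted(
            std, prsmod.CombinationWeights({a: wts.weights[f"prs_{a}"] for a in std}))
        scores = pd.DataFrame({"PRSsum": prssum.scores, "gapPRSsum": gap.scores,
                               "mgbPRSsum": mgb.scores})
        scores.to_csv(out / "prs_scores.csv")
        cohort = cohort.join(scores)

        # ---- association ---------------------------------------------------
        covs = list(cfg.covariates)
        assoc_rows = []
        cohort["dm_v1"] = (cohort["dm_status_v1"] == "diabetic").astype(float)
        for name in ("PRSsum", "gapPRSsum", "mgbPRSsum"):
            fit = surv.SurveyGLM(cohort["dm_v1"], cohort[[name] + covs],
                                 cohort["weight_v1"], family="logistic").fit()
            row = fit.summary().loc[name]
            assoc_rows.append({"prs": name, "outcome": "dm_v1", **row.to_dict()})
        at_risk = cohort[cohort["incident_dm_count"].notna()].copy()
        at_risk["log_followup"] = np.log(at_risk["followup_years"])
        for name in ("PRSsum", "gapPRSsum", "mgbPRSsum"):
            fit = surv.SurveyGLM(at_risk["incident_dm_count"],
                                 at_risk[[name] + covs], at_risk["weight_v2"],
                                 family="poisson",
                                 offset=np.log(at_risk["followup_years"])).fit()
            row = fit.summary().loc[name]
            assoc_rows.append({"prs": name, "outcome": "incident_dm", **row.to_dict()})
        pd.DataFrame(assoc_rows).to_csv(out / "associations.csv", index=False)

        # stratified + interaction by OSA category
        strata = surv.stratified_association(
            at_risk.dropna(subset=["osa_category"]).query("osa_category != 'missing'"),
            "osa_category",
            "incident_dm_count ~ mgbPRSsum + " + " + ".join(covs),
            "weight_v2", family="poisson", offset_col="log_followup")
        srows = []
        for level, f in strata.items():
            if f is None:
                srows.append({"stratum": level, "skipped": True})
            else:
                srows.append({"stratum": level, "skipped": False,
                              **f.summary().loc["mgbPRSsum"].to_dict()})
        pd.DataFrame(srows).to_csv(out / "stratified.csv", index=False)

        # ---- mediation -----------------------------------------------------
        med_data = at_risk.dropna(subset=["osa_mild_severe"]).copy()
        med_data["osa_mild_severe"] = med_data["osa_mild_severe"].astype(float)
        model = med.MediationModel(
            med_data, "mgbPRSsum", "osa_mild_severe", "incident_dm_count",
            covs, "weight_v2", "followup_years")
        res = model.fit(n_draws=cfg.n_draws, seed=cfg.seed)
        res.summary().to_csv(out / "mediation.csv")

        # ---- MR ------------------------------------------------------------
        exp_ss, out_ss, truth = simulate_two_sample_gwas(GwasSimConfig(
            n_instruments=cfg.n_instruments, causal_theta=cfg.causal_theta,
            seed=cfg.seed))
        write_gwas(exp_ss, out / "gwas_exposure.tsv")
        write_gwas(out_ss, out / "gwas_outcome.tsv")
        snps = mrmod.select_instruments(exp_ss, out_ss, p_thresh=cfg.p_thresh,
                                        clump_kb=cfg.clump_kb, clump_r2=cfg.clump_r2)
        h = mrmod.harmonize(exp_ss, out_ss, snps=snps)
        h.to_csv(out / "harmonized.tsv", sep="\t", index=False)
        mr_model = mrmod.MRModel(h)
        mr_tab = mr_model.fit_all(("ivw", "egger", "weighted_median", "raps"))
        mr_tab["true_theta"] = truth.true_theta
        mr_tab.to_csv(out / "mr_results.csv", index=False)

        logger.info("pipeline complete: %s", out)
        return out
    finally:
        logging.getLogger().removeHandler(fh)
        fh.close()
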