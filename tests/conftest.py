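import numpy as np
import pandas as pd
import pytest

from prsmed.phenotypes import add_derived_phenotypes
from prsmed.synthetic import (CohortSimConfig, GwasSimConfig,
                              simulate_admixed_cohort, simulate_two_sample_gwas)

COVARIATES = ["age", "sex", "bmi", "pc1", "pc2", "pc3", "pc4", "pc5"]


@pytest.fixture(scope="session")
def default_sim():
    """Default synthetic cohort (n=5000) with derived phenotypes attached."""
    sim = simulate_admixed_cohort(CohortSimConfig(seed=1))
    sim.cohort_derived = add_derived_phenotypes(sim.cohort)
    return sim


@pytest.fixture(scope="session")
def at_risk(default_sim):
    """At-risk subcohort for incidence/mediation analyses."""
    d = default_sim.cohort_derived
    ar = d[d["incident_dm_count"].notna()].dropna(subset=["osa_mild_severe"]).copy()
    ar["osa_mild_severe"] = ar["osa_mild_severe"].astype(float)
    return ar


@pytest.fixture(scope="session")
def gwas_pair():
    """Default two-sample GWAS (theta = log 2.34, no pleiotropy)."""
    return simulate_two_sample_gwas(GwasSimConfig(seed=11))


@pytest.fixture()
def tiny_weight_table():
    return pd.DataFrame({
        "variant_id": ["rs1", "rs2", "rs3"],
        "chr": [1, 2, 3],
        "pos": [100, 200, 300],
        "effect_allele": ["A", "G", "C"],
        "other_allele": ["G", "T", "A"],
        "weight": [0.5, -0.2, 0.1],
        "eaf": [0.3, 0.5, 0.2],
        "imputation_r2": [0.95, 0.9, 0.99],
    })


def make_dosages(values, coded, other, ids=None, vids=None):
    from prsmed.prs import DosageMatrix
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    ids = ids or [f"i{k}" for k in range(n)]
    vids = vids or [f"rs{k+1}" for k in range(m)]
    return DosageMatrix(
        pd.DataFrame(values, index=ids, columns=vids),
        pd.Series(list(coded), index=vids),
        pd.Series(list(other), index=vids),
    )
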