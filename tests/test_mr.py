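"""MR suite: meta-analysis, instrument selection, harmonization, estimators."""

import numpy as np
import pandas as pd
import pytest

from prsmed.mr import (MRModel, harmonize, ivw_meta_analyze, mr_egger, mr_ivw,
                       mr_mode, mr_presso, mr_raps, mr_wald_ratio,
                       mr_weighted_median, mvmr_ivw, select_instruments)
from prsmed.synthetic import GwasSimConfig, simulate_two_sample_gwas


def _ss(snp, ea, oa, beta, se, **kw):
    base = {"snp": snp, "effect_allele": ea, "other_allele": oa,
            "beta": beta, "se": se}
    base.update(kw)
    return pd.DataFrame(base)


class TestMetaAnalysis:
    def test_identical_studies(self):
        a = _ss(["rs1"], ["A"], ["G"], [0.1], [0.1])
        out = ivw_meta_analyze(a, a.copy())
        assert out.loc[0, "beta"] == pytest.approx(0.1)
        assert out.loc[0, "se"] == pytest.approx(0.1 / np.sqrt(2))

    def test_huge_se_study_ignored(self):
        a = _ss(["rs1"], ["A"], ["G"], [0.1], [0.05])
        b = _ss(["rs1"], ["A"], ["G"], [9.9], [1e6])
        out = ivw_meta_analyze(a, b)
        assert out.loc[0, "beta"] == pytest.approx(0.1, abs=1e-6)

    def test_flipped_alleles_sign_corrected(self):
        a = _ss(["rs1", "rs2"], ["A", "C"], ["G", "T"], [0.1, -0.2], [0.1, 0.1])
        b = _ss(["rs1", "rs2"], ["G", "C"], ["A", "T"], [-0.1, -0.2], [0.1, 0.1])
        out = ivw_meta_analyze(a, b).set_index("snp")
        assert out.loc["rs1", "beta"] == pytest.approx(0.1)
        assert out.loc["rs2", "beta"] == pytest.approx(-0.2)

    def test_unshared_snps_dropped(self):
        a = _ss(["rs1", "rs2"], ["A", "C"], ["G", "T"], [0.1, 0.2], [0.1, 0.1])
        b = _ss(["rs1"], ["A"], ["G"], [0.1], [0.1])
        assert len(ivw_meta_analyze(a, b)) == 1


class TestInstrumentSelection:
    def _exposure(self):
        return _ss(["rs1", "rs2", "rs3"], ["A"] * 3, ["G"] * 3,
                   [0.1, 0.09, 0.08], [0.01] * 3,
                   chr=[1, 1, 1], pos=[1000, 2000, 3000],
                   p=[1e-10, 1e-9, 1e-8], eaf=[0.3, 0.3, 0.3])

    def test_correlated_window_keeps_lowest_p(self):
        exp = self._exposure()
        out = _ss(["rs1", "rs2", "rs3"], ["A"] * 3, ["G"] * 3, [0.0] * 3, [0.01] * 3)
        ld = pd.DataFrame(0.5, index=exp["snp"], columns=exp["snp"])
        np.fill_diagonal(ld.values, 1.0)
        assert select_instruments(exp, out, ld=ld) == ["rs1"]

    def test_independent_all_kept(self):
        exp = self._exposure()
        out = _ss(["rs1", "rs2", "rs3"], ["A"] * 3, ["G"] * 3, [0.0] * 3, [0.01] * 3)
        ld = pd.DataFrame(np.eye(3), index=exp["snp"], columns=exp["snp"])
        assert sorted(select_instruments(exp, out, ld=ld)) == ["rs1", "rs2", "rs3"]

    def test_p_tie_breaks_by_position(self):
        exp = self._exposure()
        exp["p"] = [1e-9, 1e-9, 1e-8]
        exp.loc[1, "pos"] = 500  # rs2 earlier than rs1
        ld = pd.DataFrame(1.0, index=exp["snp"], columns=exp["snp"])
        assert select_instruments(exp, _ss(exp["snp"], ["A"] * 3, ["G"] * 3,
                                           [0.0] * 3, [0.01] * 3), ld=ld) == ["rs2"]

    def test_distant_snps_not_clumped(self):
        exp = self._exposure()
        exp["pos"] = [1, 20_000_000_000, 40_000_000_000]  # > 10,000 kb apart
        ld = pd.DataFrame(1.0, index=exp["snp"], columns=exp["snp"])
        out = _ss(exp["snp"], ["A"] * 3, ["G"] * 3, [0.0] * 3, [0.01] * 3)
        assert len(select_instruments(exp, out, ld=ld)) == 3

    def test_empty_steps_raise_with_stage_name(self):
        exp = self._exposure()
        out = _ss(["rsX"], ["A"], ["G"], [0.0], [0.01])
        with pytest.raises(ValueError, match="shared"):
            select_instruments(exp, out)
        out2 = _ss(exp["snp"], ["A"] * 3, ["G"] * 3, [0.0] * 3, [0.01] * 3)
        with pytest.raises(ValueError, match="p <"):
            select_instruments(exp.assign(p=0.5), out2)


class TestHarmonize:
    def test_swapped_alleles_flip_outcome(self):
        exp = _ss(["rs1"], ["A"], ["G"], [0.1], [0.01])
        out = _ss(["rs1"], ["G"], ["A"], [0.2], [0.02])
        h = harmonize(exp, out)
        assert h.loc[0, "beta_outcome"] == pytest.approx(-0.2)
        assert bool(h.loc[0, "flipped"])

    def test_complement_strand_aligned(self):
        exp = _ss(["rs1"], ["A"], ["G"], [0.1], [0.01])
        out = _ss(["rs1"], ["T"], ["C"], [0.2], [0.02])
        h = harmonize(exp, out)
        assert len(h) == 1
        assert h.loc[0, "beta_outcome"] == pytest.approx(0.2)
        assert bool(h.loc[0, "strand_corrected"])

    def test_palindromic_high_maf_dropped(self):
        exp = _ss(["rs1"], ["A"], ["T"], [0.1], [0.01], eaf=[0.5])
        out = _ss(["rs1"], ["A"], ["T"], [0.2], [0.02], eaf=[0.5])
        assert harmonize(exp, out).empty

    def test_palindromic_low_maf_oriented_by_frequency(self):
        exp = _ss(["rs1"], ["A"], ["T"], [0.1], [0.01], eaf=[0.1])
        out_same = _ss(["rs1"], ["A"], ["T"], [0.2], [0.02], eaf=[0.12])
        out_opp = _ss(["rs1"], ["A"], ["T"], [0.2], [0.02], eaf=[0.88])
        assert harmonize(exp, out_same).loc[0, "beta_outcome"] == pytest.approx(0.2)
        assert harmonize(exp, out_opp).loc[0, "beta_outcome"] == pytest.approx(-0.2)

    def test_incompatible_pair_dropped(self):
        exp = _ss(["rs1"], ["A"], ["G"], [0.1], [0.01])
        out = _ss(["rs1"], ["A"], ["C"], [0.2], [0.02])
        assert harmonize(exp, out).empty

    def test_idempotent(self, gwas_pair):
        exp, out, _ = gwas_pair
        h1 = harmonize(exp, out)
        # re-harmonizing the harmonized set against the exposure is a no-op
        out_h = h1.rename(columns={"beta_outcome": "beta", "se_outcome": "se"})[
            ["snp", "effect_allele", "other_allele", "beta", "se"]]
        out_h["eaf"] = h1["eaf_exposure"]
        h2 = harmonize(exp, out_h)
        assert np.allclose(h1["beta_outcome"], h2["beta_outcome"])


@pytest.fixture()
def printed_fixture():
    """3-SNP set with exact WLS solution b = 0.5, Q = 0."""
    return pd.DataFrame({
        "snp": ["rs1", "rs2", "rs3"],
        "beta_exposure": [0.1, 0.2, 0.3], "se_exposure": [0.01] * 3,
        "beta_outcome": [0.05, 0.10, 0.15], "se_outcome": [0.01] * 3,
    })


class TestEstimators:
    def test_wald_ratio(self):
        h = pd.DataFrame({"snp": ["rs1"], "beta_exposure": [0.1],
                          "se_exposure": [0.01], "beta_outcome": [0.05],
                          "se_outcome": [0.02]})
        r = mr_wald_ratio(h)
        assert r.estimate == pytest.approx(0.5)
        assert r.se == pytest.approx(0.2)
        h_neg = h.assign(beta_exposure=-0.1)
        assert mr_wald_ratio(h_neg).estimate == pytest.approx(-0.5)
        assert mr_wald_ratio(h.assign(beta_outcome=0.0)).estimate == 0.0

    def test_ivw_closed_form(self, printed_fixture):
        r = mr_ivw(printed_fixture)
        assert r.estimate == pytest.approx(0.5, abs=1e-12)
        assert r.q == pytest.approx(0.0, abs=1e-12)
        # Q=0: no inflation, fixed-effect SE 1/sqrt(sum bx^2/se^2)
        assert r.se == pytest.approx(1 / np.sqrt(np.sum(
            np.array([0.1, 0.2, 0.3]) ** 2 / 0.01**2)))

    def test_ivw_single_snp_equals_wald(self):
        h = pd.DataFrame({"snp": ["rs1"], "beta_exposure": [0.2],
                          "se_exposure": [0.01], "beta_outcome": [0.1],
                          "se_outcome": [0.03]})
        assert MRModel(h).fit("ivw").estimate == pytest.approx(
            mr_wald_ratio(h).estimate)

    def test_ivw_k_identical_rows(self):
        h1 = pd.DataFrame({"snp": ["rs1"], "beta_exposure": [0.1],
                           "se_exposure": [0.0], "beta_outcome": [0.05],
                           "se_outcome": [0.02]})
        h4 = pd.concat([h1] * 4, ignore_index=True)
        r1, r4 = mr_wald_ratio(h1), mr_ivw(h4, random_effects=False)
        assert r4.estimate == pytest.approx(r1.estimate)
        assert r4.se == pytest.approx(r1.se / 2)

    def test_ivw_recovery_simulation(self):
        theta = np.log(2.3)
        e, o, t = simulate_two_sample_gwas(GwasSimConfig(
            n_instruments=20, causal_theta=theta, seed=42))
        r = mr_ivw(harmonize(e, o))
        assert abs(r.estimate - theta) < 2 * r.se

    def test_snp_order_invariance(self, printed_fixture):
        shuffled = printed_fixture.sample(frac=1, random_state=3).reset_index(drop=True)
        for f in (mr_ivw, mr_egger, mr_raps):
            assert f(shuffled).estimate == pytest.approx(f(printed_fixture).estimate)

    def test_joint_recoding_invariance(self, printed_fixture):
        """Flipping both betas of one SNP leaves every estimator unchanged."""
        flipped = printed_fixture.copy()
        flipped.loc[0, ["beta_exposure", "beta_outcome"]] *= -1
        for f in (mr_ivw, mr_egger, mr_raps,
                  lambda h: mr_weighted_median(h, n_boot=50)):
            assert f(flipped).estimate == pytest.approx(f(printed_fixture).estimate)

    def test_egger_exact_on_clean_fixture(self, printed_fixture):
        r = mr_egger(printed_fixture)
        assert r.estimate == pytest.approx(0.5, abs=1e-10)
        assert r.egger_intercept == pytest.approx(0.0, abs=1e-10)

    def test_egger_detects_directional_pleiotropy(self):
        ints = []
        for s in range(25):
            e, o, _ = simulate_two_sample_gwas(GwasSimConfig(
                n_instruments=30, beta_sd=0.1, pleiotropy_mean=0.02,
                pleiotropy_sd=0.005, seed=s))
            ints.append(mr_egger(harmonize(e, o)).egger_intercept)
        assert np.mean(ints) == pytest.approx(0.02, abs=0.005)

    def test_egger_intercept_coverage_under_null(self):
        cover = 0
        for s in range(40):
            e, o, _ = simulate_two_sample_gwas(GwasSimConfig(
                n_instruments=30, beta_sd=0.1, seed=100 + s))
            r = mr_egger(harmonize(e, o))
            lo = r.egger_intercept - 1.96 * r.egger_intercept_se
            hi = r.egger_intercept + 1.96 * r.egger_intercept_se
            cover += lo <= 0 <= hi
        assert cover / 40 >= 0.85

    def test_weighted_median_equal_weights_is_median(self):
        h = pd.DataFrame({"snp": list("abcde"),
                          "beta_exposure": [1.0] * 5, "se_exposure": [1e-8] * 5,
                          "beta_outcome": [0.1, 0.2, 0.3, 0.4, 0.5],
                          "se_outcome": [0.1] * 5})
        r = mr_weighted_median(h, n_boot=50)
        assert r.estimate == pytest.approx(0.3)

    def test_weighted_median_breakdown(self):
        theta = 0.5
        rng = np.random.default_rng(8)
        k_valid, k_bad = 11, 10
        bx = rng.uniform(0.1, 0.3, k_valid + k_bad)
        by = theta * bx
        by[k_valid:] += 5.0  # gross pleiotropy in 10/21 instruments
        h = pd.DataFrame({"snp": [f"rs{i}" for i in range(k_valid + k_bad)],
                          "beta_exposure": bx, "se_exposure": 0.001,
                          "beta_outcome": by, "se_outcome": 0.01})
        r = mr_weighted_median(h, n_boot=100)
        assert r.estimate == pytest.approx(theta, abs=0.05)

    def test_mode_prefers_heavier_cluster(self):
        h = pd.DataFrame({"snp": [f"rs{i}" for i in range(9)],
                          "beta_exposure": [1.0] * 9, "se_exposure": [1e-6] * 9,
                          "beta_outcome": [0.5] * 6 + [2.0] * 3,
                          "se_outcome": [0.01] * 9})
        r = mr_mode(h, n_boot=50)
        assert r.estimate == pytest.approx(0.5, abs=0.1)

    def test_mode_all_identical(self):
        h = pd.DataFrame({"snp": ["a", "b", "c"], "beta_exposure": [1.0] * 3,
                          "se_exposure": [1e-6] * 3, "beta_outcome": [0.7] * 3,
                          "se_outcome": [0.01] * 3})
        assert mr_mode(h, n_boot=20).estimate == pytest.approx(0.7, abs=1e-3)

    def test_raps_limit_equals_fixed_effect_ivw(self, printed_fixture):
        h = printed_fixture.assign(se_exposure=1e-12)
        assert mr_raps(h).estimate == pytest.approx(
            mr_ivw(h, random_effects=False).estimate, abs=1e-6)

    def test_raps_sign_antisymmetry(self, printed_fixture):
        h = printed_fixture.assign(beta_outcome=lambda d: -d["beta_outcome"])
        assert mr_raps(h).estimate == pytest.approx(
            -mr_raps(printed_fixture).estimate, abs=1e-8)

    def test_raps_less_biased_than_ivw_with_weak_instruments(self):
        theta = 0.5
        rng = np.random.default_rng(13)
        reps = 60
        err_ivw, err_raps = [], []
        for _ in range(reps):
            k = 40
            b = rng.normal(0, 0.02, k)
            sx = np.full(k, 0.01)
            sy = np.full(k, 0.01)
            bx = b + rng.normal(0, sx)
            by = theta * b + rng.normal(0, sy)
            h = pd.DataFrame({"snp": range(k), "beta_exposure": bx,
                              "se_exposure": sx, "beta_outcome": by,
                              "se_outcome": sy})
            err_ivw.append(mr_ivw(h).estimate - theta)
            err_raps.append(mr_raps(h).estimate - theta)
        assert abs(np.mean(err_raps)) < abs(np.mean(err_ivw))


class TestPresso:
    def test_injected_outlier_flagged(self, gwas_pair):
        exp, out, _ = gwas_pair
        h = harmonize(exp, out)
        h.loc[0, "beta_outcome"] += 10 * h.loc[0, "se_outcome"]
        r = mr_presso(h, n_dist=2000, seed=5)
        assert 0 in r.outliers
        assert r.global_p < 0.05

    def test_clean_data_rarely_flagged(self, gwas_pair):
        exp, out, _ = gwas_pair
        r = mr_presso(harmonize(exp, out), n_dist=2000, seed=6)
        assert r.outliers == []

    def test_small_ndist_p_bounds(self, gwas_pair):
        exp, out, _ = gwas_pair
        r = mr_presso(harmonize(exp, out), n_dist=100, seed=7)
        assert 1 / 100 <= r.global_p <= 1.0

    def test_outlier_corrected_estimate_improves(self, gwas_pair):
        exp, out, truth = gwas_pair
        h = harmonize(exp, out)
        h.loc[0, "beta_outcome"] += 10 * h.loc[0, "se_outcome"]
        raw = mr_ivw(h)
        corrected = mr_presso(h, n_dist=2000, seed=8)
        assert abs(corrected.estimate - truth.true_theta) < abs(
            raw.estimate - truth.true_theta)


class TestMvmr:
    def _mvmr_h(self, theta1, theta2, seed=0, k=30, noise=True):
        rng = np.random.default_rng(seed)
        bx1 = rng.uniform(0.05, 0.3, k) * rng.choice([-1, 1], k)
        bx2 = rng.uniform(0.05, 0.3, k) * rng.choice([-1, 1], k)
        sy = np.full(k, 0.01)
        by = theta1 * bx1 + theta2 * bx2
        if noise:
            by = by + rng.normal(0, sy)
        return pd.DataFrame({"snp": [f"rs{i}" for i in range(k)],
                             "beta_exposure": bx1, "se_exposure": 0.005,
                             "beta_exposure2": bx2, "se_exposure2": 0.005,
                             "beta_outcome": by, "se_outcome": sy})

    def test_joint_recovery(self):
        res = mvmr_ivw(self._mvmr_h(0.7, 0.3, seed=1))
        assert abs(res[0].estimate - 0.7) < 2 * res[0].se
        assert abs(res[1].estimate - 0.3) < 2 * res[1].se

    def test_nesting_reduces_to_univariate(self):
        h = self._mvmr_h(0.6, 0.0, seed=2)
        # second exposure essentially null: negligible betas
        rng = np.random.default_rng(4)
        h["beta_exposure2"] = rng.normal(0, 1e-6, len(h))
        res = mvmr_ivw(h)
        uni = mr_ivw(h)
        assert res[0].estimate == pytest.approx(uni.estimate, abs=1e-3)

    def test_collinear_exposures_error(self):
        h = self._mvmr_h(0.5, 0.5, seed=3)
        h["beta_exposure2"] = 2.0 * h["beta_exposure"]
        with pytest.raises(ValueError, match="condition number"):
            mvmr_ivw(h)


class TestMRModel:
    def test_fit_all_table(self, gwas_pair):
        exp, out, truth = gwas_pair
        model = MRModel(harmonize(exp, out))
        tab = model.fit_all(("ivw", "egger", "weighted_median", "raps"))
        assert set(tab["method"]) == {"ivw", "egger", "weighted_median", "raps"}
        ivw_row = tab[tab["method"] == "ivw"].iloc[0]
        assert ivw_row["OR_ci_low"] < np.exp(truth.true_theta) < ivw_row["OR_ci_high"]

    def test_unknown_method(self, gwas_pair):
        exp, out, _ = gwas_pair
        with pytest.raises(ValueError, match="unknown"):
            MRModel(harmonize(exp, out)).fit("banana")
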