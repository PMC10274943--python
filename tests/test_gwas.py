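"""Additive-model association, IVW meta-analysis, replication criteria,
threshold derivation and genomic inflation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metaboqtl import gwas, syndata
from metaboqtl.gwas import (
    SignificanceCriteria,
    apply_replication_criteria,
    derive_studywide_threshold,
    fit_additive_model,
    genomic_inflation,
    ivw_meta,
    run_mgwas,
)

from conftest import make_metabolite_matrix


class TestFitAdditiveModel:
    def test_noiseless_relationship(self):
        rng = np.random.default_rng(0)
        dose = rng.binomial(2, 0.3, 100).astype(float)
        fit = fit_additive_model(2.0 * dose, dose)
        assert fit["beta"] == pytest.approx(2.0, abs=1e-10)
        assert fit["p"] == pytest.approx(0.0, abs=1e-200)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = rng.integers(30, 120)
            dose = rng.binomial(2, rng.uniform(0.1, 0.5), n).astype(float)
            C = rng.normal(size=(n, 2))
            y = rng.normal(size=n) + 0.2 * dose
            fit = fit_additive_model(y, dose, C)
            X = np.column_stack([np.ones(n), dose, C])
            beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ beta_oracle
            sigma2 = resid @ resid / (n - X.shape[1])
            se_oracle = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
            assert fit["beta"] == pytest.approx(beta_oracle[1], abs=1e-10)
            assert fit["se"] == pytest.approx(se_oracle, abs=1e-10)

    def test_null_pvalues_uniform(self):
        g = syndata.simulate_genotypes(400, 2000, seed=3)
        rng = np.random.default_rng(4)
        y = rng.normal(size=400)
        ss = syndata.gwas_scan(y, g)
        _, p = stats.kstest(ss["P"], "uniform")
        assert p > 0.01

    def test_type_one_error_within_exact_binomial_interval(self):
        # 10,000 independent null tests at alpha = 0.05
        g = syndata.simulate_genotypes(300, 10_000, ld_block_size=1, seed=5)
        rng = np.random.default_rng(6)
        y = rng.normal(size=300)
        ss = syndata.gwas_scan(y, g)
        rejections = int((ss["P"] < 0.05).sum())
        lo, hi = stats.binom.interval(0.99, len(ss), 0.05)
        assert lo <= rejections <= hi

    def test_constant_dosage_non_testable(self):
        fit = fit_additive_model(np.random.default_rng(0).normal(size=50),
                                 np.ones(50))
        assert not fit["testable"]

    def test_missing_y_dropped_casewise(self):
        rng = np.random.default_rng(7)
        dose = rng.binomial(2, 0.4, 100).astype(float)
        y = 0.5 * dose + rng.normal(size=100)
        y[:20] = np.nan
        fit = fit_additive_model(y, dose)
        assert fit["n"] == 80


class TestRunMgwas:
    def test_planted_qtl_recovered(self, large_geno):
        qtl = syndata.QtlSpec("M000", large_geno.variant_ids[10], 0.3)
        met, _ = syndata.simulate_metabolome(large_geno, [qtl], 2, seed=8)
        ss = run_mgwas(met, large_geno)
        hit = ss[(ss["phenotype"] == "M000") & (ss["SNP"] == qtl.variant_id)]
        assert abs(hit["BETA"].iloc[0] - 0.3) < 3 * hit["SE"].iloc[0]

    def test_orthogonal_covariate_leaves_beta_unchanged(self, small_geno):
        rng = np.random.default_rng(9)
        met, _ = syndata.simulate_metabolome(small_geno, [], 1, seed=9)
        raw_cov = rng.normal(size=small_geno.n_samples)
        # orthogonalize the covariate against every dosage and the intercept
        X = np.column_stack([np.ones(small_geno.n_samples), small_geno.dosages])
        Q, _ = np.linalg.qr(X)
        cov = raw_cov - Q @ (Q.T @ raw_cov)
        cov_df = pd.DataFrame({"c": cov}, index=small_geno.samples)
        s0 = run_mgwas(met, small_geno)
        s1 = run_mgwas(met, small_geno, covariates=cov_df)
        assert np.allclose(s0["BETA"], s1["BETA"], atol=1e-8)

    def test_row_count_bookkeeping(self, small_geno):
        met, _ = syndata.simulate_metabolome(small_geno, [], 3, seed=10)
        ss = run_mgwas(met, small_geno)
        assert len(ss) == 3 * small_geno.n_variants

    def test_no_overlap_raises(self, small_geno):
        met, _ = syndata.simulate_metabolome(small_geno, [], 1, seed=11)
        met.values.index = ["X" + s for s in met.values.index]
        with pytest.raises(ValueError):
            run_mgwas(met, small_geno)


def _stats_row(phen, snp, beta, se, freq=0.3, a1="G", a2="A", n=100, bp=1000):
    z = beta / se
    return {
        "phenotype": phen, "SNP": snp, "CHR": "1", "BP": bp, "A1": a1,
        "A2": a2, "FREQ": freq, "BETA": beta, "SE": se,
        "P": 2 * stats.norm.sf(abs(z)), "N": n,
    }


class TestIvwMeta:
    def test_equal_studies_closed_form(self):
        s = pd.DataFrame([_stats_row("m", "v", 0.5, 0.1)])
        meta = ivw_meta([s, s.copy()])
        assert meta["BETA"].iloc[0] == pytest.approx(0.5)
        assert meta["SE"].iloc[0] == pytest.approx(0.1 / np.sqrt(2), rel=1e-12)

    def test_opposite_effects_cancel(self):
        s1 = pd.DataFrame([_stats_row("m", "v", 0.5, 0.1)])
        s2 = pd.DataFrame([_stats_row("m", "v", -0.5, 0.1)])
        meta = ivw_meta([s1, s2])
        assert meta["BETA"].iloc[0] == pytest.approx(0.0, abs=1e-15)

    def test_three_studies_match_weighted_mean_oracle(self):
        rng = np.random.default_rng(12)
        betas = rng.normal(size=3)
        ses = rng.uniform(0.05, 0.3, size=3)
        studies = [pd.DataFrame([_stats_row("m", "v", b, s)])
                   for b, s in zip(betas, ses)]
        meta = ivw_meta(studies)
        w = 1 / ses**2
        assert meta["BETA"].iloc[0] == pytest.approx((betas * w).sum() / w.sum(),
                                                     abs=1e-12)
        assert meta["SE"].iloc[0] == pytest.approx(np.sqrt(1 / w.sum()), abs=1e-12)

    def test_single_study_identity(self):
        s = pd.DataFrame([_stats_row("m", "v", 0.4, 0.2)])
        meta = ivw_meta([s])
        assert meta["BETA"].iloc[0] == pytest.approx(0.4)
        assert meta["SE"].iloc[0] == pytest.approx(0.2)

    def test_meta_se_never_exceeds_any_study_se(self):
        rng = np.random.default_rng(13)
        ses = rng.uniform(0.05, 0.5, size=4)
        studies = [pd.DataFrame([_stats_row("m", "v", 0.1, s)]) for s in ses]
        meta = ivw_meta(studies)
        assert meta["SE"].iloc[0] <= ses.min() + 1e-15

    def test_swapped_alleles_flipped(self):
        s1 = pd.DataFrame([_stats_row("m", "v", 0.5, 0.1, a1="G", a2="A")])
        s2 = pd.DataFrame([_stats_row("m", "v", -0.5, 0.1, a1="A", a2="G",
                                      freq=0.7)])
        meta = ivw_meta([s1, s2])
        assert meta["BETA"].iloc[0] == pytest.approx(0.5)

    def test_two_halves_approximate_pooled_fit(self):
        # meta of split halves stays within 2 pooled SEs of the pooled fit
        ok = 0
        for rep in range(100):
            g = syndata.simulate_genotypes(400, 1, seed=200 + rep)
            rng = np.random.default_rng(300 + rep)
            y = 0.2 * g.dosages[:, 0] + rng.normal(size=400)
            pooled = fit_additive_model(y, g.dosages[:, 0])
            halves = []
            for sl in (slice(0, 200), slice(200, 400)):
                h = fit_additive_model(y[sl], g.dosages[sl, 0])
                halves.append(pd.DataFrame([_stats_row("m", "v", h["beta"],
                                                       h["se"])]))
            meta = ivw_meta(halves)
            ok += abs(meta["BETA"].iloc[0] - pooled["beta"]) < 2 * pooled["se"]
        assert ok >= 95

    def test_stage_effect_concordance_at_planted_qtls(self):
        # betas at strong planted QTLs correlate across independent stages
        rng = np.random.default_rng(14)
        betas_true = rng.uniform(0.2, 0.5, 30) * rng.choice([-1, 1], 30)
        est = {0: [], 1: []}
        for stage in (0, 1):
            g = syndata.simulate_genotypes(800, 30, ld_block_size=1,
                                           seed=400 + stage)
            noise = np.random.default_rng(500 + stage).normal(size=(800, 30))
            for j in range(30):
                y = betas_true[j] * g.dosages[:, j] + 0.25 * noise[:, j]
                est[stage].append(fit_additive_model(y, g.dosages[:, j])["beta"])
        r = np.corrcoef(est[0], est[1])[0, 1]
        assert r > 0.9


class TestThresholdAndCriteria:
    @pytest.mark.parametrize(
        "n,expected", [(179, 2.79e-10), (287, 1.74e-10), (1, 5e-8)]
    )
    def test_studywide_threshold(self, n, expected):
        got = derive_studywide_threshold(n)
        assert float(f"{got:.3g}") == pytest.approx(expected, rel=1e-3)

    def test_invalid_n_rejected(self):
        with pytest.raises(ValueError):
            derive_studywide_threshold(0)

    def _tables(self, p_d, p_r, b_d, b_r, p_meta):
        d = pd.DataFrame([_stats_row("m", "v", b_d, 0.1)]); d["P"] = p_d
        r = pd.DataFrame([_stats_row("m", "v", b_r, 0.1)]); r["P"] = p_r
        m = pd.DataFrame([_stats_row("m", "v", (b_d + b_r) / 2, 0.07)])
        m["P"] = p_meta
        return d, r, m

    def test_all_criteria_pass(self):
        d, r, m = self._tables(0.01, 0.04, 0.3, 0.2, 1e-11)
        out = apply_replication_criteria(d, r, m, SignificanceCriteria())
        assert len(out) == 1

    def test_opposite_signs_fail(self):
        d, r, m = self._tables(0.01, 0.04, 0.3, -0.2, 1e-11)
        out = apply_replication_criteria(d, r, m, SignificanceCriteria())
        assert out.empty

    def test_nonsignificant_discovery_fails(self):
        d, r, m = self._tables(0.06, 0.001, 0.3, 0.2, 1e-20)
        out = apply_replication_criteria(d, r, m, SignificanceCriteria())
        assert out.empty

    def test_missing_stage_fails(self):
        d, r, m = self._tables(0.01, 0.04, 0.3, 0.2, 1e-11)
        out = apply_replication_criteria(d.iloc[0:0], r, m, SignificanceCriteria())
        assert out.empty

    def test_criteria_invariant_enforced(self):
        with pytest.raises(ValueError):
            SignificanceCriteria(stagewise_alpha=0.05, studywide_p=0.1)


class TestGenomicInflation:
    def test_uniform_pvalues_lambda_one(self):
        rng = np.random.default_rng(15)
        lam = genomic_inflation(rng.uniform(size=100_000))
        assert abs(lam - 1.0) < 0.02

    def test_monotone_in_inflation(self):
        rng = np.random.default_rng(16)
        p = rng.uniform(size=1000)
        assert genomic_inflation(p / 10) > genomic_inflation(p)

    def test_inflated_chisq_recovers_factor(self):
        rng = np.random.default_rng(17)
        chi2 = 1.5 * rng.chisquare(1, size=100_000)
        p = stats.chi2.sf(chi2, df=1)
        assert genomic_inflation(p) == pytest.approx(1.5, abs=0.05)

    def test_needs_enough_pvalues(self):
        with pytest.raises(ValueError):
            genomic_inflation(np.full(10, 0.5))
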