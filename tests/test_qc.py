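"""Metabolomics and genotype QC rules: replicate merging, the staged
filter set, disease-linked recovery, PCA outliers and variant filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import gammaln

from metaboqtl import qc
from metaboqtl.containers import MetaboliteMatrix

from conftest import make_metabolite_matrix, planted_violation_fixture


class TestMergeReplicates:
    def _matrix(self, col):
        return make_metabolite_matrix(np.array(col).reshape(-1, 1))

    def test_both_present_averages(self):
        m = self._matrix([10.0, 12.0] + [50.0] * 18)
        out = qc.merge_replicates(m, [("S0000", "S0001")])
        assert out.values.iloc[0, 0] == 11.0
        assert "S0001" not in out.values.index

    def test_single_value_kept_near_detection_limit(self):
        col = [np.nan, 1.0] + list(np.linspace(10, 100, 18))
        out = qc.merge_replicates(self._matrix(col), [("S0000", "S0001")])
        assert out.values.iloc[0, 0] == 1.0  # below the 10% quantile

    def test_single_value_at_median_dropped(self):
        col = [np.nan, 55.0] + list(np.linspace(10, 100, 18))
        out = qc.merge_replicates(self._matrix(col), [("S0000", "S0001")])
        assert np.isnan(out.values.iloc[0, 0])

    def test_neither_present_missing(self):
        col = [np.nan, np.nan] + [50.0] * 18
        out = qc.merge_replicates(self._matrix(col), [("S0000", "S0001")])
        assert np.isnan(out.values.iloc[0, 0])

    def test_sample_in_two_pairs_rejected(self):
        m = self._matrix([1.0] * 20)
        with pytest.raises(ValueError):
            qc.merge_replicates(m, [("S0000", "S0001"), ("S0001", "S0002")])


class TestRecoverDiseaseAssociated:
    def test_planted_disease_missingness_recovered(self):
        rng = np.random.default_rng(1)
        n = 200
        status = pd.Series(["case"] * 100 + ["control"] * 100,
                           index=[f"S{i}" for i in range(n)])
        vals = pd.Series(rng.normal(10, 1, n), index=status.index)
        vals[status == "case"] -= 2.0            # lower abundance in cases
        miss_case = rng.random(100) < 0.6        # much more missing in cases
        vals.loc[status.index[:100][miss_case]] = np.nan
        vals.loc[status.index[100:][rng.random(100) < 0.05]] = np.nan
        assert qc.recover_disease_associated(vals, status) == "recover"

    def test_direction_inconsistent_excluded(self):
        rng = np.random.default_rng(2)
        n = 200
        status = pd.Series(["case"] * 100 + ["control"] * 100,
                           index=[f"S{i}" for i in range(n)])
        vals = pd.Series(rng.normal(10, 1, n), index=status.index)
        vals[status == "case"] += 2.0            # HIGHER abundance in cases
        miss_case = rng.random(100) < 0.6
        vals.loc[status.index[:100][miss_case]] = np.nan
        assert qc.recover_disease_associated(vals, status) == "exclude"

    def test_random_missingness_excluded(self):
        rng = np.random.default_rng(3)
        n = 200
        status = pd.Series(rng.choice(["case", "control"], n),
                           index=[f"S{i}" for i in range(n)])
        vals = pd.Series(rng.normal(10, 1, n), index=status.index)
        vals[rng.random(n) < 0.85] = np.nan
        assert qc.recover_disease_associated(vals, status) == "exclude"

    def test_requires_control_group(self):
        vals = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            qc.recover_disease_associated(vals, pd.Series(["x", "y"],
                                                          index=["a", "b"]))


class TestRunMetaboliteQc:
    def test_half_minimum_imputation_value(self):
        col = np.concatenate([[np.nan], 10 ** np.linspace(0.5, 1.5, 59)])
        other = 10 ** np.linspace(0.5, 1.5, 60)
        m = make_metabolite_matrix(np.column_stack([col, other]))
        out, _ = qc.run_metabolite_qc(m)
        # missing imputed to half the observed minimum, then log10
        assert np.isclose(out.values.iloc[0, 0], np.log10(10**0.5 / 2.0))

    def test_constant_metabolite_removed(self):
        vals = np.column_stack([np.full(60, 5.0), 10 ** np.linspace(1, 2, 60)])
        m = make_metabolite_matrix(vals)
        out, reports = qc.run_metabolite_qc(m)
        assert "M000" in [r for rep in reports for r in rep.removed_metabolites]
        assert list(out.values.columns) == ["M001"]

    def test_planted_violation_fixture_one_removal_per_stage(self):
        matrix, status, expect = planted_violation_fixture()
        out, reports = qc.run_metabolite_qc(matrix, disease_status=status)
        by_stage = {r.stage: r for r in reports}
        assert by_stage["sample_missingness"].removed_samples == expect["sample_missingness"]
        assert by_stage["metabolite_missingness"].removed_metabolites == expect["metabolite_missingness"]
        assert by_stage["half_min_imputation"].parameters["imputed"] == expect["half_min_imputation"]
        assert by_stage["log10_transform"].masked_values == expect["log10_transform"]
        assert by_stage["low_variation"].removed_metabolites == expect["low_variation"]
        assert by_stage["outlier_masking"].masked_values == expect["outlier_masking"]
        assert by_stage["min_observations"].removed_metabolites == expect["min_observations"]

    def test_idempotent_on_own_output(self):
        matrix, status, _ = planted_violation_fixture()
        out1, _ = qc.run_metabolite_qc(matrix, disease_status=status)
        out2, reports2 = qc.run_metabolite_qc(out1, disease_status=status.loc[out1.samples])
        pd.testing.assert_frame_equal(out1.values, out2.values)
        assert all(not r.removed_samples and not r.removed_metabolites
                   for r in reports2)

    def test_conservation_per_stage(self):
        matrix, status, _ = planted_violation_fixture()
        out, reports = qc.run_metabolite_qc(matrix, disease_status=status)
        n_removed = sum(len(r.removed_metabolites) for r in reports)
        assert n_removed + len(out.values.columns) == len(matrix.values.columns)
        n_s_removed = sum(len(r.removed_samples) for r in reports)
        assert n_s_removed + len(out.values.index) == len(matrix.values.index)

    def test_xenobiotics_never_imputed(self):
        vals = np.column_stack([10 ** np.linspace(1, 2, 60)] * 2)
        vals[5, 1] = np.nan
        m = make_metabolite_matrix(vals)
        m.meta.loc["M001", "klass"] = "xenobiotic"
        out, _ = qc.run_metabolite_qc(m)
        assert np.isnan(out.values.iloc[5, 1])
        assert not out.values["M000"].isna().any()


class TestSampleOutliersPca:
    def test_planted_shift_removed(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, size=(100, 10))
        vals[7] += 20.0
        m = make_metabolite_matrix(vals, log_scale=True)
        assert qc.sample_outliers_pca(m) == ["S0007"]

    def test_homogeneous_data_no_removals(self):
        rng = np.random.default_rng(6)
        m = make_metabolite_matrix(rng.normal(size=(500, 20)), log_scale=True)
        assert qc.sample_outliers_pca(m) == []

    def test_invariant_to_column_order(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(0, 1, size=(80, 12))
        vals[3] += 15.0
        m1 = make_metabolite_matrix(vals, log_scale=True)
        m2 = make_metabolite_matrix(vals[:, ::-1], log_scale=True)
        assert qc.sample_outliers_pca(m1) == qc.sample_outliers_pca(m2)

    def test_too_few_samples_noop(self):
        m = make_metabolite_matrix(np.ones((2, 4)), log_scale=True)
        assert qc.sample_outliers_pca(m) == []


def _hwe_oracle(n_AA, n_Aa, n_aa):
    """Direct conditional-multinomial enumeration of the HWE exact test."""
    n = n_AA + n_Aa + n_aa
    n_minor = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if n == 0 or n_minor == 0:
        return 1.0
    configs, probs = [], []
    for het in range(n_minor % 2, n_minor + 1, 2):
        hom_min = (n_minor - het) // 2
        hom_maj = n - het - hom_min
        if hom_maj < 0:
            continue
        logp = het * np.log(2.0) - (
            gammaln(het + 1) + gammaln(hom_min + 1) + gammaln(hom_maj + 1)
        )
        configs.append(het)
        probs.append(np.exp(logp))
    probs = np.array(probs) / np.sum(probs)
    p_obs = probs[configs.index(n_Aa)]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


class TestHweExactTest:
    def test_perfect_hwe_p_one(self):
        assert qc.hwe_exact_test(25, 50, 25) == pytest.approx(1.0)

    def test_two_minor_alleles_enumeration(self):
        assert qc.hwe_exact_test(0, 2, 0) == pytest.approx(_hwe_oracle(0, 2, 0))

    def test_monomorphic_p_one(self):
        assert qc.hwe_exact_test(100, 0, 0) == 1.0

    def test_zero_samples_p_one(self):
        assert qc.hwe_exact_test(0, 0, 0) == 1.0

    @given(
        st.integers(0, 40), st.integers(0, 40), st.integers(0, 40)
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_oracle_and_is_symmetric(self, a, h, b):
        p = qc.hwe_exact_test(a, h, b)
        assert 0 <= p <= 1
        assert p == pytest.approx(_hwe_oracle(a, h, b), abs=1e-12)
        assert p == pytest.approx(qc.hwe_exact_test(b, h, a), abs=1e-12)

    def test_extreme_departure_small_p(self):
        assert qc.hwe_exact_test(70, 0, 30) < 1e-6


class TestGenotypeQc:
    def _geno(self, dosage_cols):
        from metaboqtl.containers import GenotypeMatrix
        D = np.column_stack(dosage_cols).astype(float)
        n, v = D.shape
        variants = pd.DataFrame(
            {
                "variant_id": [f"v{j}" for j in range(v)],
                "chrom": "1",
                "pos": 1000 * (np.arange(v) + 1),
                "ref": "A",
                "alt": "G",
                "freq": np.nanmean(D, axis=0) / 2,
            }
        )
        return GenotypeMatrix(D, [f"S{i}" for i in range(n)], variants)

    def test_low_call_rate_removed(self):
        rng = np.random.default_rng(8)
        good = rng.binomial(2, 0.3, 100).astype(float)
        bad = good.copy()
        bad[:10] = np.nan  # 90% call rate
        g = self._geno([good, bad])
        out, rep = qc.genotype_qc(g)
        assert out.variant_ids == ["v0"]
        assert rep.parameters["removed_per_filter"]["call_rate"] == 1

    def test_mac_boundary(self):
        base = np.zeros(100)
        mac4 = base.copy(); mac4[:4] = 1
        mac5 = base.copy(); mac5[:5] = 1
        rng = np.random.default_rng(9)
        filler = rng.binomial(2, 0.4, 100).astype(float)
        g = self._geno([mac4, mac5, filler])
        out, rep = qc.genotype_qc(g)
        assert "v0" not in out.variant_ids and "v1" in out.variant_ids

    def test_hwe_failure_removed(self):
        col = np.array([0.0] * 70 + [2.0] * 30)  # no heterozygotes
        rng = np.random.default_rng(10)
        filler = rng.binomial(2, 0.4, 100).astype(float)
        g = self._geno([col, filler])
        out, rep = qc.genotype_qc(g)
        assert "v0" not in out.variant_ids
        assert rep.parameters["removed_per_filter"]["hwe"] == 1
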