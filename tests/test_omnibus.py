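"""Omnibus quadratic form, the two correlation estimators, and repair."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from pleiometa.omnibus import (
    CorrelationMatrix,
    estimate_sigma_B,
    estimate_sigma_P,
    omnibus_test,
    repair_correlation,
    two_phenotype_statistic,
)
from scipy import stats as st


def corr2(r):
    return np.array([[1.0, r], [r, 1.0]])


class TestOmnibusTest:
    def test_identity_zero_vector(self):
        res = omnibus_test(np.zeros(3), np.eye(3))
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_antagonistic_closed_form(self):
        res = omnibus_test(np.array([2.0, -2.0]), corr2(0.6))
        assert res.statistic == pytest.approx(20.0, abs=1e-12)
        assert res.p == pytest.approx(np.exp(-10.0), rel=1e-9)

    def test_aligned_closed_form(self):
        res = omnibus_test(np.array([2.0, 2.0]), corr2(0.6))
        assert res.statistic == pytest.approx(5.0, abs=1e-12)
        assert res.p == pytest.approx(np.exp(-2.5), rel=1e-9)

    @given(hst.lists(hst.floats(-5, 5), min_size=4, max_size=4))
    @settings(max_examples=50, deadline=None)
    def test_identity_sigma_reduces_to_sum_of_squares(self, zs):
        z = np.array(zs)
        res = omnibus_test(z, np.eye(4))
        assert res.statistic == pytest.approx(float(z @ z), rel=1e-12, abs=1e-12)
        assert res.p == pytest.approx(st.chi2.sf(z @ z, 4), rel=1e-9)

    def test_singular_sigma_repaired_and_flagged(self):
        res = omnibus_test(np.array([1.0, 1.0]), corr2(1.0 - 1e-14))
        assert res.repaired
        assert np.isfinite(res.statistic)

    def test_mapping_input_aligns_to_matrix(self):
        m = CorrelationMatrix(corr2(0.5), ("P1", "P2"), "P", "meta")
        a = omnibus_test({"P2": -2.0, "P1": 2.0}, m)
        b = omnibus_test(np.array([2.0, -2.0]), corr2(0.5))
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)


class TestTwoPhenotypeStatistic:
    def test_matches_worked_example(self):
        assert two_phenotype_statistic(2.0, -2.0, corr2(0.6)) == pytest.approx(20.0)

    def test_zero_correlation_sum_of_squares(self):
        assert two_phenotype_statistic(1.5, -2.5, corr2(0.0)) == pytest.approx(
            1.5**2 + 2.5**2)

    @given(hst.floats(-4, 4), hst.floats(-4, 4), hst.floats(-0.95, 0.95))
    @settings(max_examples=200, deadline=None)
    def test_equals_general_quadratic_form(self, z1, z2, r):
        S = corr2(r)
        direct = two_phenotype_statistic(z1, z2, S)
        z = np.array([z1, z2])
        general = float(z @ np.linalg.solve(S, z))
        assert direct == pytest.approx(general, rel=1e-12, abs=1e-12)

    @given(hst.floats(0.5, 4), hst.floats(0.5, 4), hst.floats(0.05, 0.95))
    @settings(max_examples=100, deadline=None)
    def test_antagonism_inflates_statistic(self, z1, z2, r):
        # opposite signs on positively correlated phenotypes
        antag = two_phenotype_statistic(z1, -z2, corr2(r))
        assert antag > z1**2 + z2**2

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError):
            two_phenotype_statistic(1.0, 1.0, corr2(1.0))


class TestRepair:
    def test_shrinks_minimally(self):
        S = corr2(1.0 - 1e-12)
        fixed, lam = repair_correlation(S)
        assert lam <= 0.05
        ev = np.linalg.eigvalsh(fixed)
        assert ev.min() > 0 and ev.max() / ev.min() < 1e8

    def test_pd_matrix_untouched(self):
        S = corr2(0.4)
        fixed, lam = repair_correlation(S)
        assert lam == 0.0
        np.testing.assert_array_equal(fixed, S)


def _attenuated_rho(rho=0.6, beta=0.4, maf=0.3):
    # the antagonistic causal SNP itself shifts the observable phenotype
    # correlation: cov += b1*b2*var(g), var += b^2*var(g)
    vg = 2 * maf * (1 - maf)
    return (rho - beta**2 * vg) / (1 + beta**2 * vg)


class TestSigmaP:
    def test_recovers_generator_correlation(self, small_study):
        m = estimate_sigma_P(small_study, "meta")
        assert m.values[0, 1] == pytest.approx(_attenuated_rho(), abs=0.04)
        assert m.kind == "P" and m.scope == "meta"

    def test_cohort_scope_uses_one_cohort(self, small_study):
        m = estimate_sigma_P(small_study, "C1")
        assert m.scope == "C1"
        assert abs(m.values[0, 1] - _attenuated_rho()) < 0.08

    def test_missing_phenotype_handled_pairwise(self, mixed_study):
        m = estimate_sigma_P(mixed_study, "meta")
        assert m.K == 4
        assert np.all(np.isfinite(m.values))

    def test_unknown_scope_rejected(self, small_study):
        with pytest.raises(ValueError):
            estimate_sigma_P(small_study, "nope")


class TestSigmaB:
    def test_null_z_correlation_matches_phenotype_correlation(self, small_study):
        m = estimate_sigma_B("snp_0", small_study, "C1", R=250, seed=5)
        assert m.values[0, 1] == pytest.approx(_attenuated_rho(), abs=0.12)
        assert m.n_permutations == 250

    def test_independent_phenotypes_near_zero(self):
        import pleiometa.synthetic as syn
        from pleiometa.types import CohortSpec, EffectConfig, PhenotypeSpec

        phenos = [PhenotypeSpec("P1", "quantitative", "marker"),
                  PhenotypeSpec("P2", "quantitative", "marker")]
        ds = syn.simulate_study(
            [CohortSpec("C1", 2000, ("P1", "P2"))], phenos, np.eye(2),
            [EffectConfig("s0", maf=0.3, pattern="null")],
            seed=4, icc=1.0, missing_rate=0.0)
        m = estimate_sigma_B("s0", ds, "C1", R=250, seed=6)
        assert abs(m.values[0, 1]) < 0.2  # 1.96/sqrt(R-3) ~ 0.125

    def test_seeded_determinism(self, small_study):
        a = estimate_sigma_B("snp_0", small_study, "meta", R=60, seed=9)
        b = estimate_sigma_B("snp_0", small_study, "meta", R=60, seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_refit_method_agrees_with_linear_on_quantitative(self, small_study):
        a = estimate_sigma_B("snp_0", small_study, "C1", R=60, seed=3, method="linear")
        b = estimate_sigma_B("snp_0", small_study, "C1", R=60, seed=3, method="refit")
        assert a.values[0, 1] == pytest.approx(b.values[0, 1], abs=0.02)

    def test_too_few_permutations_rejected(self, small_study):
        with pytest.raises(ValueError):
            estimate_sigma_B("snp_0", small_study, "C1", R=10, seed=0)

    def test_absent_snp_rejected(self, small_study):
        with pytest.raises(ValueError, match="absent"):
            estimate_sigma_B("nope", small_study, "C1", R=60, seed=0)
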