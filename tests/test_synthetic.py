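"""Generator structure: HWE genotypes, copula correlation, seeding."""

import numpy as np
import pytest

from pleiometa import synthetic
from pleiometa.stage1 import bulk_linear_scan
from pleiometa.types import CohortSpec, EffectConfig, PhenotypeSpec


class TestPhenotypeCorrelation:
    def test_zero_strength_is_identity(self):
        np.testing.assert_allclose(
            synthetic.make_phenotype_correlation(2, 0.0, method="constant"),
            np.eye(2))

    def test_constant_dialect_forces_offdiagonal(self):
        m = synthetic.make_phenotype_correlation(2, 0.6, method="constant")
        assert m[0, 1] == pytest.approx(0.6)

    @pytest.mark.parametrize("K,strength", [(20, 0.5), (8, 0.8), (3, 0.2)])
    def test_random_matrices_positive_definite(self, K, strength):
        m = synthetic.make_phenotype_correlation(K, strength, seed=1)
        ev = np.linalg.eigvalsh(m)
        assert ev.min() > 0
        off = m[~np.eye(K, dtype=bool)]
        assert np.all(np.abs(off) <= strength + 1e-12)
        np.testing.assert_allclose(np.diag(m), 1.0)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            synthetic.make_phenotype_correlation(1, 0.5)


class TestGenotypes:
    def test_empirical_frequency_near_maf(self):
        g = synthetic.simulate_genotypes(10_000, 0.5, seed=1)
        assert abs(g.mean() / 2 - 0.5) < 0.02

    def test_hwe_class_proportions(self):
        g = synthetic.simulate_genotypes(100_000, 0.25, seed=2)
        props = np.bincount(g.astype(int), minlength=3) / g.size
        # (1-p)^2, 2p(1-p), p^2
        np.testing.assert_allclose(props, [0.5625, 0.375, 0.0625], atol=0.01)

    def test_seeded_determinism(self):
        a = synthetic.simulate_genotypes(4, 0.25, seed=9)
        b = synthetic.simulate_genotypes(4, 0.25, seed=9)
        np.testing.assert_array_equal(a, b)

    @pytest.mark.parametrize("maf", [0.0, -0.1, 0.6])
    def test_invalid_maf_rejected(self, maf):
        with pytest.raises(ValueError):
            synthetic.simulate_genotypes(10, maf)


class TestSimulateCohort:
    def test_correlation_recovered_without_visit_noise(self):
        phenos = [PhenotypeSpec(f"P{i}", "quantitative", "marker") for i in range(4)]
        corr = synthetic.make_phenotype_correlation(4, 0.5, seed=5)
        ds = synthetic.simulate_cohort(
            CohortSpec("C1", 10_000, tuple(p.name for p in phenos)),
            phenos, corr, seed=np.random.default_rng(5),
            icc=1.0, missing_rate=0.0)
        vals = np.column_stack([ds.subject_values(p.name) for p in phenos])
        # remove the shared age/sex structure before comparing to the copula
        C = np.column_stack([np.ones(len(vals)), ds.covariates.to_numpy()])
        q, _ = np.linalg.qr(C)
        resid = vals - q @ (q.T @ vals)
        emp = np.corrcoef(resid, rowvar=False)
        np.testing.assert_allclose(emp, corr, atol=0.03)

    def test_null_snp_uncorrelated_with_phenotypes(self):
        phenos = [PhenotypeSpec("P1", "quantitative", "marker")]
        ds = synthetic.simulate_cohort(
            CohortSpec("C1", 5_000, ("P1",)), phenos, np.eye(1),
            [EffectConfig("s0", maf=0.3, pattern="null")],
            seed=np.random.default_rng(6), icc=1.0, missing_rate=0.0)
        r = np.corrcoef(ds.dosages["s0"], ds.subject_values("P1"))[0, 1]
        assert abs(r) < 3 / np.sqrt(5_000)

    def test_antagonistic_effects_give_opposite_z(self, quant_pair):
        phenos, corr = quant_pair
        eff = EffectConfig("s1", maf=0.3, betas={"P1": 0.3, "P2": -0.3},
                           pattern="antagonistic")
        ds = synthetic.simulate_cohort(
            CohortSpec("C1", 5_000, ("P1", "P2")), phenos, corr, [eff],
            seed=np.random.default_rng(8), icc=1.0, missing_rate=0.0)
        Y = np.column_stack([ds.subject_values("P1"), ds.subject_values("P2")])
        beta, se = bulk_linear_scan(ds.dosages["s1"], Y, ds.covariates.to_numpy())
        z = beta[0] / se[0]
        assert z[0] > 2 and z[1] < -2

    def test_seeded_determinism(self, quant_pair):
        phenos, corr = quant_pair
        kw = dict(icc=0.5, missing_rate=0.1)
        a = synthetic.simulate_cohort(CohortSpec("C1", 200, ("P1", "P2")),
                                      phenos, corr, seed=np.random.default_rng(3), **kw)
        b = synthetic.simulate_cohort(CohortSpec("C1", 200, ("P1", "P2")),
                                      phenos, corr, seed=np.random.default_rng(3), **kw)
        np.testing.assert_array_equal(a.measurements["P1"], b.measurements["P1"])

    def test_dimension_mismatch_names_offender(self, quant_pair):
        phenos, _ = quant_pair
        with pytest.raises(ValueError, match="pheno_corr"):
            synthetic.simulate_cohort(CohortSpec("C1", 100, ("P1",)),
                                      phenos, np.eye(3))

    def test_every_subject_has_a_visit(self, mixed_study):
        for ds in mixed_study:
            for vals in ds.measurements.values():
                assert np.all(np.any(np.isfinite(vals), axis=1))

    def test_dosages_within_bounds_and_event_ages_positive(self, mixed_study):
        for ds in mixed_study:
            for g in ds.dosages.values():
                assert g.min() >= 0 and g.max() <= 2
            for event, age in ds.outcomes.values():
                assert np.all(age > 0)
                assert set(np.unique(event)) <= {0, 1}


class TestSimulateStudy:
    def test_default_design_totals(self):
        cohorts = synthetic.default_cohorts()
        assert sum(c.n_subjects for c in cohorts) == 33_431
        assert len(cohorts) == 5
        phenos = synthetic.default_phenotypes()
        assert len(phenos) == 20
        assert sum(p.domain_tag == "marker" for p in phenos) == 12

    def test_phenotype_subset_respected(self, mixed_study):
        c3 = next(d for d in mixed_study if d.cohort == "C3")
        assert "S1" not in c3.phenotypes
        assert len(c3.phenotypes) == 3

    def test_duplicate_cohort_names_rejected(self, quant_pair):
        phenos, corr = quant_pair
        dup = [CohortSpec("C1", 100, ("P1",)), CohortSpec("C1", 100, ("P1",))]
        with pytest.raises(ValueError, match="duplicate"):
            synthetic.simulate_study(dup, phenos, corr)
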