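"""Stage-1 association fits against closed-form and brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as st
from scipy.optimize import minimize_scalar

from pleiometa import stage1
from pleiometa.stage1 import (
    FitError,
    MonomorphicSNPError,
    fit_binary,
    fit_quantitative,
    fit_survival,
    prioritize,
)
from pleiometa.types import AssocStat, PhenotypeSpec


class TestQuantitative:
    def test_toy_ols_closed_form(self):
        # group means (1.5, 3.5, 5.5) lie on an exact line
        y = np.arange(1.0, 7.0)
        g = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        # relax the subject minimum for the hand-checked toy
        old = stage1.MIN_SUBJECTS
        stage1.MIN_SUBJECTS = 5
        try:
            res = fit_quantitative(g, y)
        finally:
            stage1.MIN_SUBJECTS = old
        assert res.beta == pytest.approx(2.0, abs=1e-12)

    def test_single_visit_equals_plain_ols(self):
        rng = np.random.default_rng(0)
        n = 200
        g = rng.binomial(2, 0.3, n).astype(float)
        cov = pd.DataFrame({"age": rng.normal(60, 8, n), "sex": rng.integers(0, 2, n)})
        y = 0.2 * g + 0.01 * cov["age"].to_numpy() + rng.standard_normal(n)
        res = fit_quantitative(g, y, cov)
        X = sm.add_constant(pd.DataFrame({
            "dosage": g, "age": cov["age"] - cov["age"].mean(), "sex": cov["sex"]}))
        ols = sm.OLS(y, X).fit()
        assert res.beta == pytest.approx(ols.params["dosage"], abs=1e-12)
        assert res.se == pytest.approx(ols.bse["dosage"], abs=1e-12)

    def test_repeated_visits_random_intercept(self):
        rng = np.random.default_rng(1)
        n, v = 300, 4
        g = rng.binomial(2, 0.3, n).astype(float)
        subject = rng.standard_normal(n)
        y = 0.3 * g[:, None] + subject[:, None] + 0.7 * rng.standard_normal((n, v))
        res = fit_quantitative(g, y)
        assert abs(res.beta - 0.3) < 3 * res.se
        # repeated measures shrink the standard error below the
        # single-visit fit's
        res1 = fit_quantitative(g, y[:, 0])
        assert res.se < res1.se

    def test_log_transform_rejects_nonpositive(self):
        spec = PhenotypeSpec("TG", "quantitative", "marker", log_transform=True)
        y = np.full(40, 2.0)
        y[3] = -1.0
        g = np.tile([0.0, 1.0], 20)
        with pytest.raises(ValueError, match="subject"):
            fit_quantitative(g, y, spec=spec)

    def test_monomorphic_flagged(self):
        with pytest.raises(MonomorphicSNPError):
            fit_quantitative(np.ones(50), np.random.default_rng(0).standard_normal(50))

    def test_null_p_uniform(self):
        rng = np.random.default_rng(2)
        n = 1000
        Y = rng.standard_normal((n, 1))
        G = rng.binomial(2, 0.3, size=(n, 500)).astype(float)
        beta, se = stage1.bulk_linear_scan(G, Y)
        p = 2 * st.norm.sf(np.abs(beta[:, 0] / se[:, 0]))
        assert st.kstest(p, "uniform").pvalue > 0.01

    def test_z_times_se_equals_beta(self, mixed_study):
        recs = stage1.fit_dataset(mixed_study[0], snp_ids=["rs1"])
        assert recs
        for r in recs:
            assert r.z * r.se == pytest.approx(r.beta, rel=1e-9)


class TestBinary:
    def test_contingency_table_log_or(self):
        # exposed: 30/70, unexposed: 10/90 -> log OR = ln(30*90/(70*10))
        g = np.r_[np.ones(100), np.zeros(100)]
        y = np.r_[np.ones(30), np.zeros(70), np.ones(10), np.zeros(90)]
        res = fit_binary(g, y)
        assert res.beta == pytest.approx(np.log(30 * 90 / (70 * 10)), abs=1e-6)

    def test_null_z_moderate(self):
        rng = np.random.default_rng(3)
        n = 5000
        g = rng.binomial(2, 0.3, n).astype(float)
        y = rng.binomial(1, 0.3, n)
        res = fit_binary(g, y)
        assert abs(res.z) < 4

    def test_monomorphic_rejected(self):
        with pytest.raises(MonomorphicSNPError):
            fit_binary(np.zeros(100), np.r_[np.ones(50), np.zeros(50)])

    def test_too_few_events_rejected(self):
        rng = np.random.default_rng(4)
        g = rng.binomial(2, 0.3, 100).astype(float)
        y = np.r_[np.ones(3), np.zeros(97)]
        with pytest.raises(FitError):
            fit_binary(g, y)


def breslow_partial_loglik(beta, t, event, g):
    """Independent oracle: Breslow partial log-likelihood evaluated
    directly from its definition."""
    ll = 0.0
    eta = beta * g
    for tj in np.unique(t[event == 1]):
        d = (t == tj) & (event == 1)
        risk = t >= tj
        ll += eta[d].sum() - d.sum() * np.log(np.exp(eta[risk]).sum())
    return ll


class TestSurvival:
    def test_matches_brute_force_partial_likelihood(self):
        rng = np.random.default_rng(5)
        n = 18
        g = rng.binomial(2, 0.4, n).astype(float)
        t = rng.exponential(10.0, n) * np.exp(-0.4 * g) + 0.5
        event = rng.binomial(1, 0.8, n)
        event[:2] = 1  # ensure events
        old = stage1.MIN_EVENTS
        stage1.MIN_EVENTS = 2
        try:
            res = fit_survival(g, t, event)
        finally:
            stage1.MIN_EVENTS = old
        opt = minimize_scalar(
            lambda b: -breslow_partial_loglik(b, t, event, g),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10})
        assert res.beta == pytest.approx(opt.x, abs=1e-4)

    def test_known_hazard_ratio_recovered(self):
        rng = np.random.default_rng(6)
        n = 2000
        g = rng.binomial(1, 0.5, n).astype(float)
        t = rng.exponential(1.0, n) / np.exp(np.log(2.0) * g)
        cens = np.quantile(t, 0.5)
        event = (t <= cens).astype(int)
        res = fit_survival(g, np.minimum(t, cens) + 1e-9, event)
        assert abs(res.beta - np.log(2.0)) < 2 * res.se

    def test_zero_events_rejected(self):
        rng = np.random.default_rng(7)
        g = rng.binomial(2, 0.3, 100).astype(float)
        with pytest.raises(FitError):
            fit_survival(g, np.full(100, 80.0), np.zeros(100))

    def test_age_excluded_from_covariates(self):
        rng = np.random.default_rng(8)
        n = 500
        g = rng.binomial(2, 0.3, n).astype(float)
        t = rng.exponential(50.0, n) + 1
        event = rng.binomial(1, 0.6, n)
        cov = pd.DataFrame({"age": rng.normal(60, 8, n), "sex": rng.integers(0, 2, n)})
        res = fit_survival(g, t, event, cov)  # age on the time scale only
        assert np.isfinite(res.p)


class TestPrioritize:
    def _stat(self, snp, p, pheno="P1", cohort="C1"):
        se = 0.1
        z = st.norm.isf(p / 2)
        return AssocStat(snp, pheno, cohort, "A", "G", 0.3,
                         beta=z * se, se=se, z=z, p=p, n=100)

    def test_fisher_over_nominal_hits_only(self):
        stats = [self._stat("rs1", 0.01), self._stat("rs1", 0.04, "P2"),
                 self._stat("rs1", 0.5, "P3"), self._stat("rs2", 0.2)]
        recs = {r.snp_id: r for r in prioritize(stats)}
        assert recs["rs1"].fisher_statistic == pytest.approx(
            -2 * (np.log(0.01) + np.log(0.04)), abs=1e-9)
        assert recs["rs1"].df == 4
        assert recs["rs2"].p_prioritize == 1.0
        assert recs["rs2"].rank > recs["rs1"].rank

    def test_top_n_selection(self):
        rng = np.random.default_rng(9)
        stats = [self._stat(f"rs{i:04d}", float(rng.uniform(1e-4, 1)))
                 for i in range(1500)]
        recs = prioritize(stats, top_n=1000)
        assert sum(r.selected for r in recs) == 1000
        ranks = sorted(r.rank for r in recs if r.selected)
        assert ranks == list(range(1, 1001))
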