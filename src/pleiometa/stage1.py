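"""Per-cohort univariate association under an additive genetic model.

Quantitative markers with repeated visits are fitted with a
random-intercept linear mixed model (REML; single-visit data reduce to
ordinary least squares), diseases with logistic regression, and ages at
onset with a Cox proportional-hazards model (Breslow tie handling, age as
the time scale).  All models adjust for age and sex; right-skewed markers
are natural-log-transformed and multiplied by 100.  A Fisher-combination
prioritization over nominally significant (p < 0.05) univariate p-values
selects the top SNPs for the stage-2 meta-analysis.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.duration.hazard_regression import PHReg
from scipy import stats as _st

from .meta import fisher_combine
from .synthetic import IndividualDataset
from .types import (
    BINARY,
    QUANTITATIVE,
    TIME_TO_EVENT,
    AssocStat,
    PhenotypeSpec,
    PrioritizationRecord,
)

log = logging.getLogger(__name__)

LOG_SCALE = 100.0
MIN_SUBJECTS = 30
MIN_EVENTS = 10


class FitError(RuntimeError):
    """A stage-1 model could not produce a valid statistic."""


class MonomorphicSNPError(FitError):
    """Dosage has zero variance in this cohort."""


class SeparationError(FitError):
    """Logistic model suffered (quasi-)separation."""


def _check_dosage(dosage: np.ndarray) -> np.ndarray:
    dosage = np.asarray(dosage, dtype=float)
    if np.var(dosage) <= 0:
        raise MonomorphicSNPError("monomorphic SNP: dosage variance is zero")
    return dosage


def _eaf(dosage: np.ndarray) -> float:
    return float(np.mean(dosage) / 2.0)


def fit_quantitative(
    dosage: np.ndarray,
    measurements: np.ndarray,
    covariates: pd.DataFrame | None = None,
    visit_ages: np.ndarray | None = None,
    spec: PhenotypeSpec | None = None,
    snp_id: str = "snp",
    phenotype: str = "pheno",
    cohort: str = "cohort",
    effect_allele: str = "A",
    other_allele: str = "G",
) -> AssocStat:
    """Additive-model effect of dosage on a quantitative marker.

    ``measurements`` is (n_subjects,) or (n_subjects, n_visits) with NaN
    for missed visits.  With more than one observation per subject a
    random-intercept mixed model (REML) is used; otherwise plain OLS.
    """
    dosage = _check_dosage(dosage)
    y = np.asarray(measurements, dtype=float)
    if y.ndim == 1:
        y = y[:, None]
    n_subj, n_visits = y.shape
    if n_subj != len(dosage):
        raise ValueError("measurements and dosage disagree on subject count")
    if np.sum(np.any(np.isfinite(y), axis=1)) < MIN_SUBJECTS:
        raise FitError(f"fewer than {MIN_SUBJECTS} subjects with a visit")

    if spec is not None and spec.log_transform:
        bad = np.where(np.nanmin(np.where(np.isfinite(y), y, np.inf), axis=1) <= 0)[0]
        if bad.size:
            raise ValueError(
                f"non-positive values under log-transform for subject index {bad[0]}"
            )
        y = np.log(y) * LOG_SCALE

    subj, visit = np.nonzero(np.isfinite(y))
    frame = pd.DataFrame(
        {
            "y": y[subj, visit],
            "dosage": dosage[subj],
            "subject": subj,
        }
    )
    if covariates is not None:
        if visit_ages is not None and "age" in covariates:
            va = np.asarray(visit_ages, dtype=float)
            if va.ndim == 1:
                va = va[:, None]
            frame["age"] = va[subj, visit]
        for col in covariates.columns:
            if col not in frame:
                frame[col] = np.asarray(covariates[col])[subj]
    exog_cols = ["dosage"] + [c for c in frame.columns if c not in ("y", "dosage", "subject")]
    X = sm.add_constant(frame[exog_cols], has_constant="add")

    multi_visit = frame["subject"].duplicated().any()
    if "age" in X:
        X = X.assign(age=X["age"] - X["age"].mean())  # conditioning only
    if not multi_visit:
        res = sm.OLS(frame["y"], X).fit()
        beta, se = float(res.params["dosage"]), float(res.bse["dosage"])
    else:
        beta, se = _random_intercept_fit(frame, X)
    if not np.isfinite(se) or se <= 0:
        raise FitError("non-finite standard error")
    return AssocStat.from_beta_se(
        snp_id, phenotype, cohort, beta, se, n=n_subj,
        effect_allele=effect_allele, other_allele=other_allele, eaf=_eaf(dosage),
    )


def _random_intercept_fit(frame: pd.DataFrame, X: pd.DataFrame) -> tuple[float, float]:
    """REML random-intercept fit of the dosage effect; falls back to an
    OLS fit on subject means if the mixed-model optimizer fails."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MixedLM(frame["y"], X, groups=frame["subject"]).fit(reml=True)
            beta, se = float(res.params["dosage"]), float(res.bse["dosage"])
            if np.isfinite(se) and se > 0:
                return beta, se
        except (np.linalg.LinAlgError, ValueError):
            pass
    log.warning("mixed model failed; using subject-mean OLS fallback")
    agg = frame.assign(**{c: X[c] for c in X.columns if c != "const"})
    agg = agg.drop(columns=["dosage"], errors="ignore").join(
        frame[["dosage"]]).groupby("subject").mean()
    Xm = sm.add_constant(agg.drop(columns=["y"]), has_constant="add")
    res = sm.OLS(agg["y"], Xm).fit()
    return float(res.params["dosage"]), float(res.bse["dosage"])


def fit_binary(
    dosage: np.ndarray,
    event_indicator: np.ndarray,
    covariates: pd.DataFrame | None = None,
    snp_id: str = "snp",
    phenotype: str = "pheno",
    cohort: str = "cohort",
    effect_allele: str = "A",
    other_allele: str = "G",
) -> AssocStat:
    """Log-odds ratio per allele copy from age/sex-adjusted logistic fit."""
    dosage = _check_dosage(dosage)
    yb = np.asarray(event_indicator, dtype=float)
    n_events = int(yb.sum())
    if n_events < MIN_EVENTS or (len(yb) - n_events) < MIN_EVENTS:
        raise FitError(f"need >= {MIN_EVENTS} subjects in each outcome class")
    X = pd.DataFrame({"dosage": dosage})
    if covariates is not None:
        for col in covariates.columns:
            X[col] = np.asarray(covariates[col])
    X = sm.add_constant(X, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.Logit(yb, X).fit(disp=0)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
            raise SeparationError(f"separation in logistic fit: {exc}") from exc
    beta = float(res.params["dosage"])
    se = float(res.bse["dosage"])
    if not np.isfinite(se) or se <= 0 or se > 1e3:
        raise SeparationError("unstable logistic fit (diverging standard error)")
    return AssocStat.from_beta_se(
        snp_id, phenotype, cohort, beta, se, n=len(yb),
        effect_allele=effect_allele, other_allele=other_allele, eaf=_eaf(dosage),
    )


def fit_survival(
    dosage: np.ndarray,
    age_at_event: np.ndarray,
    event_indicator: np.ndarray,
    covariates: pd.DataFrame | None = None,
    snp_id: str = "snp",
    phenotype: str = "pheno",
    cohort: str = "cohort",
    effect_allele: str = "A",
    other_allele: str = "G",
) -> AssocStat:
    """Log hazard ratio per allele copy (Cox partial likelihood, Breslow
    ties).  Age at onset/censoring is the time variable, so age is not a
    covariate; no frailty term is used (subjects are unrelated)."""
    dosage = _check_dosage(dosage)
    t = np.asarray(age_at_event, dtype=float)
    ev = np.asarray(event_indicator, dtype=float)
    if np.any(t <= 0):
        raise ValueError("event/censoring ages must be positive")
    if int(ev.sum()) < MIN_EVENTS:
        raise FitError(f"need >= {MIN_EVENTS} events")
    cols = {"dosage": dosage}
    if covariates is not None:
        for col in covariates.columns:
            if col != "age":  # age is the time scale
                cols[col] = np.asarray(covariates[col])
    X = pd.DataFrame(cols)
    res = PHReg(t, X, status=ev, ties="breslow").fit(disp=0)
    idx = list(X.columns).index("dosage")
    beta = float(res.params[idx])
    se = float(res.bse[idx])
    if not np.isfinite(se) or se <= 0:
        raise FitError("non-finite standard error in Cox fit")
    return AssocStat.from_beta_se(
        snp_id, phenotype, cohort, beta, se, n=len(t),
        effect_allele=effect_allele, other_allele=other_allele, eaf=_eaf(dosage),
    )


def fit_dataset(
    ds: IndividualDataset,
    snp_ids: Sequence[str] | None = None,
    phenotypes: Sequence[str] | None = None,
    on_error: str = "log",
) -> list[AssocStat]:
    """Run the appropriate stage-1 fit for every SNP x phenotype of one
    cohort dataset.  Failed fits are logged and skipped (``on_error='log'``)
    or re-raised (``'raise'``)."""
    out: list[AssocStat] = []
    snps = list(snp_ids) if snp_ids is not None else list(ds.dosages)
    phenos = list(phenotypes) if phenotypes is not None else list(ds.phenotypes)
    for snp in snps:
        g = ds.dosages[snp]
        ea, oa = ds.effect_alleles.get(snp, ("A", "G"))
        for pheno in phenos:
            if pheno not in ds.phenotypes:
                continue
            spec = ds.phenotype_specs.get(pheno)
            try:
                if pheno in ds.measurements:
                    out.append(fit_quantitative(
                        g, ds.measurements[pheno], ds.covariates,
                        visit_ages=ds.visit_ages.get(pheno), spec=spec,
                        snp_id=snp, phenotype=pheno, cohort=ds.cohort,
                        effect_allele=ea, other_allele=oa,
                    ))
                else:
                    event, age = ds.outcomes[pheno]
                    if spec is not None and spec.kind == BINARY:
                        out.append(fit_binary(
                            g, event, ds.covariates, snp_id=snp,
                            phenotype=pheno, cohort=ds.cohort,
                            effect_allele=ea, other_allele=oa,
                        ))
                    else:
                        out.append(fit_survival(
                            g, age, event, ds.covariates, snp_id=snp,
                            phenotype=pheno, cohort=ds.cohort,
                            effect_allele=ea, other_allele=oa,
                        ))
            except FitError as exc:
                if on_error == "raise":
                    raise
                log.warning("stage-1 fit skipped (%s / %s / %s): %s",
                            snp, pheno, ds.cohort, exc)
    return out


def bulk_linear_scan(
    G: np.ndarray,
    Y: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized OLS of every column of ``Y`` (n x K traits) on every
    column of ``G`` (n x S dosages), adjusted for ``covariates``.

    Returns (beta, se), each of shape (S, K).  Equivalent to per-pair
    ``fit_quantitative`` on single-visit data up to the small-sample
    degrees-of-freedom convention (residual df uses the covariate count of
    the full model).  Used for fast permutation nulls and experiment
    batteries; NaNs are not allowed here.
    """
    G = np.asarray(G, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if G.ndim == 1:
        G = G[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    n = G.shape[0]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        C = np.column_stack([np.ones(n), C])
    else:
        C = np.ones((n, 1))
    q, _ = np.linalg.qr(C)
    Gr = G - q @ (q.T @ G)
    Yr = Y - q @ (q.T @ Y)
    gg = np.sum(Gr * Gr, axis=0)  # (S,)
    if np.any(gg <= 0):
        raise MonomorphicSNPError("monomorphic SNP in bulk scan")
    beta = (Gr.T @ Yr) / gg[:, None]  # (S, K)
    dof = n - C.shape[1] - 1
    rss = np.sum(Yr * Yr, axis=0)[None, :] - beta**2 * gg[:, None]
    sigma2 = np.maximum(rss, 1e-300) / dof
    se = np.sqrt(sigma2 / gg[:, None])
    return beta, se


def prioritize(
    stats: Iterable[AssocStat],
    top_n: int = 1000,
    alpha: float = 0.05,
) -> list[PrioritizationRecord]:
    """Fisher-combination SNP prioritization.

    Per SNP, Fisher's statistic is computed over the univariate p-values
    below ``alpha`` pooled across phenotypes and cohorts; SNPs with no
    nominal hit get p = 1.  The ``top_n`` smallest combined p-values are
    flagged for stage 2.  Ties break on the smallest single univariate p,
    then lexicographic SNP id.
    """
    by_snp: dict[str, list[float]] = {}
    min_p: dict[str, float] = {}
    for s in stats:
        by_snp.setdefault(s.snp_id, [])
        min_p[s.snp_id] = min(min_p.get(s.snp_id, 1.0), s.p)
        if s.p < alpha:
            by_snp[s.snp_id].append(s.p)
    if not by_snp:
        raise ValueError("no association statistics supplied")
    rows = []
    for snp, ps in by_snp.items():
        if ps:
            fr = fisher_combine(ps)
            rows.append((snp, fr.statistic, fr.df, fr.p))
        else:
            rows.append((snp, 0.0, 0, 1.0))
    rows.sort(key=lambda r: (r[3], min_p[r[0]], r[0]))
    return [
        PrioritizationRecord(
            snp_id=snp, fisher_statistic=stat, df=df, p_prioritize=p,
            rank=i + 1, selected=i < top_n,
        )
        for i, (snp, stat, df, p) in enumerate(rows)
    ]


__all__ = [
    "fit_quantitative",
    "fit_binary",
    "fit_survival",
    "fit_dataset",
    "bulk_linear_scan",
    "prioritize",
    "FitError",
    "MonomorphicSNPError",
    "SeparationError",
    "MIN_EVENTS",
    "MIN_SUBJECTS",
]
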