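"""Multi-cohort individual-level data generator.

Emulates the statistical structure of a multi-study longitudinal GWAS
consortium: five cohorts of unrelated subjects, Hardy–Weinberg genotypes
with MAF >= 2%, a panel of weakly-to-modestly correlated phenotypes (12
quantitative markers with repeated visits plus disease/death age-at-onset
outcomes), cohort-specific phenotype subsets, and configurable aligned or
antagonistic genetic effect geometry with inter-cohort heterogeneity.

The generative model is a latent-liability Gaussian copula: each subject
carries a multivariate-normal latent trait vector with the target
phenotype correlation; quantitative visits add independent within-subject
noise (intraclass correlation ``icc``), binary outcomes threshold the
liability, and ages at onset follow an exponential hazard scaled by
``exp`` of the linear predictor, administratively censored at a fixed age.
All randomness flows from one study-level seed expanded deterministically
per cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .types import (
    BINARY,
    QUANTITATIVE,
    TIME_TO_EVENT,
    CohortSpec,
    EffectConfig,
    PhenotypeSpec,
)

# Log-scale markers are stored as raw positive measurements; the stage-1
# transform ln(x)*100 recovers the latent scale exactly.
_LOG_OFFSET = 450.0
_LOG_SCALE = 100.0

DEFAULT_CENSOR_AGE = 85.0
DEFAULT_ICC = 0.5
_AGE_SLOPE = 0.02  # SD units of a marker per year of age
_SEX_EFFECT = 0.1
_VISIT_SPACING = 2.0  # years between successive visits
_BASELINE_EVENT_FRACTION = 0.5  # P(event before censor age) at null liability


def make_phenotype_correlation(
    K: int,
    strength: float,
    seed: int | np.random.Generator = 0,
    method: str = "random",
) -> np.ndarray:
    """A K x K positive-definite phenotype correlation matrix.

    ``method='constant'`` sets every off-diagonal to ``strength`` exactly
    (exchangeable structure, PD for strength in [0, 1)); ``'random'``
    draws off-diagonals uniformly in [-strength, strength] and shrinks
    toward the identity until the matrix is positive definite.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if not (0.0 <= strength < 1.0):
        raise ValueError("strength must be in [0, 1)")
    if method == "constant":
        sigma = np.full((K, K), strength)
        np.fill_diagonal(sigma, 1.0)
        return sigma
    if method != "random":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    off = rng.uniform(-strength, strength, size=(K, K))
    sigma = (off + off.T) / 2.0
    np.fill_diagonal(sigma, 1.0)
    # shrink toward identity until PD; preserves |off-diagonal| <= strength
    for lam in np.linspace(0.0, 0.99, 100):
        cand = (1 - lam) * sigma + lam * np.eye(K)
        if np.linalg.eigvalsh(cand).min() > 1e-10:
            return cand
    return np.eye(K)  # pragma: no cover - unreachable for strength < 1


def simulate_genotypes(
    n: int, maf: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Hardy–Weinberg allele-dosage vector: Binomial(2, maf) per subject."""
    if not (0.0 < maf <= 0.5):
        raise ValueError("maf must be in (0, 0.5]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    return rng.binomial(2, maf, size=n).astype(float)


@dataclass
class IndividualDataset:
    """Individual-level data for one cohort.

    ``measurements[pheno]`` is an (n_subjects, n_visits) array with NaN for
    missed visits; ``visit_ages`` matches its shape.  ``outcomes[pheno]``
    is an (event indicator, age at event/censoring) pair.  ``dosages`` maps
    snp_id to a length-n dosage vector in [0, 2].
    """

    cohort: str
    subject_ids: np.ndarray
    covariates: pd.DataFrame  # columns: age, sex
    dosages: dict[str, np.ndarray]
    measurements: dict[str, np.ndarray] = field(default_factory=dict)
    visit_ages: dict[str, np.ndarray] = field(default_factory=dict)
    outcomes: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    phenotype_specs: dict[str, PhenotypeSpec] = field(default_factory=dict)
    effect_alleles: dict[str, tuple[str, str]] = field(default_factory=dict)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def phenotypes(self) -> tuple[str, ...]:
        return tuple(self.measurements) + tuple(self.outcomes)

    def subject_values(self, phenotype: str) -> np.ndarray:
        """Per-subject scalar summary used for correlation estimation:
        visit-averaged (transformed) values for markers, 0/1 event
        indicators for outcomes."""
        if phenotype in self.measurements:
            spec = self.phenotype_specs[phenotype]
            vals = self.measurements[phenotype]
            if spec.log_transform:
                vals = np.log(vals) * _LOG_SCALE
            with np.errstate(invalid="ignore"):
                return np.nanmean(vals, axis=1)
        if phenotype in self.outcomes:
            return self.outcomes[phenotype][0].astype(float)
        raise KeyError(f"phenotype {phenotype!r} not in cohort {self.cohort!r}")


def _quantitative_visits(
    rng: np.random.Generator,
    latent: np.ndarray,
    shift: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    age_mean: float,
    n_visits: int,
    icc: float,
    missing_rate: float,
) -> tuple[np.ndarray, np.ndarray]:
    n = latent.shape[0]
    visit_age = age[:, None] + _VISIT_SPACING * np.arange(n_visits)[None, :]
    mean = (
        shift[:, None]
        + np.sqrt(icc) * latent[:, None]
        + _AGE_SLOPE * (visit_age - age_mean)
        + _SEX_EFFECT * sex[:, None]
    )
    vals = mean + np.sqrt(1.0 - icc) * rng.standard_normal((n, n_visits))
    if missing_rate > 0 and n_visits > 1:
        miss = rng.random((n, n_visits)) < missing_rate
        # keep at least one visit per subject
        keep = rng.integers(0, n_visits, size=n)
        miss[np.arange(n), keep] = False
        vals = np.where(miss, np.nan, vals)
        visit_age = np.where(miss, np.nan, visit_age)
    return vals, visit_age


def simulate_cohort(
    cohort: CohortSpec,
    phenotypes: Sequence[PhenotypeSpec],
    pheno_corr: np.ndarray,
    effects: Sequence[EffectConfig] = (),
    seed: int | np.random.Generator = 0,
    icc: float = DEFAULT_ICC,
    censor_age: float = DEFAULT_CENSOR_AGE,
    missing_rate: float = 0.05,
    prevalence: float = 0.3,
    outcome_latent_scale: float = 1.0,
) -> IndividualDataset:
    """Generate one cohort's individual-level dataset.

    ``pheno_corr`` is indexed by the *full* ``phenotypes`` list; the cohort
    only receives columns in its ``phenotype_subset``.  Genetic effects are
    added to phenotype liabilities in standard-deviation units per
    effect-allele copy, scaled by the per-cohort multiplier.
    """
    names = [p.name for p in phenotypes]
    K = len(names)
    pheno_corr = np.asarray(pheno_corr, dtype=float)
    if pheno_corr.shape != (K, K):
        raise ValueError(
            f"pheno_corr has shape {pheno_corr.shape}, expected ({K}, {K}) "
            f"matching phenotypes {names}"
        )
    missing = set(cohort.phenotype_subset) - set(names)
    if missing:
        raise ValueError(f"cohort {cohort.name}: unknown phenotypes {sorted(missing)}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = cohort.n_subjects

    chol = np.linalg.cholesky(pheno_corr + 1e-10 * np.eye(K))
    latent = rng.standard_normal((n, K)) @ chol.T

    age = rng.normal(cohort.age_mean, cohort.age_sd, size=n).clip(min=30.0)
    sex = rng.integers(0, 2, size=n).astype(float)

    dosages: dict[str, np.ndarray] = {}
    alleles: dict[str, tuple[str, str]] = {}
    for eff in effects:
        dosages[eff.snp_id] = simulate_genotypes(n, eff.maf, rng)
        alleles[eff.snp_id] = ("A", "G")

    # total genetic shift per phenotype (SD units)
    shifts = np.zeros((n, K))
    for eff in effects:
        mult = eff.multiplier(cohort.name)
        g = dosages[eff.snp_id]
        for pheno, beta in eff.betas.items():
            if pheno in names:
                shifts[:, names.index(pheno)] += beta * mult * g

    ds = IndividualDataset(
        cohort=cohort.name,
        subject_ids=np.array([f"{cohort.name}_{i:06d}" for i in range(n)]),
        covariates=pd.DataFrame({"age": age, "sex": sex}),
        dosages=dosages,
        phenotype_specs={p.name: p for p in phenotypes if p.name in cohort.phenotype_subset},
        effect_alleles=alleles,
    )

    for k, spec in enumerate(phenotypes):
        if spec.name not in cohort.phenotype_subset:
            continue
        if spec.kind == QUANTITATIVE:
            n_visits = cohort.n_visits or spec.n_visits
            vals, visit_age = _quantitative_visits(
                rng, latent[:, k], shifts[:, k], age, sex,
                cohort.age_mean, n_visits, icc, missing_rate,
            )
            if spec.log_transform:
                # stored raw positive values; ln(raw)*100 recovers
                # 100*latent-scale value + constant offset
                vals = np.exp((vals * _LOG_SCALE + _LOG_OFFSET) / _LOG_SCALE)
            ds.measurements[spec.name] = vals
            ds.visit_ages[spec.name] = visit_age
        elif spec.kind == BINARY:
            # logistic-liability link: the injected beta is the per-copy
            # log-odds ratio (exactly so when outcome_latent_scale = 0)
            eta = (
                _st.logistic.ppf(prevalence)
                + shifts[:, k]
                + outcome_latent_scale * latent[:, k]
                + _SEX_EFFECT * sex
            )
            ds.outcomes[spec.name] = (
                (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int),
                age.copy(),
            )
        elif spec.kind == TIME_TO_EVENT:
            lam0 = -np.log(1.0 - _BASELINE_EVENT_FRACTION) / censor_age
            rate = lam0 * np.exp(
                shifts[:, k]
                + 0.5 * outcome_latent_scale * latent[:, k]
                + _SEX_EFFECT * sex
            )
            t = rng.exponential(1.0 / rate)
            event = (t <= censor_age).astype(int)
            onset_age = np.where(event == 1, np.maximum(t, 1e-3), censor_age)
            ds.outcomes[spec.name] = (event, onset_age)
    return ds


def simulate_study(
    cohorts: Sequence[CohortSpec],
    phenotypes: Sequence[PhenotypeSpec],
    pheno_corr: np.ndarray,
    effects: Sequence[EffectConfig] = (),
    seed: int = 0,
    **kwargs,
) -> list[IndividualDataset]:
    """Independent datasets, one per cohort, sharing the SNP panel."""
    if not cohorts:
        raise ValueError("need at least one cohort")
    names = [c.name for c in cohorts]
    if len(set(names)) != len(names):
        raise ValueError("duplicate cohort names")
    children = np.random.SeedSequence(seed).spawn(len(cohorts))
    return [
        simulate_cohort(c, phenotypes, pheno_corr, effects,
                        seed=np.random.default_rng(s), **kwargs)
        for c, s in zip(cohorts, children)
    ]


# --- default study design -------------------------------------------------

_LOG_MARKERS = {"BG", "BMI", "CRP", "HDL-C", "HR", "TC", "TG"}
MARKERS = ("BG", "BMI", "CRP", "creatinine", "DBP", "FVC",
           "HC", "HDL-C", "HR", "SBP", "TC", "TG")
OUTCOMES = ("AD", "AF", "cancer", "CHD", "DM", "HF", "stroke", "death")


def default_phenotypes(n_visits: int = 4) -> list[PhenotypeSpec]:
    """The 20-phenotype panel: 12 quantitative markers (log scale where the
    raw distribution is right-skewed) plus 7 diseases and death as
    age-at-onset outcomes."""
    phenos = [
        PhenotypeSpec(m, QUANTITATIVE, "marker",
                      log_transform=m in _LOG_MARKERS, n_visits=n_visits)
        for m in MARKERS
    ]
    phenos += [PhenotypeSpec(o, TIME_TO_EVENT, "outcome") for o in OUTCOMES]
    return phenos


def default_cohorts(scale: float = 1.0) -> list[CohortSpec]:
    """Five cohorts mirroring a multi-study consortium design totalling
    33,431 subjects at scale 1.0; ``scale`` shrinks every cohort for
    fast runs (minimum 50 subjects each)."""
    all_p = MARKERS + OUTCOMES

    def sub(exclude: tuple[str, ...]) -> tuple[str, ...]:
        return tuple(p for p in all_p if p not in exclude)

    raw = [
        ("ARIC", 9612, sub(("AD",)), 54.3, 5.7, 4),
        ("CHS", 3182, sub(()), 72.4, 5.4, 6),
        ("FHS", 8628, sub(()), 37.8, 9.3, 8),
        ("MESA", 2527, sub(("cancer", "AD")), 64.3, 10.2, 5),
        ("HRS", 9482, sub(("creatinine", "FVC", "HC", "HR", "TG", "AF")), 58.2, 9.1, 2),
    ]
    return [
        CohortSpec(name, max(50, int(round(n * scale))), subset,
                   age_mean=am, age_sd=asd, n_visits=nv)
        for name, n, subset, am, asd, nv in raw
    ]


__all__ = [
    "make_phenotype_correlation",
    "simulate_genotypes",
    "simulate_cohort",
    "simulate_study",
    "IndividualDataset",
    "default_phenotypes",
    "default_cohorts",
    "MARKERS",
    "OUTCOMES",
    "DEFAULT_ICC",
]
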