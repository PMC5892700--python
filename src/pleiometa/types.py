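"""Core record types shared across the pipeline.

The pipeline moves per-SNP association statistics through two combination
pathways (across cohorts then phenotypes, or the reverse), so the containers
here are deliberately small, validated dataclasses rather than bare tuples:
an :class:`AssocStat` is one stage-1 regression result, a :class:`MetaResult`
one fixed-effects pool, and a :class:`PleioResult` the full stage-2 test
battery for one SNP in one phenotype domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as _st

QUANTITATIVE = "quantitative"
BINARY = "binary"
TIME_TO_EVENT = "time-to-event"
PHENOTYPE_KINDS = (QUANTITATIVE, BINARY, TIME_TO_EVENT)

GW_SIGNIFICANCE = 5e-8


def two_sided_p(z: float) -> float:
    """Two-sided p-value of a Wald z statistic under the standard normal."""
    return float(2.0 * _st.norm.sf(abs(z)))


@dataclass(frozen=True)
class PhenotypeSpec:
    """Definition of one study phenotype.

    ``domain_tag`` separates quantitative physiological markers from
    disease/death risk outcomes; markers may be measured at several visits,
    outcomes carry a single event indicator with an age at onset/censoring.
    """

    name: str
    kind: str
    domain_tag: str = "marker"
    log_transform: bool = False
    n_visits: int = 1

    def __post_init__(self) -> None:
        if self.kind not in PHENOTYPE_KINDS:
            raise ValueError(f"unknown phenotype kind {self.kind!r}")
        if self.domain_tag not in ("marker", "outcome"):
            raise ValueError(f"unknown domain_tag {self.domain_tag!r}")
        if self.n_visits < 1:
            raise ValueError("n_visits must be >= 1")
        if self.domain_tag == "marker" and self.kind != QUANTITATIVE:
            raise ValueError("marker phenotypes must be quantitative")
        if self.kind in (BINARY, TIME_TO_EVENT) and self.n_visits != 1:
            raise ValueError("binary/time-to-event phenotypes have one visit")


@dataclass(frozen=True)
class CohortSpec:
    """One cohort: its size, age structure and available phenotype subset."""

    name: str
    n_subjects: int
    phenotype_subset: tuple[str, ...]
    age_mean: float = 60.0
    age_sd: float = 8.0
    n_visits: int | None = None  # overrides PhenotypeSpec.n_visits when set

    def __post_init__(self) -> None:
        if self.n_subjects < 50:
            raise ValueError("cohorts need n_subjects >= 50")
        if not self.phenotype_subset:
            raise ValueError("phenotype_subset must be non-empty")


@dataclass(frozen=True)
class EffectConfig:
    """True genetic effect geometry for one simulated SNP.

    ``betas`` are in phenotype-standard-deviation units per effect-allele
    copy.  ``pattern`` is a declared geometry: ``aligned`` effects share a
    sign on correlated phenotypes, ``antagonistic`` effects oppose each
    other on positively correlated phenotypes — the configuration the
    omnibus test is designed to detect.  ``cohort_multipliers`` inject
    inter-cohort effect-size heterogeneity.
    """

    snp_id: str
    maf: float
    betas: Mapping[str, float] = field(default_factory=dict)
    pattern: str = "custom"
    cohort_multipliers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError("maf must be in (0, 0.5]")
        if self.pattern not in ("null", "aligned", "antagonistic", "custom"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.pattern == "null" and any(b != 0 for b in self.betas.values()):
            raise ValueError("pattern='null' requires all betas = 0")

    def multiplier(self, cohort: str) -> float:
        return float(self.cohort_multipliers.get(cohort, 1.0))


@dataclass(frozen=True)
class AssocStat:
    """One stage-1 association record: SNP x phenotype x cohort."""

    snp_id: str
    phenotype: str
    cohort: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    z: float
    p: float
    n: int

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}/{self.phenotype}/{self.cohort}: se must be > 0")
        if abs(self.z - self.beta / self.se) > 1e-9 * max(1.0, abs(self.z)):
            raise ValueError("z inconsistent with beta/se")
        if not (0.0 < self.p <= 1.0):
            raise ValueError("p must be in (0, 1]")

    @classmethod
    def from_beta_se(
        cls,
        snp_id: str,
        phenotype: str,
        cohort: str,
        beta: float,
        se: float,
        n: int,
        effect_allele: str = "A",
        other_allele: str = "G",
        eaf: float = float("nan"),
    ) -> "AssocStat":
        z = beta / se
        return cls(
            snp_id=snp_id,
            phenotype=phenotype,
            cohort=cohort,
            effect_allele=effect_allele,
            other_allele=other_allele,
            eaf=eaf,
            beta=float(beta),
            se=float(se),
            z=float(z),
            p=max(two_sided_p(z), 1e-300),
            n=int(n),
        )

    def flipped(self) -> "AssocStat":
        """The same record expressed for the opposite effect allele."""
        return AssocStat(
            snp_id=self.snp_id,
            phenotype=self.phenotype,
            cohort=self.cohort,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            eaf=1.0 - self.eaf if np.isfinite(self.eaf) else self.eaf,
            beta=-self.beta,
            se=self.se,
            z=-self.z,
            p=self.p,
            n=self.n,
        )


@dataclass(frozen=True)
class MetaResult:
    """Inverse-variance fixed-effects pool of one SNP x phenotype."""

    snp_id: str
    phenotype: str
    beta: float
    se: float
    z: float
    p: float
    weights: tuple[float, ...]
    cohorts: tuple[str, ...]
    Q: float
    I2: float | None
    n_cohorts: int
    n: int


@dataclass(frozen=True)
class FisherResult:
    """Fisher combination of m independent p-values: -2*sum(ln p) ~ chi2_2m."""

    statistic: float
    df: int
    p: float
    n_combined: int


@dataclass(frozen=True)
class PrioritizationRecord:
    snp_id: str
    fisher_statistic: float
    df: int
    p_prioritize: float
    rank: int
    selected: bool


@dataclass(frozen=True)
class DomainSpec:
    """A named phenotype domain over which pleiotropy is tested."""

    name: str
    phenotypes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.phenotypes:
            raise ValueError("domain must contain at least one phenotype")


@dataclass
class PleioResult:
    """Stage-2 test battery for one SNP x domain.

    Pathway 1 (cohorts first): MOp / MOb omnibus on meta z-scores, MFp
    Fisher over meta p-values, FcFp Fisher over per-phenotype Fisher
    p-values.  Pathway 2 (phenotypes first): per-cohort OpC/ObC omnibus
    and FpC Fisher, combined across cohorts into OpFc / ObFc / FpFc.
    """

    snp_id: str
    domain: str
    pathway1: dict[str, float] = field(default_factory=dict)
    pathway2: dict[str, float] = field(default_factory=dict)
    per_cohort: dict[str, dict[str, float]] = field(default_factory=dict)
    univariate_meta_p: dict[str, float] = field(default_factory=dict)

    _ORDER = ("MOp", "MOb", "MFp", "FcFp", "OpFc", "ObFc", "FpFc")

    def tests(self) -> dict[str, float]:
        out = dict(self.pathway1)
        out.update(self.pathway2)
        return out

    @property
    def min_p(self) -> float:
        return min(self.tests().values())

    @property
    def best_test(self) -> str:
        tests = self.tests()
        return min(
            (t for t in self._ORDER if t in tests),
            key=lambda t: (tests[t], self._ORDER.index(t)),
        )

    @property
    def best_pathway(self) -> int:
        return 1 if self.best_test in ("MOp", "MOb", "MFp", "FcFp") else 2

    @property
    def genome_wide(self) -> bool:
        return self.min_p < GW_SIGNIFICANCE


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds of the classification stage.

    ``orders_tol`` absorbs the rounding of p-values printed with three
    significant digits: the >=2-orders-of-magnitude gap rule is evaluated
    as log10(p_F) - log10(p_O) >= ratio_orders - orders_tol.
    """

    p_gw: float = GW_SIGNIFICANCE
    ratio_orders: float = 2.0
    orders_tol: float = 0.05
    validation_alpha: float = 0.05
    suggestive: float = 0.1
    replication_orders: float = 0.2
    flat_prior_p: float = 0.4
    top_n: int = 1000
    permutations: int = 250

    def __post_init__(self) -> None:
        if self.ratio_orders <= self.replication_orders:
            raise ValueError("ratio_orders must exceed replication_orders")


@dataclass(frozen=True)
class ClassifiedSNP:
    """Final label for one SNP: heterogeneity group and audit flags."""

    snp_id: str
    pathway: int
    domain: str
    group: str  # HP | HB | HP/HB | M | none
    validated: bool | None = None
    novel: bool | None = None
    replicated_cohort_count: int | None = None

    @property
    def antagonistic(self) -> bool:
        return self.group in ("HP", "HB", "HP/HB")


ANTAGONISTIC_GROUPS = ("HP", "HB", "HP/HB")

__all__ = [
    "PhenotypeSpec",
    "CohortSpec",
    "EffectConfig",
    "AssocStat",
    "MetaResult",
    "FisherResult",
    "PrioritizationRecord",
    "DomainSpec",
    "PleioResult",
    "Thresholds",
    "ClassifiedSNP",
    "GW_SIGNIFICANCE",
    "ANTAGONISTIC_GROUPS",
    "QUANTITATIVE",
    "BINARY",
    "TIME_TO_EVENT",
    "two_sided_p",
]
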