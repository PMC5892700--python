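"""Stage-2 primitive tests: fixed-effects meta-analysis, Fisher p-value
combination, Cochran's Q / I-squared heterogeneity, and allele
harmonization across cohorts."""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _st

from .types import AssocStat, FisherResult, MetaResult, two_sided_p

log = logging.getLogger(__name__)

P_FLOOR = 1e-300  # keeps ln(p) finite; clipping is logged

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class AlleleMismatchError(ValueError):
    """Cohort records report irreconcilable allele pairs for one SNP."""


def harmonize_alleles(stats: Sequence[AssocStat]) -> list[AssocStat]:
    """Flip records of one SNP to a single effect allele (the first
    record's), negating beta and complementing eaf where needed.

    Strand-ambiguous A/T and C/G SNPs are kept but logged; allele pairs
    that match neither directly nor flipped raise
    :class:`AlleleMismatchError` so the caller can exclude the SNP.
    """
    if not stats:
        return []
    ref = stats[0]
    ea, oa = ref.effect_allele, ref.other_allele
    if _COMPLEMENT.get(ea) == oa:
        log.warning("SNP %s is strand-ambiguous (%s/%s)", ref.snp_id, ea, oa)
    out = []
    for s in stats:
        if (s.effect_allele, s.other_allele) == (ea, oa):
            out.append(s)
        elif (s.effect_allele, s.other_allele) == (oa, ea):
            out.append(s.flipped())
        else:
            raise AlleleMismatchError(
                f"SNP {s.snp_id} cohort {s.cohort}: alleles "
                f"{s.effect_allele}/{s.other_allele} irreconcilable with {ea}/{oa}"
            )
    return out


def fixed_effects_meta(stats: Sequence[AssocStat]) -> MetaResult:
    """Inverse-variance weighted fixed-effects pool across cohorts.

    beta_meta = sum(w_j beta_j) / sum(w_j) with w_j = 1/se_j^2 and
    variance 1/sum(w_j); the p-value is a two-sided Wald test.
    """
    if not stats:
        raise ValueError("fixed_effects_meta needs at least one cohort record")
    for s in stats:
        if s.se <= 0:
            raise ValueError(f"cohort {s.cohort}: se must be positive")
    betas = np.array([s.beta for s in stats])
    w = np.array([1.0 / s.se**2 for s in stats])
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = beta / se
    Q = float(np.sum(w * (betas - beta) ** 2))
    k = len(stats)
    I2 = max(0.0, (Q - (k - 1)) / Q) * 100.0 if (k >= 2 and Q > 0) else (0.0 if k >= 2 else None)
    return MetaResult(
        snp_id=stats[0].snp_id,
        phenotype=stats[0].phenotype,
        beta=beta,
        se=se,
        z=float(z),
        p=max(two_sided_p(z), P_FLOOR),
        weights=tuple(float(x) for x in w),
        cohorts=tuple(s.cohort for s in stats),
        Q=Q,
        I2=I2,
        n_cohorts=k,
        n=int(sum(s.n for s in stats)),
    )


def fisher_combine(pvalues: Iterable[float]) -> FisherResult:
    """Fisher's method: -2 sum(ln p_i) ~ chi-square with 2m df.

    Zero p-values are clipped to 1e-300 (logged); values above 1 are
    rejected.  A single p is returned unchanged (df-2 identity).
    """
    ps = np.asarray(list(pvalues), dtype=float)
    if ps.size == 0:
        raise ValueError("fisher_combine needs at least one p-value")
    if np.any(ps > 1.0) or np.any(ps < 0.0) or not np.all(np.isfinite(ps)):
        raise ValueError("p-values must lie in (0, 1]")
    if np.any(ps == 0.0):
        log.warning("clipping %d zero p-value(s) to %.0e", int(np.sum(ps == 0)), P_FLOOR)
        ps = np.clip(ps, P_FLOOR, 1.0)
    stat = float(-2.0 * np.sum(np.log(ps)))
    df = 2 * ps.size
    return FisherResult(
        statistic=stat,
        df=df,
        p=max(float(_st.chi2.sf(stat, df)), P_FLOOR),
        n_combined=ps.size,
    )


def heterogeneity_I2(stats: Sequence[AssocStat]) -> float | None:
    """Percentage of effect-size variability due to between-cohort
    heterogeneity: I2 = max(0, (Q - (k-1))/Q) * 100 with Cochran's
    Q = sum w_j (beta_j - beta_meta)^2.  Undefined (None) for < 2 cohorts.
    """
    if len(stats) < 2:
        return None
    return fixed_effects_meta(list(stats)).I2


__all__ = [
    "fixed_effects_meta",
    "fisher_combine",
    "heterogeneity_I2",
    "harmonize_alleles",
    "AlleleMismatchError",
    "P_FLOOR",
]
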