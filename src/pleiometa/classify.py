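"""Decision rules on the stage-2 battery: genome-wide significance,
antagonistic-heterogeneity groups, cross-cohort validation and
replication, prior-evidence novelty, and the efficiency ratio.

Group semantics (per SNP, within its best pathway): with p_Op and p_Ob the
Sigma_P- and Sigma_B-based omnibus p-values and p_F the corresponding
Fisher pleiotropic p (MFp in pathway 1, FpFc in pathway 2),

  HP    — p_Op genome-wide and p_F larger by >= 2 orders of magnitude;
  HB    — the same for p_Ob;
  HP/HB — both;
  M     — at least one test genome-wide but neither gap reaches 2 orders.

A >=2-order p-value gap of an omnibus test below the Fisher test is the
signature of antagonistic heterogeneity: genetic effects pointing in
opposite directions on directly correlated phenotypes.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

from .meta import fisher_combine
from .types import (
    ANTAGONISTIC_GROUPS,
    ClassifiedSNP,
    FisherResult,
    PleioResult,
    Thresholds,
)

DEFAULT_THRESHOLDS = Thresholds()


def _orders_gap(p_fisher: float, p_omnibus: float) -> float:
    return math.log10(p_fisher) - math.log10(p_omnibus)


def assign_group(
    pathway: int,
    p_op: float,
    p_ob: float,
    p_fisher: float,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> str:
    """Heterogeneity group from the three battery p-values of one pathway.

    ``p_fisher`` must be the pathway's Fisher comparator: MFp for pathway
    1, FpFc for pathway 2.  Returns 'HP', 'HB', 'HP/HB', 'M' or 'none'.
    """
    if pathway not in (1, 2):
        raise ValueError("pathway must be 1 or 2")
    for name, p in (("p_op", p_op), ("p_ob", p_ob), ("p_fisher", p_fisher)):
        if p is None or not (0.0 < p <= 1.0) or math.isnan(p):
            raise ValueError(f"{name} must be a p-value in (0, 1], got {p!r}")
    cut = thresholds.ratio_orders - thresholds.orders_tol
    hp = p_op < thresholds.p_gw and _orders_gap(p_fisher, p_op) >= cut
    hb = p_ob < thresholds.p_gw and _orders_gap(p_fisher, p_ob) >= cut
    if hp and hb:
        return "HP/HB"
    if hp:
        return "HP"
    if hb:
        return "HB"
    if min(p_op, p_ob, p_fisher) < thresholds.p_gw:
        return "M"
    return "none"


def classify_result(
    pleio: PleioResult,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
    univariate_meta_p: Mapping[str, float] | None = None,
    n_cohorts: int | None = None,
) -> ClassifiedSNP:
    """Classify one SNP from its merged stage-2 battery.

    The pathway is the one holding the battery's smallest p-value; the
    validation flag is filled when the needed inputs are present.
    """
    pathway = pleio.best_pathway
    if pathway == 1:
        p_op, p_ob, p_f = (pleio.pathway1[k] for k in ("MOp", "MOb", "MFp"))
    else:
        p_op, p_ob, p_f = (pleio.pathway2[k] for k in ("OpFc", "ObFc", "FpFc"))
    group = assign_group(pathway, p_op, p_ob, p_f, thresholds)
    validated: bool | None = None
    if group != "none":
        uni = univariate_meta_p if univariate_meta_p is not None else pleio.univariate_meta_p
        if pathway == 1 and uni:
            validated = validate(1, [], list(uni.values()), n_cohorts or 1, thresholds)
        elif pathway == 2 and pleio.per_cohort:
            best = pleio.best_test  # OpFc/ObFc/FpFc -> per-cohort OpC/ObC/FpC
            per = [c[best[:2] + "C"] for c in pleio.per_cohort.values()]
            validated = validate(2, per, [], len(per), thresholds)
    replicated = None
    if pleio.per_cohort:
        replicated = replicate_antagonism(pleio.per_cohort.values(), thresholds)
    return ClassifiedSNP(
        snp_id=pleio.snp_id, pathway=pathway, domain=pleio.domain,
        group=group, validated=validated,
        replicated_cohort_count=replicated,
    )


def validate(
    pathway: int,
    per_cohort_p: Sequence[float],
    univariate_p: Sequence[float],
    n_cohorts: int,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> bool:
    """Cross-validation of a genome-wide pleiotropic association.

    Pathway 1: automatically validated when every univariate meta p-value
    exceeds the genome-wide cut-off — the GW pleiotropic signal is then
    assembled from sub-GW parts.  Pathway 2: automatically validated when
    no single cohort is GW by itself; otherwise at least one additional
    cohort must reach the Bonferroni level 0.05/(n_cohorts - 1).
    """
    if pathway == 1:
        return all(p > thresholds.p_gw for p in univariate_p)
    gw = [p for p in per_cohort_p if p < thresholds.p_gw]
    if not gw:
        return True
    if n_cohorts < 2:
        raise ValueError("Bonferroni validation needs >= 2 cohorts")
    bonf = thresholds.validation_alpha / (n_cohorts - 1)
    others = [p for p in per_cohort_p if p >= thresholds.p_gw]
    return any(p < bonf for p in others)


def replicate_antagonism(
    per_cohort: Sequence[Mapping[str, float]] | Mapping[str, Mapping[str, float]],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> int:
    """Count cohorts replicating the antagonistic signature.

    A cohort counts when the pattern is at least suggestive
    (min(OpC, ObC) < 0.1 or FpC < 0.1) and the omnibus p undercuts the
    Fisher p by >= 0.2 orders of magnitude.  Replication requires >= 2
    cohorts (checked by the caller against the returned count).
    """
    if isinstance(per_cohort, Mapping):
        per_cohort = list(per_cohort.values())
    count = 0
    for c in per_cohort:
        p_o = min(c["OpC"], c["ObC"])
        if min(p_o, c["FpC"]) >= thresholds.suggestive:
            continue
        if _orders_gap(c["FpC"], p_o) >= thresholds.replication_orders:
            count += 1
    return count


def prior_evidence_fisher(
    reported: Mapping[str, float],
    k_total: int,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> tuple[FisherResult, bool]:
    """Fisher combination of prior-catalog p-values with a flat penalty.

    Every phenotype without a reported prior p-value contributes the flat
    p = 0.4, so sparse prior evidence cannot fake pleiotropy.  The SNP is
    novel when the combined prior p stays above genome-wide significance
    and no single reported prior p is genome-wide by itself.
    """
    if not (0 <= len(reported) <= k_total):
        raise ValueError("reported count exceeds k_total")
    for pheno, p in reported.items():
        if not (0.0 < p <= 1.0):
            raise ValueError(f"prior p for {pheno} outside (0, 1]")
    ps = list(reported.values()) + [thresholds.flat_prior_p] * (k_total - len(reported))
    fr = fisher_combine(ps)
    novel = fr.p >= thresholds.p_gw and all(p >= thresholds.p_gw for p in reported.values())
    return fr, novel


def efficiency_ratio(p_a: float, n_a: int, p_b: float, n_b: int) -> float:
    """Efficiency of study a relative to study b, quantified by the ratio
    of log10(p)/n: (log10 p_a * n_b) / (log10 p_b * n_a)."""
    for name, p in (("p_a", p_a), ("p_b", p_b)):
        if not (0.0 < p < 1.0):
            raise ValueError(f"{name} must be in (0, 1) (log10 of 1 is zero)")
    if n_a <= 0 or n_b <= 0:
        raise ValueError("sample sizes must be positive")
    return (math.log10(p_a) * n_b) / (math.log10(p_b) * n_a)


def classify_table(
    rows,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
):
    """Apply :func:`assign_group` to a fixture-style table.

    ``rows`` is an iterable of mappings with keys ``pathway``, ``p_op``,
    ``p_ob``, ``p_mfp`` (pathway-1 comparator) and ``p_fisher``; returns
    the predicted group per row.
    """
    out = []
    for r in rows:
        pw = int(r["pathway"])
        p_f = r["p_mfp"] if pw == 1 else r["p_fisher"]
        out.append(assign_group(pw, r["p_op"], r["p_ob"], p_f, thresholds))
    return out


__all__ = [
    "assign_group",
    "classify_result",
    "classify_table",
    "validate",
    "replicate_antagonism",
    "prior_evidence_fisher",
    "efficiency_ratio",
    "DEFAULT_THRESHOLDS",
]
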