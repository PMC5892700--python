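"""Stage-2 orchestration: the seven-test battery over both pathways.

Pathway 1 combines statistics first across cohorts (fixed-effects
meta-test and Fisher test per phenotype) and then across phenotypes
(omnibus tests MOp / MOb on the meta z-score vector, Fisher tests MFp /
FcFp).  Pathway 2 combines first across phenotypes within each cohort
(omnibus OpC / ObC and Fisher FpC) and then across cohorts by Fisher
(OpFc / ObFc / FpFc).  Phenotypes missing in a cohort are dropped from
that cohort's tests (K_j reduced), never imputed.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .meta import fisher_combine, fixed_effects_meta, harmonize_alleles
from .omnibus import CorrelationMatrix, omnibus_test
from .types import AssocStat, DomainSpec, MetaResult, PleioResult

from .synthetic import MARKERS, OUTCOMES


def default_domains(phenotypes: Sequence[str] | None = None) -> list[DomainSpec]:
    """The three standard domains: 12 quantitative markers, disease/death
    outcomes, and all 20 phenotypes (restricted to ``phenotypes`` when a
    study uses a subset)."""
    all20 = list(MARKERS) + list(OUTCOMES)
    if phenotypes is not None:
        avail = [p for p in all20 if p in phenotypes]
        avail += [p for p in phenotypes if p not in avail]
    else:
        avail = all20
    markers = tuple(p for p in avail if p in MARKERS)
    outcomes = tuple(p for p in avail if p in OUTCOMES)
    domains = []
    if markers:
        domains.append(DomainSpec("markers12", markers))
    if outcomes:
        domains.append(DomainSpec("outcomes", outcomes))
    domains.append(DomainSpec("all20", tuple(avail)))
    return domains


def meta_analyze_snp(
    stats: Sequence[AssocStat],
) -> tuple[dict[str, MetaResult], dict[str, float]]:
    """Per-phenotype fixed-effects meta and Fisher-across-cohorts p for
    one SNP's stage-1 records (alleles are harmonized first)."""
    by_pheno: dict[str, list[AssocStat]] = {}
    for s in harmonize_alleles(list(stats)):
        by_pheno.setdefault(s.phenotype, []).append(s)
    meta = {p: fixed_effects_meta(recs) for p, recs in by_pheno.items()}
    fisher_c = {p: fisher_combine([s.p for s in recs]).p for p, recs in by_pheno.items()}
    return meta, fisher_c


def run_pathway1(
    snp_id: str,
    domain: DomainSpec,
    meta_results: Mapping[str, MetaResult],
    fisher_cohort_p: Mapping[str, float],
    sigma_mP: CorrelationMatrix,
    sigma_mB: CorrelationMatrix,
) -> PleioResult:
    """Cohorts-first battery: MOp, MOb, MFp, FcFp for one SNP x domain."""
    phenos = [p for p in domain.phenotypes if p in meta_results]
    if not phenos:
        raise ValueError(f"no univariate meta results in domain {domain.name}")
    z = {p: meta_results[p].z for p in phenos}
    missing = [p for p in phenos if p not in sigma_mP.phenotypes or p not in sigma_mB.phenotypes]
    if missing:
        raise ValueError(f"correlation matrices lack phenotypes {missing}")
    res = PleioResult(snp_id=snp_id, domain=domain.name)
    res.pathway1["MOp"] = omnibus_test(z, sigma_mP.subset(phenos)).p
    res.pathway1["MOb"] = omnibus_test(z, sigma_mB.subset(phenos)).p
    res.pathway1["MFp"] = fisher_combine([meta_results[p].p for p in phenos]).p
    res.pathway1["FcFp"] = fisher_combine([fisher_cohort_p[p] for p in phenos]).p
    res.univariate_meta_p = {p: meta_results[p].p for p in phenos}
    return res


def run_pathway2(
    snp_id: str,
    domain: DomainSpec,
    stage1: Mapping[str, Mapping[str, AssocStat]],
    sigma_P: Mapping[str, CorrelationMatrix],
    sigma_B: Mapping[str, CorrelationMatrix],
) -> PleioResult:
    """Phenotypes-first battery.

    ``stage1`` maps cohort -> phenotype -> AssocStat; ``sigma_P`` /
    ``sigma_B`` map cohort -> cohort-scope matrices.  Per cohort j the
    omnibus tests OpC_j / ObC_j and Fisher FpC_j run over that cohort's
    available domain phenotypes; the per-cohort p-values are then combined
    across cohorts by Fisher.
    """
    res = PleioResult(snp_id=snp_id, domain=domain.name)
    for cohort, stats in stage1.items():
        phenos = [p for p in domain.phenotypes if p in stats]
        if not phenos:
            continue
        if cohort not in sigma_P or cohort not in sigma_B:
            raise ValueError(f"missing correlation matrices for cohort {cohort}")
        z = {p: stats[p].z for p in phenos}
        res.per_cohort[cohort] = {
            "OpC": omnibus_test(z, sigma_P[cohort].subset(phenos)).p,
            "ObC": omnibus_test(z, sigma_B[cohort].subset(phenos)).p,
            "FpC": fisher_combine([stats[p].p for p in phenos]).p,
        }
    if not res.per_cohort:
        raise ValueError(f"no cohort covers domain {domain.name}")
    for test, combined in (("OpC", "OpFc"), ("ObC", "ObFc"), ("FpC", "FpFc")):
        res.pathway2[combined] = fisher_combine(
            [c[test] for c in res.per_cohort.values()]
        ).p
    return res


def run_all(
    snp_id: str,
    stage1: Mapping[str, Mapping[str, AssocStat]],
    domains: Sequence[DomainSpec],
    sigma_mP: CorrelationMatrix,
    sigma_mB: CorrelationMatrix,
    sigma_jP: Mapping[str, CorrelationMatrix],
    sigma_jB: Mapping[str, CorrelationMatrix],
) -> list[PleioResult]:
    """Both pathways on every domain for one SNP.

    Returns one merged :class:`PleioResult` per domain; the GW flag and
    best test/pathway are properties of the result objects.
    """
    flat = [s for per_pheno in stage1.values() for s in per_pheno.values()]
    meta_results, fisher_c = meta_analyze_snp(flat)
    out = []
    for domain in domains:
        r1 = run_pathway1(snp_id, domain, meta_results, fisher_c, sigma_mP, sigma_mB)
        r2 = run_pathway2(snp_id, domain, stage1, sigma_jP, sigma_jB)
        merged = PleioResult(
            snp_id=snp_id, domain=domain.name,
            pathway1=r1.pathway1, pathway2=r2.pathway2,
            per_cohort=r2.per_cohort, univariate_meta_p=r1.univariate_meta_p,
        )
        out.append(merged)
    return out


def best_domain_result(results: Sequence[PleioResult]) -> PleioResult:
    """Smallest-p domain attribution when several domains are tested."""
    return min(results, key=lambda r: r.min_p)


def group_stage1_by_cohort(
    stats: Sequence[AssocStat],
) -> dict[str, dict[str, dict[str, AssocStat]]]:
    """snp_id -> cohort -> phenotype -> AssocStat."""
    out: dict[str, dict[str, dict[str, AssocStat]]] = {}
    for s in stats:
        out.setdefault(s.snp_id, {}).setdefault(s.cohort, {})[s.phenotype] = s
    return out


__all__ = [
    "default_domains",
    "meta_analyze_snp",
    "run_pathway1",
    "run_pathway2",
    "run_all",
    "best_domain_result",
    "group_stage1_by_cohort",
]
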