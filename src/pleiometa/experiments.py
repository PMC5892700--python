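"""Calibration and validation batteries.

Each function here sets up a synthetic study with the conditions the
method is designed for, runs the real pipeline on it, and returns summary
numbers: type-I error of the seven tests under a global null, the
direction of the omnibus-vs-Fisher gap under antagonistic and aligned
effect geometry, agreement of the permutation (Sigma_B) and phenotype
(Sigma_P) correlation estimates, stage-1 parameter recovery, and the
worked-example checks on the shipped classification fixture.

These batteries use single-visit measurements without within-subject
noise (icc = 1) so the realized phenotype correlation equals the nominal
value being studied, and the parameter-recovery runs switch off the
shared latent component of outcomes (``outcome_latent_scale = 0``) so the
injected coefficient is exactly the marginal estimand of the fitted
model.
"""

from __future__ import annotations

import numpy as np

from . import classify, io, pipeline, stage1, synthetic
from .meta import fisher_combine, fixed_effects_meta
from .omnibus import estimate_sigma_B, estimate_sigma_P, omnibus_test
from .types import (
    AssocStat,
    BINARY,
    CohortSpec,
    DomainSpec,
    EffectConfig,
    PhenotypeSpec,
    QUANTITATIVE,
    TIME_TO_EVENT,
    Thresholds,
    two_sided_p,
)

# Prior-study comparison for the triglycerides association: p-value and
# sample size of the present design versus the published catalog entry.
EFFICIENCY_EXAMPLE = {"p_a": 9.4e-14, "n_a": 33_431, "p_b": 1.6e-14, "n_b": 140_059}


def table2_group_counts(thresholds: Thresholds | None = None) -> dict:
    """Re-derive the heterogeneity group of every fixture SNP and count.

    Returns the per-group totals, the pathway-1 row count, and the number
    of rows whose derived label matches the printed one.
    """
    thresholds = thresholds or classify.DEFAULT_THRESHOLDS
    df = io.load_table2_fixture()
    predicted = classify.classify_table(df.to_dict("records"), thresholds)
    df = df.assign(predicted=predicted)
    counts = df["predicted"].value_counts().to_dict()
    return {
        "n_rows": int(len(df)),
        "n_match": int((df["predicted"] == df["group"]).sum()),
        "HP": int(counts.get("HP", 0)),
        "HB": int(counts.get("HB", 0)),
        "HP/HB": int(counts.get("HP/HB", 0)),
        "M": int(counts.get("M", 0)),
        "antagonistic": int(sum(counts.get(g, 0) for g in ("HP", "HB", "HP/HB"))),
        "pathway1": int((df["pathway"] == 1).sum()),
    }


def efficiency_example() -> float:
    """The worked efficiency-ratio comparison (about 4-fold)."""
    e = EFFICIENCY_EXAMPLE
    return classify.efficiency_ratio(e["p_a"], e["n_a"], e["p_b"], e["n_b"])


def _quant_phenotypes(K: int) -> list[PhenotypeSpec]:
    return [PhenotypeSpec(f"P{i+1}", QUANTITATIVE, "marker") for i in range(K)]


def _study(
    n_cohorts: int,
    n_per_cohort: int,
    phenos: list[PhenotypeSpec],
    corr: np.ndarray,
    effects: list[EffectConfig],
    seed: int,
    **kwargs,
) -> list[synthetic.IndividualDataset]:
    cohorts = [
        CohortSpec(f"C{j+1}", n_per_cohort, tuple(p.name for p in phenos))
        for j in range(n_cohorts)
    ]
    kwargs.setdefault("icc", 1.0)
    kwargs.setdefault("missing_rate", 0.0)
    return synthetic.simulate_study(cohorts, phenos, corr, effects, seed=seed, **kwargs)


def _bulk_stage1(datasets, snp_prefix="s"):
    """Vectorized stage-1 z/beta/se for every SNP of every cohort.

    Returns {cohort: (snp_ids, phenotypes, beta, se)} with beta/se of
    shape (S, K)."""
    out = {}
    for ds in datasets:
        snps = list(ds.dosages)
        G = np.column_stack([ds.dosages[s] for s in snps])
        phenos = list(ds.phenotypes)
        Y = np.column_stack([ds.subject_values(p) for p in phenos])
        beta, se = stage1.bulk_linear_scan(G, Y, ds.covariates.to_numpy())
        out[ds.cohort] = (snps, phenos, beta, se)
    return out


def type_i_error(
    seed: int = 0,
    n_snps: int = 10_000,
    n_cohorts: int = 2,
    n_per_cohort: int = 1_000,
    K: int = 5,
    rho: float = 0.3,
    R: int = 100,
    pool_snps: int = 25,
    maf: float = 0.3,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Empirical rejection rate of each battery test on null SNPs.

    Exchangeable-correlation quantitative phenotypes, no genetic effects.
    Sigma_B is estimated once per scope by pooling the permutation
    z-vectors of ``pool_snps`` SNPs (the null z-vector law does not depend
    on the SNP), which removes the Monte-Carlo noise a small per-SNP R
    would inject into the chi-square reference.
    """
    rng = np.random.default_rng(seed)
    phenos = _quant_phenotypes(K)
    corr = synthetic.make_phenotype_correlation(K, rho, method="constant")
    effects = [
        EffectConfig(f"s{i}", maf=maf, pattern="null") for i in range(n_snps)
    ]
    datasets = _study(n_cohorts, n_per_cohort, phenos, corr, effects,
                      seed=int(rng.integers(2**31)))
    bulk = _bulk_stage1(datasets)

    sig_P = {d.cohort: estimate_sigma_P(datasets, d.cohort) for d in datasets}
    sig_P["meta"] = estimate_sigma_P(datasets, "meta")
    pool = [f"s{i}" for i in range(min(pool_snps, n_snps))]
    sig_B = {
        d.cohort: estimate_sigma_B(pool, datasets, d.cohort, R=R,
                                   seed=int(rng.integers(2**31)))
        for d in datasets
    }
    sig_B["meta"] = estimate_sigma_B(pool, datasets, "meta", R=R,
                                     seed=int(rng.integers(2**31)))

    pheno_names = [p.name for p in phenos]
    domain = DomainSpec("all", tuple(pheno_names))
    rej = {t: 0 for t in ("MOp", "MOb", "MFp", "FcFp", "OpFc", "ObFc", "FpFc")}
    for i in range(n_snps):
        stage1_stats = {}
        for ds in datasets:
            snps, phs, beta, se = bulk[ds.cohort]
            stage1_stats[ds.cohort] = {
                p: AssocStat.from_beta_se(f"s{i}", p, ds.cohort,
                                          beta[i, k], se[i, k], n=ds.n_subjects)
                for k, p in enumerate(phs)
            }
        results = pipeline.run_all(
            f"s{i}", stage1_stats, [domain],
            sig_P["meta"], sig_B["meta"], sig_P, sig_B,
        )
        for test, p in results[0].tests().items():
            if p < alpha:
                rej[test] += 1
    return {t: c / n_snps for t, c in rej.items()}


def antagonism_direction(
    seed: int = 0,
    n_seeds: int = 100,
    n_cohorts: int = 5,
    n_per_cohort: int = 2_000,
    rho: float = 0.6,
    beta: float = 0.4,
    maf: float = 0.3,
) -> dict[str, float]:
    """Fraction of replicates where the Sigma_P omnibus p undercuts the
    Fisher p for antagonistic effects, and exceeds it for aligned effects
    of equal magnitude (pathway 1: MOp versus MFp)."""
    phenos = _quant_phenotypes(2)
    corr = synthetic.make_phenotype_correlation(2, rho, method="constant")
    children = np.random.SeedSequence(seed).spawn(n_seeds)
    antag_smaller = aligned_larger = 0
    for ss in children:
        srng = np.random.default_rng(ss)
        effects = [
            EffectConfig("antag", maf=maf, betas={"P1": beta, "P2": -beta},
                         pattern="antagonistic"),
            EffectConfig("align", maf=maf, betas={"P1": beta, "P2": beta},
                         pattern="aligned"),
        ]
        datasets = _study(n_cohorts, n_per_cohort, phenos, corr, effects,
                          seed=int(srng.integers(2**31)))
        sigma_mP = estimate_sigma_P(datasets, "meta")
        bulk = _bulk_stage1(datasets)
        for which in ("antag", "align"):
            stats = []
            for ds in datasets:
                snps, phs, b, s = bulk[ds.cohort]
                i = snps.index(which)
                stats += [
                    AssocStat.from_beta_se(which, p, ds.cohort, b[i, k], s[i, k],
                                           n=ds.n_subjects)
                    for k, p in enumerate(phs)
                ]
            meta_results, _ = pipeline.meta_analyze_snp(stats)
            z = {p: m.z for p, m in meta_results.items()}
            p_op = omnibus_test(z, sigma_mP).p
            p_fisher = fisher_combine([m.p for m in meta_results.values()]).p
            if which == "antag" and p_op < p_fisher:
                antag_smaller += 1
            if which == "align" and p_op > p_fisher:
                aligned_larger += 1
    return {
        "antagonistic_omnibus_smaller": antag_smaller / n_seeds,
        "aligned_omnibus_larger": aligned_larger / n_seeds,
    }


def antagonism_classification(
    seed: int = 0,
    n_seeds: int = 20,
    n_cohorts: int = 5,
    n_per_cohort: int = 2_000,
    rho: float = 0.6,
    beta: float = 0.4,
    maf: float = 0.3,
    R: int = 100,
) -> dict[str, float]:
    """Fraction of replicates assigned an antagonistic group (HP, HB or
    HP/HB) for antagonistic-geometry SNPs, and the fraction of aligned
    SNPs ever reaching such a group (should be zero)."""
    phenos = _quant_phenotypes(2)
    corr = synthetic.make_phenotype_correlation(2, rho, method="constant")
    children = np.random.SeedSequence(seed).spawn(n_seeds)
    domain = DomainSpec("all", ("P1", "P2"))
    antag_hits = aligned_hits = 0
    for ss in children:
        srng = np.random.default_rng(ss)
        effects = [
            EffectConfig("antag", maf=maf, betas={"P1": beta, "P2": -beta},
                         pattern="antagonistic"),
            EffectConfig("align", maf=maf, betas={"P1": beta, "P2": beta},
                         pattern="aligned"),
        ]
        datasets = _study(n_cohorts, n_per_cohort, phenos, corr, effects,
                          seed=int(srng.integers(2**31)))
        sig_P = {d.cohort: estimate_sigma_P(datasets, d.cohort) for d in datasets}
        sig_P["meta"] = estimate_sigma_P(datasets, "meta")
        bulk = _bulk_stage1(datasets)
        for which in ("antag", "align"):
            sig_B = {
                d.cohort: estimate_sigma_B(which, datasets, d.cohort, R=R,
                                           seed=int(srng.integers(2**31)))
                for d in datasets
            }
            sig_B["meta"] = estimate_sigma_B(which, datasets, "meta", R=R,
                                             seed=int(srng.integers(2**31)))
            stage1_stats = {}
            for ds in datasets:
                snps, phs, b, s = bulk[ds.cohort]
                i = snps.index(which)
                stage1_stats[ds.cohort] = {
                    p: AssocStat.from_beta_se(which, p, ds.cohort, b[i, k],
                                              s[i, k], n=ds.n_subjects)
                    for k, p in enumerate(phs)
                }
            res = pipeline.run_all(which, stage1_stats, [domain],
                                   sig_P["meta"], sig_B["meta"], sig_P, sig_B)[0]
            cls = classify.classify_result(res)
            if which == "antag" and cls.antagonistic:
                antag_hits += 1
            if which == "align" and cls.antagonistic:
                aligned_hits += 1
    return {
        "antagonistic_assigned": antag_hits / n_seeds,
        "aligned_assigned": aligned_hits / n_seeds,
    }


def sigma_agreement(
    seed: int = 0,
    n_subjects: int = 5_000,
    K: int = 5,
    strength: float = 0.5,
    R: int = 250,
    n_snps: int = 10,
    maf: float = 0.3,
) -> dict[str, float]:
    """Entrywise agreement of the permutation estimate Sigma_B with the
    phenotype-correlation estimate Sigma_P under the null (max absolute
    off-diagonal difference, single cohort, linear models).

    The property under test is consistency — that Sigma_B estimates the
    same matrix Sigma_P does — so the permutation z-vectors of ``n_snps``
    exchangeable null SNPs (R permutations each) are pooled to keep the
    Monte-Carlo error of the Sigma_B estimate well below the band being
    checked."""
    rng = np.random.default_rng(seed)
    phenos = _quant_phenotypes(K)
    corr = synthetic.make_phenotype_correlation(K, strength,
                                                seed=int(rng.integers(2**31)))
    effects = [EffectConfig(f"s{i}", maf=maf, pattern="null")
               for i in range(n_snps)]
    datasets = _study(1, n_subjects, phenos, corr, effects,
                      seed=int(rng.integers(2**31)))
    sP = estimate_sigma_P(datasets, "C1")
    sB = estimate_sigma_B([e.snp_id for e in effects], datasets, "C1", R=R,
                          seed=int(rng.integers(2**31)))
    off = ~np.eye(K, dtype=bool)
    diff = np.abs(sB.values - sP.values)[off]
    return {"max_abs_diff": float(diff.max()), "mean_abs_diff": float(diff.mean())}


def parameter_recovery(
    seed: int = 0,
    n_reps: int = 200,
    beta: float = 0.25,
    maf: float = 0.3,
) -> dict[str, float]:
    """Fraction of replicates whose stage-1 estimate falls within 2
    standard errors of the injected effect, per phenotype kind.

    Quantitative markers use three visits through the random-intercept
    model; binary outcomes inject a log-odds ratio; ages at onset inject
    a log hazard ratio.  Outcomes are simulated without the shared latent
    so the injected coefficient equals the fitted model's estimand.
    """
    specs = {
        "quantitative": PhenotypeSpec("Q", QUANTITATIVE, "marker", n_visits=3),
        "binary": PhenotypeSpec("B", BINARY, "outcome"),
        "survival": PhenotypeSpec("S", TIME_TO_EVENT, "outcome"),
    }
    n_by_kind = {"quantitative": 500, "binary": 2_000, "survival": 1_500}
    children = np.random.SeedSequence(seed).spawn(n_reps)
    hits = {k: 0 for k in specs}
    for ss in children:
        srng = np.random.default_rng(ss)
        for kind, spec in specs.items():
            n = n_by_kind[kind]
            cohort = CohortSpec("C1", n, (spec.name, "pad"))
            pad = PhenotypeSpec("pad", QUANTITATIVE, "marker")
            eff = EffectConfig("s0", maf=maf, betas={spec.name: beta})
            ds = synthetic.simulate_cohort(
                cohort, [spec, pad], np.eye(2), [eff],
                seed=np.random.default_rng(srng.integers(2**31)),
                icc=0.5 if kind == "quantitative" else 1.0,
                missing_rate=0.0, outcome_latent_scale=0.0,
            )
            g = ds.dosages["s0"]
            if kind == "quantitative":
                est = stage1.fit_quantitative(
                    g, ds.measurements["Q"], ds.covariates,
                    visit_ages=ds.visit_ages["Q"], spec=spec,
                )
            elif kind == "binary":
                event, _ = ds.outcomes["B"]
                est = stage1.fit_binary(g, event, ds.covariates)
            else:
                event, age = ds.outcomes["S"]
                est = stage1.fit_survival(g, age, event, ds.covariates)
            if abs(est.beta - beta) <= 2.0 * est.se:
                hits[kind] += 1
    return {k: v / n_reps for k, v in hits.items()}


__all__ = [
    "table2_group_counts",
    "efficiency_example",
    "type_i_error",
    "antagonism_direction",
    "antagonism_classification",
    "sigma_agreement",
    "parameter_recovery",
    "EFFICIENCY_EXAMPLE",
]
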