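# pleiometa

Two-stage, two-pathway pleiotropic GWAS meta-analysis with omnibus tests
and antagonistic-heterogeneity classification.

## The problem

Genome-wide association studies of age-related phenotypes (lipids, blood
pressure, cardiovascular disease, death, ...) routinely pool evidence
across several cohorts and across many correlated phenotypes.  The usual
assumption is that a risk allele pushes correlated phenotypes in the
*same* direction, so a test that penalizes correlation (an omnibus test)
should give *larger* p-values than a naive Fisher combination.  For many
age-related traits the opposite happens: the allele's effects on directly
correlated phenotypes point in *opposite* directions — antagonistic
genetic heterogeneity — and the correlation-aware omnibus test becomes
dramatically *more* significant than the Fisher test.  This package
implements the full analysis that detects and classifies that signature,
together with a synthetic multi-cohort generator so every stage is
testable without access to controlled individual-level data.

## The statistics

For SNP effects β̂ᵢⱼ with standard errors σ̂ᵢⱼ (phenotype *i*, cohort *j*):

* **Fixed-effects meta-test** — β_meta = Σⱼ wⱼβ̂ⱼ / Σⱼ wⱼ with wⱼ = 1/σ̂ⱼ²,
  variance 1/Σⱼ wⱼ, two-sided Wald p-value; heterogeneity by Cochran's Q
  and I² = max(0, (Q − (k−1))/Q)·100.
* **Fisher combination** — −2 Σ ln pᵢ ~ χ²₂ₘ.
* **Omnibus test** — for the z-score vector **z** = β̂/σ̂ over the K
  phenotypes of one scope, **z**′Σ⁻¹**z** ~ χ²_K under the null, with Σ the
  z-score correlation matrix estimated either from phenotype correlations
  (Σ_P) or from 250 dosage permutations refitted against all phenotypes
  (Σ_B).  In two dimensions the statistic is
  (z₁²Σ₂₂ − z₁z₂Σ₂₁ − z₁z₂Σ₁₂ + z₂²Σ₁₁)/det Σ: opposite-sign z's on a
  positively correlated pair *inflate* the statistic beyond z₁² + z₂².
* **Two pathways** — pathway 1 combines cohorts first (tests MOp, MOb,
  MFp, FcFp), pathway 2 combines phenotypes first within each cohort and
  then cohorts by Fisher (OpFc, ObFc, FpFc).
* **Classification** — a SNP with a genome-wide (p < 5×10⁻⁸) omnibus test
  whose Fisher counterpart is ≥ 2 orders of magnitude weaker is labelled
  HP (Σ_P-based), HB (Σ_B-based) or HP/HB (both); genome-wide SNPs without
  such a gap are M.  Validation, per-cohort replication (≥ 0.2 orders in
  ≥ 2 cohorts), and prior-evidence novelty (Fisher with a flat p = 0.4
  penalty for unreported phenotypes) complete the decision rules.

## Worked example

Five cohorts of 2,000 subjects, two phenotypes correlated at ρ = 0.6, and
one SNP with antagonistic per-copy effects ±0.1 SD:

```python
import numpy as np
from pleiometa import (simulate_study, CohortSpec, PhenotypeSpec, EffectConfig,
                       make_phenotype_correlation, estimate_sigma_P,
                       estimate_sigma_B, run_all, classify_result)
from pleiometa.stage1 import fit_dataset
from pleiometa.pipeline import group_stage1_by_cohort
from pleiometa.types import DomainSpec

phenos = [PhenotypeSpec("P1", "quantitative", "marker"),
          PhenotypeSpec("P2", "quantitative", "marker")]
corr = make_phenotype_correlation(2, 0.6, method="constant")
cohorts = [CohortSpec(f"C{j+1}", 2000, ("P1", "P2")) for j in range(5)]
snp = EffectConfig("rs_demo", maf=0.3, betas={"P1": 0.1, "P2": -0.1},
                   pattern="antagonistic")
study = simulate_study(cohorts, phenos, corr, [snp], seed=42,
                       icc=1.0, missing_rate=0.0)

stats = [s for ds in study for s in fit_dataset(ds)]
grouped = group_stage1_by_cohort(stats)
sigma_P = {ds.cohort: estimate_sigma_P(study, ds.cohort) for ds in study}
sigma_P["meta"] = estimate_sigma_P(study, "meta")
sigma_B = {scope: estimate_sigma_B("rs_demo", study, scope, R=250, seed=7)
           for scope in [ds.cohort for ds in study] + ["meta"]}

res = run_all("rs_demo", grouped["rs_demo"], [DomainSpec("pair", ("P1", "P2"))],
              sigma_P["meta"], sigma_B["meta"], sigma_P, sigma_B)[0]
for test, p in res.tests().items():
    print(f"{test:5s} p = {p:.3g}")
cls = classify_result(res)
print("group:", cls.group, "| best test:", res.best_test,
      "| pathway:", res.best_pathway, "| replicated cohorts:",
      cls.replicated_cohort_count)
```

prints

```
MOp   p = 8.12e-43
MOb   p = 1.59e-43
MFp   p = 3.08e-18
FcFp  p = 3.92e-15
OpFc  p = 3.57e-38
ObFc  p = 6.3e-40
FpFc  p = 4.43e-15
group: HP/HB | best test: MOb | pathway: 1 | replicated cohorts: 5
```

The omnibus tests land ~25 orders of magnitude below the Fisher tests —
the antagonistic-heterogeneity signature — so the SNP is assigned HP/HB,
and the per-cohort pattern replicates in all five cohorts.  The same
pipeline is available from the shell (`pleiometa simulate / stage1 /
meta / pleio / classify / report`), and

```bash
pleiometa reproduce-table2
```

re-derives the heterogeneity group of each of the 115 SNPs in the
shipped worked-example fixture and prints the group totals
(81 HP, 5 HB, 22 HP/HB, 7 M; 115/115 agreement).

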