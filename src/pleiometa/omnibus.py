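"""Omnibus chi-square test for cross-phenotype association.

For one SNP in one cohort (or at meta scope), let z be the vector of Wald
z-scores over the K phenotypes analysed there.  Under the global null,

    z' Sigma^{-1} z  ~  chi-square with K degrees of freedom,

where Sigma is the correlation matrix of the z-scores.  Two estimators of
Sigma are provided: Sigma_P, the pairwise Pearson correlation of
(visit-averaged) phenotype values, and Sigma_B, the correlation of z-score
vectors obtained by refitting the association models with permuted
dosages (default 250 permutations; the same permuted vector is reused
against all phenotypes of a cohort, preserving their cross-phenotype
dependence).  At meta scope the permutation z-scores are first combined
across cohorts by the fixed-effects meta-test.

When genetic effects on positively correlated phenotypes point in
opposite directions (antagonistic heterogeneity), the cross terms
-2 r z1 z2 of the quadratic form are positive, so the omnibus statistic
exceeds the sum of squares and the omnibus p-value undercuts the Fisher
combination — the signature exploited by the downstream classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

from .meta import fisher_combine
from .stage1 import bulk_linear_scan, fit_dataset
from .synthetic import IndividualDataset
from .types import AssocStat

log = logging.getLogger(__name__)

MAX_CONDITION = 1e8
DEFAULT_PERMUTATIONS = 250


@dataclass(frozen=True)
class CorrelationMatrix:
    """K x K z-score correlation with provenance metadata."""

    values: np.ndarray
    phenotypes: tuple[str, ...]
    kind: str  # "P" | "B"
    scope: str  # cohort name or "meta"
    n_permutations: int | None = None
    repaired: bool = False
    shrinkage: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.phenotypes),) * 2:
            raise ValueError("matrix shape disagrees with phenotype list")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise ValueError("correlation matrix must have unit diagonal")

    @property
    def K(self) -> int:
        return len(self.phenotypes)

    def subset(self, phenotypes: Sequence[str]) -> "CorrelationMatrix":
        keep = [p for p in phenotypes if p in self.phenotypes]
        idx = [self.phenotypes.index(p) for p in keep]
        return replace(self, values=self.values[np.ix_(idx, idx)],
                       phenotypes=tuple(keep))


@dataclass(frozen=True)
class OmnibusResult:
    statistic: float
    df: int
    p: float
    repaired: bool = False


def repair_correlation(
    sigma: np.ndarray, max_condition: float = MAX_CONDITION
) -> tuple[np.ndarray, float]:
    """Shrink Sigma toward the identity, Sigma <- (1-l)Sigma + l I, with
    the smallest l in {0, 0.01, 0.02, ...} giving a positive-definite
    matrix with condition number below ``max_condition``."""
    sigma = np.asarray(sigma, dtype=float)
    for lam in np.arange(0.0, 1.0, 0.01):
        cand = (1 - lam) * sigma + lam * np.eye(sigma.shape[0])
        ev = np.linalg.eigvalsh(cand)
        if ev.min() > 0 and ev.max() / ev.min() < max_condition:
            return cand, float(lam)
    raise np.linalg.LinAlgError("correlation matrix could not be repaired")


def estimate_sigma_P(
    datasets: Sequence[IndividualDataset],
    scope: str = "meta",
    phenotypes: Sequence[str] | None = None,
    adjust_covariates: bool = True,
) -> CorrelationMatrix:
    """Pairwise Pearson correlation of per-subject phenotype summaries.

    Quantitative markers enter as visit-averaged (transformed) values and
    outcomes as 0/1 event indicators; cohort-specific phenotype gaps are
    handled pairwise-complete.  ``scope`` is a cohort name or ``"meta"``
    (all cohorts' subjects pooled).

    Because the z-scores this matrix calibrates come from age/sex-adjusted
    models, the summaries are by default residualized on each cohort's
    covariates (with a per-cohort intercept) before correlating; this is
    the correlation the null z-scores actually have, and it also prevents
    between-cohort mean differences from inflating the pooled estimate.
    """
    use = [d for d in datasets if scope == "meta" or d.cohort == scope]
    if not use:
        raise ValueError(f"no dataset matches scope {scope!r}")
    if phenotypes is None:
        seen: list[str] = []
        for d in use:
            seen += [p for p in d.phenotypes if p not in seen]
        phenotypes = seen
    frames = []
    for d in use:
        cols = {p: d.subject_values(p) for p in phenotypes if p in d.phenotypes}
        frame = pd.DataFrame(cols, index=d.subject_ids)
        if adjust_covariates and len(frame):
            C = np.column_stack([np.ones(d.n_subjects), d.covariates.to_numpy()])
            vals = frame.to_numpy(copy=True)
            for j in range(vals.shape[1]):
                ok = np.isfinite(vals[:, j])
                if ok.sum() > C.shape[1]:
                    q, _ = np.linalg.qr(C[ok])
                    vals[ok, j] -= q @ (q.T @ vals[ok, j])
            frame = pd.DataFrame(vals, index=frame.index, columns=frame.columns)
        frames.append(frame)
    pooled = pd.concat(frames, axis=0).reindex(columns=list(phenotypes))
    corr = pooled.corr(method="pearson", min_periods=2).to_numpy()
    for k, p in enumerate(phenotypes):
        col = pooled[p]
        if col.notna().sum() == 0 or float(col.std()) == 0 or np.isnan(corr[k, k]):
            log.warning("phenotype %s constant/absent in scope %s; identity row used", p, scope)
            corr[k, :] = corr[:, k] = 0.0
            corr[k, k] = 1.0
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    corr = (corr + corr.T) / 2.0
    repaired_vals, lam = repair_correlation(corr)
    return CorrelationMatrix(
        values=repaired_vals, phenotypes=tuple(phenotypes), kind="P",
        scope=scope, repaired=lam > 0, shrinkage=lam,
    )


def _permutation_z_linear(
    ds: IndividualDataset,
    snp_id: str,
    phenotypes: Sequence[str],
    perm_idx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(beta, se) of each permuted dosage against each phenotype using the
    vectorized linear score fit on per-subject summaries."""
    g = ds.dosages[snp_id]
    G = g[perm_idx.T]  # (n, R)
    Y = np.column_stack([ds.subject_values(p) for p in phenotypes])
    ok = np.all(np.isfinite(Y), axis=1)
    return bulk_linear_scan(G[ok], Y[ok], ds.covariates.to_numpy()[ok])


def _permutation_z_refit(
    ds: IndividualDataset,
    snp_id: str,
    phenotypes: Sequence[str],
    perm_idx: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """(beta, se) via full stage-1 model refits for every permutation."""
    from .stage1 import FitError

    R = perm_idx.shape[0]
    beta = np.full((R, len(phenotypes)), np.nan)
    se = np.full((R, len(phenotypes)), np.nan)
    g = ds.dosages[snp_id]
    for r in range(R):
        ds.dosages["_perm"] = g[perm_idx[r]]
        ds.effect_alleles["_perm"] = ds.effect_alleles.get(snp_id, ("A", "G"))
        try:
            stats = fit_dataset(ds, snp_ids=["_perm"], phenotypes=phenotypes,
                                on_error="raise")
            for s in stats:
                k = list(phenotypes).index(s.phenotype)
                beta[r, k] = s.beta
                se[r, k] = s.se
        except FitError:
            pass  # row stays NaN and is dropped
        finally:
            ds.dosages.pop("_perm", None)
            ds.effect_alleles.pop("_perm", None)
    return beta, se


def estimate_sigma_B(
    snp_ids: str | Sequence[str],
    datasets: Sequence[IndividualDataset],
    scope: str = "meta",
    R: int = DEFAULT_PERMUTATIONS,
    seed: int | np.random.Generator = 0,
    phenotypes: Sequence[str] | None = None,
    method: str = "linear",
) -> CorrelationMatrix:
    """Permutation estimate of the z-score correlation matrix Sigma_B.

    For each permutation the subject indices of one cohort are shuffled
    once and the same permuted dosage vector is fitted against all of that
    cohort's phenotypes.  At ``scope="meta"`` the per-cohort effect sizes
    of each permutation are combined by inverse-variance weighting before
    correlating.  ``method="linear"`` (default) uses the vectorized linear
    score fit on per-subject summaries — exact for single-visit
    quantitative traits and equivalent under the permutation null —
    while ``method="refit"`` re-runs the full stage-1 models.

    Several ``snp_ids`` may be supplied; their permutation z-vectors are
    pooled, which under the null (where the z-vector law does not depend
    on the SNP) reduces the Monte-Carlo error of the estimate.
    """
    if R < 50:
        raise ValueError("need at least 50 permutations")
    if isinstance(snp_ids, str):
        snp_ids = [snp_ids]
    use = [d for d in datasets if scope == "meta" or d.cohort == scope]
    if not use:
        raise ValueError(f"no dataset matches scope {scope!r}")
    for d in use:
        for snp in snp_ids:
            if snp not in d.dosages:
                raise ValueError(f"SNP {snp} absent from cohort {d.cohort}")
    if phenotypes is None:
        seen: list[str] = []
        for d in use:
            seen += [p for p in d.phenotypes if p not in seen]
        phenotypes = seen
    phenotypes = list(phenotypes)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fitter = _permutation_z_linear if method == "linear" else _permutation_z_refit

    z_rows = []
    for snp in snp_ids:
        per_cohort: list[tuple[np.ndarray, np.ndarray, list[int]]] = []
        for d in use:
            avail = [k for k, p in enumerate(phenotypes) if p in d.phenotypes]
            if not avail:
                continue
            perm_idx = np.array([rng.permutation(d.n_subjects) for _ in range(R)])
            beta, se = fitter(d, snp, [phenotypes[k] for k in avail], perm_idx)
            per_cohort.append((beta, se, avail))
        # combine across cohorts per permutation (fixed-effects weights)
        K = len(phenotypes)
        num = np.zeros((R, K))
        den = np.zeros((R, K))
        for beta, se, avail in per_cohort:
            w = 1.0 / se**2
            num[:, avail] += np.where(np.isfinite(beta), w * beta, 0.0)
            den[:, avail] += np.where(np.isfinite(w), w, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (num / den) * np.sqrt(den)  # beta_meta / se_meta
        z_rows.append(z)
    Z = np.vstack(z_rows)
    ok = np.all(np.isfinite(Z), axis=1)
    if np.mean(~ok) > 0.10:
        raise RuntimeError(
            f"{int(np.sum(~ok))} of {Z.shape[0]} permutations dropped (>10%)"
        )
    Z = Z[ok]
    corr = np.corrcoef(Z, rowvar=False)
    corr = np.atleast_2d(corr)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    repaired_vals, lam = repair_correlation((corr + corr.T) / 2.0)
    return CorrelationMatrix(
        values=repaired_vals, phenotypes=tuple(phenotypes), kind="B",
        scope=scope, n_permutations=int(Z.shape[0]),
        repaired=lam > 0, shrinkage=lam,
    )


def omnibus_test(
    z: np.ndarray | Mapping[str, float],
    sigma: CorrelationMatrix | np.ndarray,
) -> OmnibusResult:
    """Evaluate z' Sigma^{-1} z against chi-square with K df.

    ``z`` may be a plain vector (ordered as sigma.phenotypes) or a mapping
    phenotype -> z-score, in which case sigma is subset and aligned to the
    mapped phenotypes.  A singular Sigma is repaired by identity shrinkage
    and flagged in the result.
    """
    repaired = False
    if isinstance(sigma, CorrelationMatrix):
        if isinstance(z, Mapping):
            phenos = [p for p in sigma.phenotypes if p in z]
            if len(phenos) != len(z):
                missing = sorted(set(z) - set(sigma.phenotypes))
                raise ValueError(f"z-scores for phenotypes {missing} not in sigma")
            sigma = sigma.subset(phenos)
            zv = np.array([z[p] for p in phenos], dtype=float)
        else:
            zv = np.asarray(z, dtype=float)
        S = sigma.values
        repaired = sigma.repaired
    else:
        if isinstance(z, Mapping):
            raise TypeError("mapping z requires a CorrelationMatrix sigma")
        zv = np.asarray(z, dtype=float)
        S = np.asarray(sigma, dtype=float)
    if zv.ndim != 1 or S.shape != (zv.size, zv.size):
        raise ValueError("z and sigma dimensions disagree")
    if not np.all(np.isfinite(zv)):
        raise ValueError("z-scores must be finite")
    ev = np.linalg.eigvalsh(S)
    if ev.min() <= 0 or ev.max() / ev.min() > MAX_CONDITION:
        S, lam = repair_correlation(S)
        repaired = True
        log.warning("singular z-score correlation repaired (lambda=%.2f)", lam)
    stat = float(zv @ np.linalg.solve(S, zv))
    K = zv.size
    return OmnibusResult(
        statistic=stat, df=K,
        p=max(float(_st.chi2.sf(stat, K)), 1e-300), repaired=repaired,
    )


def two_phenotype_statistic(
    z1: float, z2: float, sigma: np.ndarray | CorrelationMatrix
) -> float:
    """Closed-form two-phenotype omnibus statistic

        (z1^2 S22 - z1 z2 S21 - z1 z2 S12 + z2^2 S11) / det(S),

    identical to the general quadratic form for K=2.  Antagonistic
    configurations (z1 z2 r < 0) make the cross terms positive, so the
    statistic exceeds z1^2 + z2^2; aligned ones (z1 z2 r > 0) may fall
    below it."""
    S = sigma.values if isinstance(sigma, CorrelationMatrix) else np.asarray(sigma, float)
    if S.shape != (2, 2):
        raise ValueError("sigma must be 2x2")
    r = S[0, 1]
    if abs(r) >= 1.0:
        raise ValueError("|r| must be < 1")
    det = S[0, 0] * S[1, 1] - S[0, 1] * S[1, 0]
    return float(
        (z1**2 * S[1, 1] - z1 * z2 * S[1, 0] - z1 * z2 * S[0, 1] + z2**2 * S[0, 0]) / det
    )


__all__ = [
    "CorrelationMatrix",
    "OmnibusResult",
    "estimate_sigma_P",
    "estimate_sigma_B",
    "omnibus_test",
    "two_phenotype_statistic",
    "repair_correlation",
    "DEFAULT_PERMUTATIONS",
]
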