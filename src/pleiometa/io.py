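"""Tab-delimited file formats of the pipeline.

Everything on disk is TSV for inspectability.  The stage-1
summary-statistics table is the pipeline's lingua franca; its column names
and order are fixed.  Correlation matrices carry a ``#``-prefixed
metadata header (kind, scope, permutations, repair).  P-values are
written in scientific notation with three significant digits or more.
"""

from __future__ import annotations

import importlib.resources as _res
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .omnibus import CorrelationMatrix
from .synthetic import IndividualDataset
from .types import AssocStat

log = logging.getLogger(__name__)

STAGE1_COLUMNS = [
    "snp_id", "phenotype", "cohort", "effect_allele", "other_allele",
    "eaf", "beta", "se", "z", "p", "n",
]

META_COLUMNS = [
    "snp_id", "phenotype", "beta_meta", "se_meta", "p_meta",
    "p_fisher_cohorts", "Q", "I2", "n_cohorts",
]


@dataclass
class RowError:
    row: int
    reason: str


def write_summary_stats(stats: Sequence[AssocStat], path: str | Path) -> None:
    df = pd.DataFrame(
        [{c: getattr(s, c) for c in STAGE1_COLUMNS} for s in stats],
        columns=STAGE1_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_summary_stats(
    path: str | Path,
) -> tuple[list[AssocStat], list[RowError]]:
    """Typed stage-1 records plus an error report of rejected rows.

    A missing mandatory column or an empty file is a hard failure; a
    malformed row (non-numeric field, se <= 0, p outside (0,1]) lands in
    the error report and the run continues.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    missing = [c for c in STAGE1_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    records: list[AssocStat] = []
    errors: list[RowError] = []
    for i, row in df.iterrows():
        try:
            records.append(AssocStat(
                snp_id=row["snp_id"], phenotype=row["phenotype"],
                cohort=row["cohort"], effect_allele=row["effect_allele"],
                other_allele=row["other_allele"], eaf=float(row["eaf"]),
                beta=float(row["beta"]), se=float(row["se"]),
                z=float(row["z"]), p=float(row["p"]), n=int(row["n"]),
            ))
        except (ValueError, TypeError) as exc:
            errors.append(RowError(row=int(i), reason=str(exc)))
    if errors:
        log.warning("%s: rejected %d malformed row(s)", path, len(errors))
    return records, errors


def write_meta_table(meta_rows: Sequence[dict], path: str | Path) -> None:
    pd.DataFrame(meta_rows, columns=META_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.6g")


def write_correlation_matrix(m: CorrelationMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# kind={m.kind}\n# scope={m.scope}\n")
        fh.write(f"# n_permutations={m.n_permutations}\n")
        fh.write(f"# repaired={m.repaired}\n# shrinkage={m.shrinkage}\n")
        df = pd.DataFrame(m.values, index=m.phenotypes, columns=m.phenotypes)
        df.to_csv(fh, sep="\t", float_format="%.10g")


def read_correlation_matrix(path: str | Path) -> CorrelationMatrix:
    meta: dict[str, str] = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for ln in lines:
        if ln.startswith("#"):
            k, _, v = ln[1:].strip().partition("=")
            meta[k.strip()] = v.strip()
        else:
            body.append(ln)
    from io import StringIO

    df = pd.read_csv(StringIO("".join(body)), sep="\t", index_col=0)
    nperm = meta.get("n_permutations", "None")
    return CorrelationMatrix(
        values=df.to_numpy(),
        phenotypes=tuple(df.columns),
        kind=meta.get("kind", "P"),
        scope=meta.get("scope", "meta"),
        n_permutations=None if nperm == "None" else int(nperm),
        repaired=meta.get("repaired", "False") == "True",
        shrinkage=float(meta.get("shrinkage", "0")),
    )


def write_dataset(ds: IndividualDataset, out_dir: str | Path) -> None:
    """One cohort as three long-format TSVs plus a YAML manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for pheno, vals in ds.measurements.items():
        ages = ds.visit_ages.get(pheno)
        subj, visit = np.nonzero(np.isfinite(vals))
        for s, v in zip(subj, visit):
            rows.append((ds.subject_ids[s], pheno, int(v), vals[s, v],
                         float(ages[s, v]) if ages is not None else ""))
    pd.DataFrame(rows, columns=["subject_id", "phenotype", "visit", "value",
                                "age_at_visit"]).to_csv(
        out / f"{ds.cohort}_phenotypes.tsv", sep="\t", index=False)
    orows = []
    for pheno, (event, age) in ds.outcomes.items():
        for i in range(ds.n_subjects):
            orows.append((ds.subject_ids[i], pheno, int(event[i]), float(age[i])))
    pd.DataFrame(orows, columns=["subject_id", "outcome", "event", "age"]).to_csv(
        out / f"{ds.cohort}_outcomes.tsv", sep="\t", index=False)
    drows = []
    for snp, g in ds.dosages.items():
        for i in range(ds.n_subjects):
            drows.append((ds.subject_ids[i], snp, float(g[i])))
    pd.DataFrame(drows, columns=["subject_id", "snp_id", "dosage"]).to_csv(
        out / f"{ds.cohort}_dosages.tsv", sep="\t", index=False)
    manifest = {
        "cohort": ds.cohort,
        "n_subjects": int(ds.n_subjects),
        "phenotypes": list(ds.phenotypes),
        "snps": list(ds.dosages),
    }
    with open(out / f"{ds.cohort}_manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)


TABLE2_COLUMNS = [
    "id", "gene", "snp_id", "chr", "position", "effect_allele", "eaf",
    "domain", "n_p", "pathway", "p_op", "p_ob", "p_mfp", "p_fisher",
    "group", "p_grasp", "n_g",
]
TABLE2_ROWS = 115


def load_table2_fixture(path: str | Path | None = None) -> pd.DataFrame:
    """The shipped 115-row worked-example fixture: per SNP the pathway,
    the battery p-values (p_op/p_ob are MOp/MOb in pathway 1 and
    OpFc/ObFc in pathway 2; p_mfp only exists for pathway 1; p_fisher is
    FcFp or FpFc) and the printed heterogeneity group."""
    if path is None:
        ref = _res.files("pleiometa").joinpath("data/table2_fixture.tsv")
        with _res.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    missing = [c for c in TABLE2_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fixture missing columns {missing}")
    if len(df) != TABLE2_ROWS:
        raise ValueError(f"fixture must have {TABLE2_ROWS} rows, found {len(df)}")
    return df


def write_prior_evidence(prior: dict[str, dict[str, float]], path: str | Path) -> None:
    rows = [(snp, pheno, p) for snp, d in prior.items() for pheno, p in d.items()]
    pd.DataFrame(rows, columns=["snp_id", "phenotype", "p"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g")


def read_prior_evidence(path: str | Path) -> dict[str, dict[str, float]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, float]] = {}
    for r in df.itertuples():
        out.setdefault(r.snp_id, {})[r.phenotype] = float(r.p)
    return out


def heatmap_table(
    p_by_snp_pheno: pd.DataFrame, trim: float = -np.log10(5e-8)
) -> pd.DataFrame:
    """-log10(p) per SNP x phenotype trimmed at the genome-wide level
    (7.3), the tabular counterpart of the association heat map."""
    return (-np.log10(p_by_snp_pheno)).clip(upper=round(trim, 1))


__all__ = [
    "STAGE1_COLUMNS",
    "read_summary_stats",
    "write_summary_stats",
    "write_meta_table",
    "read_correlation_matrix",
    "write_correlation_matrix",
    "write_dataset",
    "load_table2_fixture",
    "read_prior_evidence",
    "write_prior_evidence",
    "heatmap_table",
    "RowError",
]
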