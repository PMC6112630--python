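"""Readers and writers for the package's plain-text interchange formats.

Genotypes travel as PLINK-``.raw``-style TSV (FID, IID, then one column per
SNP named ``snpid_EFFECTALLELE``); phenotypes as CSV; summary statistics and
weight tables as TSV; simulation ground truth as a YAML sidecar.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import pandas as pd
import yaml

from .simulate import GenotypeMatrix

__all__ = [
    "write_plink_raw",
    "read_plink_raw",
    "write_phenotypes",
    "read_phenotypes",
    "write_summary_stats",
    "read_summary_stats",
    "write_weights",
    "read_weights",
    "write_ground_truth",
    "read_ground_truth",
]

SUMMARY_COLUMNS = ["snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n"]
WEIGHT_COLUMNS = ["snp_id", "effect_allele", "other_allele", "weight"]


def write_plink_raw(geno: GenotypeMatrix, path) -> None:
    meta = geno.snps.set_index("snp_id")
    dosages = geno.dosages.rename(
        columns={snp: f"{snp}_{meta.loc[snp, 'effect_allele']}" for snp in geno.dosages.columns}
    )
    ids = pd.DataFrame(
        {"FID": geno.dosages.index, "IID": geno.dosages.index}, index=geno.dosages.index
    )
    pd.concat([ids, dosages], axis=1).to_csv(path, sep="\t", index=False)


def read_plink_raw(path, other_alleles: dict[str, str] | None = None) -> GenotypeMatrix:
    """Parse a PLINK-.raw-style TSV back into a genotype matrix.

    The ``.raw`` format records only the counted (effect) allele; supply
    ``other_alleles`` (snp_id -> allele) to restore full metadata, else the
    other allele is recorded as 'N' (unknown).
    """
    df = pd.read_csv(path, sep="\t", dtype={"FID": str, "IID": str})
    snp_cols = [c for c in df.columns if c not in ("FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE")]
    ids, eas = zip(*(c.rsplit("_", 1) for c in snp_cols))
    dosages = df[list(snp_cols)].astype(float)
    dosages.columns = list(ids)
    dosages.index = pd.Index(df["IID"], name="iid")
    other = other_alleles or {}
    meta = pd.DataFrame(
        {
            "snp_id": list(ids),
            "effect_allele": list(eas),
            "other_allele": [other.get(s, "N") for s in ids],
            "eaf": dosages.mean(axis=0).to_numpy() / 2.0,
        }
    )
    return GenotypeMatrix(dosages, meta)


def write_phenotypes(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index_label="iid")


def read_phenotypes(path, time_order: dict | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="iid")
    if time_order is not None:
        df.attrs["time_order"] = dict(time_order)
    return df


def write_summary_stats(stats_df: pd.DataFrame, path) -> None:
    stats_df[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SUMMARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"summary-stat file missing columns: {sorted(missing)}")
    return df


def write_weights(weights: pd.DataFrame, path) -> None:
    weights[WEIGHT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_weights(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(WEIGHT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"weight file missing columns: {sorted(missing)}")
    return df


def write_ground_truth(params, path, extra: dict | None = None) -> None:
    payload = dataclasses.asdict(params) if dataclasses.is_dataclass(params) else dict(params)
    if extra:
        payload = {**payload, **extra}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_ground_truth(path) -> dict:
    return yaml.safe_load(Path(path).read_text())
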