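"""Cohort table schema, validation and I/O.

The pipeline's universal input is a subject-level table with one row per
participant: case/control status, baseline covariates, relative LTL (T/S
ratio), and one effect-allele dosage column (0/1/2) per SNP.  Genotype columns
may instead hold allele strings like ``"C/T"``; these are resolved to dosages
against the per-SNP allele definitions.  A minimal VCF reader (biallelic SNP
rows, GT field) is provided for joining external genotypes to a cohort CSV.
"""

from __future__ import annotations

import json
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "COVARIATE_COLUMNS",
    "CONTINUOUS_COVARIATES",
    "BINARY_COVARIATES",
    "CohortValidationError",
    "validate_cohort",
    "read_cohort_csv",
    "write_cohort_csv",
    "genotype_strings_to_dosage",
    "read_genotypes_vcf",
    "cohort_schema",
]

CONTINUOUS_COVARIATES = (
    "age", "height", "weight", "bmi", "sbp", "dbp", "hcy",
    "tg", "tc", "ldl_c", "hdl_c", "glu",
)
BINARY_COVARIATES = ("sex", "smoking", "drinking", "movement")
COVARIATE_COLUMNS = CONTINUOUS_COVARIATES + BINARY_COVARIATES

REQUIRED_COLUMNS = ("subject_id", "status", "ltl")


class CohortValidationError(ValueError):
    """Schema violation in a cohort table, with row/column context."""


def cohort_schema() -> dict:
    """The versioned JSON schema describing the cohort CSV."""
    with resources.files("telomir.schema").joinpath("cohort_schema_v1.json").open() as fh:
        return json.load(fh)


def genotype_strings_to_dosage(
    values: pd.Series, effect_allele: str, other_allele: str, column: str = ""
) -> pd.Series:
    """Convert allele-pair strings ("C/T") to effect-allele dosage.

    Missing values stay missing; anything not composed of the two declared
    alleles raises CohortValidationError naming the row and column.
    """
    out = np.full(len(values), np.nan)
    for i, (idx, v) in enumerate(zip(values.index, values)):
        if pd.isna(v):
            continue
        s = str(v).strip()
        if s.replace(".", "").isdigit() and s in {"0", "1", "2"}:
            out[i] = int(s)
            continue
        alleles = s.replace("|", "/").split("/")
        if len(alleles) != 2 or not set(alleles).issubset({effect_allele, other_allele}):
            raise CohortValidationError(
                f"row {idx}, column {column or values.name}: genotype {v!r} is not a "
                f"biallelic {effect_allele}/{other_allele} call"
            )
        out[i] = sum(a == effect_allele for a in alleles)
    return pd.Series(out, index=values.index, name=values.name)


def validate_cohort(cohort: pd.DataFrame, snp_ids: list[str]) -> list[str]:
    """Validate a cohort table; returns a list of warnings, raises on errors."""
    warnings: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise CohortValidationError(f"missing required columns: {missing}")
    bad_status = cohort.loc[~cohort["status"].isin([0, 1]), "status"]
    if len(bad_status):
        raise CohortValidationError(
            f"row {bad_status.index[0]}, column 'status': value {bad_status.iloc[0]!r} "
            "is not 0/1"
        )
    if cohort["subject_id"].duplicated().any():
        dup = cohort.loc[cohort["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise CohortValidationError(f"duplicate subject_id {dup!r}")
    neg_ltl = cohort.loc[cohort["ltl"].notna() & (cohort["ltl"] < 0)]
    if len(neg_ltl):
        raise CohortValidationError(
            f"row {neg_ltl.index[0]}, column 'ltl': negative T/S ratio"
        )
    for sid in snp_ids:
        if sid not in cohort.columns:
            raise CohortValidationError(f"missing genotype column {sid!r}")
        col = cohort[sid].dropna()
        bad = col[~col.isin([0, 1, 2])]
        if len(bad):
            raise CohortValidationError(
                f"row {bad.index[0]}, column {sid!r}: dosage {bad.iloc[0]!r} not in 0/1/2"
            )
        if col.nunique() == 1:
            warnings.append(f"{sid}: monomorphic in this cohort")
    for cov in COVARIATE_COLUMNS:
        if cov not in cohort.columns:
            warnings.append(f"covariate column {cov!r} absent")
    return warnings


def read_cohort_csv(
    path, snp_ids: list[str], snp_alleles: dict[str, tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Read and validate a cohort CSV; allele-string genotype columns are
    converted to dosage when ``snp_alleles`` maps snp_id -> (effect, other)."""
    df = pd.read_csv(path)
    if snp_alleles:
        for sid, (ea, oa) in snp_alleles.items():
            if sid in df.columns and df[sid].dtype == object:
                df[sid] = genotype_strings_to_dosage(df[sid], ea, oa, column=sid)
    validate_cohort(df, snp_ids)
    return df


def write_cohort_csv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, index=False)


def read_genotypes_vcf(path, snp_ids: list[str] | None = None) -> pd.DataFrame:
    """Read effect-allele dosages from a minimal VCF (biallelic SNPs, GT field).

    The ALT allele is taken as the effect allele.  Half-calls and ``./.`` are
    treated as missing.  Returns a sample x SNP dosage frame indexed by sample
    id, suitable for joining to a cohort table on subject_id.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    data: dict[str, np.ndarray] = {}
    for variant in vcf:
        vid = variant.ID
        if snp_ids is not None and vid not in snp_ids:
            continue
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            continue  # not a biallelic SNP row
        dos = np.full(len(samples), np.nan)
        for i, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue  # missing or half-call
            dos[i] = (a > 0) + (b > 0)
        data[vid] = dos
    return pd.DataFrame(data, index=pd.Index(samples, name="subject_id"))
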