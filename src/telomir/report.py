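"""Pipeline orchestration and study-style table output.

Builds the study's table set from a cohort table: baseline characteristics
(Table-1 style), allele-model association with HWE and MAF (Table-2 style),
genetic-model logistic fits (Table-3 style), stage-1 SNP-LTL fits (Table-4
style), two-stage MR with leave-one-out (Table-5 style), and the
PRS-confounder screen (Table-6 style), plus the pairwise LD summary.  Each
table carries both full-precision columns and publication-style display columns
(OR/CI to 2 dp, P in scientific notation below 0.001) and is written as TSV
plus full-precision JSON; a run
manifest records digests, row counts and collected warnings.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import association as assoc
from . import datasets, ld, mr
from .cohort import BINARY_COVARIATES, CONTINUOUS_COVARIATES, validate_cohort
from .simulate import SimulationConfig, generate_cohort, _config_dict

#: the study's 15-row confounder screen (BMI is represented by height/weight)
SCREEN_COVARIATES = (
    "age", "sex", "height", "weight", "sbp", "dbp", "hcy", "tg", "tc",
    "ldl_c", "hdl_c", "glu", "smoking", "drinking", "movement",
)

__all__ = [
    "baseline_table",
    "genotype_counts_from_cohort",
    "allele_model_table",
    "genetic_model_table",
    "stage1_table",
    "mr_table",
    "run_pipeline",
]


def fmt_p(p: float) -> str:
    if not np.isfinite(p):
        return "NA"
    return f"{p:.2e}" if p < 0.001 else f"{p:.3f}"


def fmt_or(or_: float, lo: float, hi: float) -> str:
    return f"{or_:.2f} ({lo:.2f}-{hi:.2f})"


def genotype_counts_from_cohort(
    cohort: pd.DataFrame, snp_id: str, effect_allele: str, other_allele: str,
    status_col: str = "status",
) -> assoc.GenotypeCountTable:
    """Aggregate a dosage column into per-group (BB, AB, AA) counts."""
    counts = {}
    for grp, val in (("case", 1), ("control", 0)):
        sub = cohort.loc[cohort[status_col] == val, snp_id].dropna().astype(int)
        counts[grp] = tuple(int((sub == d).sum()) for d in (0, 1, 2))
    return assoc.GenotypeCountTable(
        snp_id=snp_id, effect_allele=effect_allele, other_allele=other_allele,
        case=counts["case"], control=counts["control"],
    )


def baseline_table(cohort: pd.DataFrame, status_col: str = "status") -> pd.DataFrame:
    """Table-1-style group comparison of baseline covariates.

    Continuous covariates: mean +/- SD per group, Welch t-test P.  Binary
    covariates: n (%) per group, Pearson chi-square (Fisher's exact when any
    expected cell < 5).  All-missing or single-subject groups are flagged.
    """
    case = cohort[cohort[status_col] == 1]
    control = cohort[cohort[status_col] == 0]
    rows = []
    for cov in CONTINUOUS_COVARIATES:
        if cov not in cohort.columns:
            continue
        a, b = case[cov].dropna(), control[cov].dropna()
        if len(a) == 0 or len(b) == 0:
            rows.append((cov, "NA", "NA", float("nan"), "omitted: all missing"))
            continue
        if len(a) < 2 or len(b) < 2:
            rows.append((cov, f"{a.mean():.2f}", f"{b.mean():.2f}", float("nan"),
                         "t-test undefined: single-subject group"))
            continue
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append((cov, f"{a.mean():.2f} ± {a.std(ddof=1):.2f}",
                     f"{b.mean():.2f} ± {b.std(ddof=1):.2f}", float(p), "welch t"))
    for cov in BINARY_COVARIATES:
        if cov not in cohort.columns:
            continue
        a, b = case[cov].dropna(), control[cov].dropna()
        if len(a) == 0 or len(b) == 0:
            rows.append((cov, "NA", "NA", float("nan"), "omitted: all missing"))
            continue
        tab = np.array([[int(a.sum()), int(len(a) - a.sum())],
                        [int(b.sum()), int(len(b) - b.sum())]])
        if tab.sum() == 0 or (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
            p, test = 1.0, "degenerate"
        else:
            exp = stats.contingency.expected_freq(tab)
            if (exp < 5).any():
                p, test = float(stats.fisher_exact(tab)[1]), "fisher"
            else:
                p, test = float(stats.chi2_contingency(tab, correction=False)[1]), "chi2"
        rows.append((cov, f"{int(a.sum())} ({a.mean():.1%})",
                     f"{int(b.sum())} ({b.mean():.1%})", p, test))
    return pd.DataFrame(rows, columns=["variable", "case", "control", "p", "test"])


def allele_model_table(count_tables: list[assoc.GenotypeCountTable]) -> pd.DataFrame:
    """Table-2-style allele-model association: allele counts, MAF, control HWE,
    OR (Woolf CI), chi-square and P per SNP."""
    rows = []
    for g in count_tables:
        al = assoc.alleles_from_genotypes(g)
        or_, lo, hi = assoc.odds_ratio_2x2(al.case_a, al.case_b, al.control_a, al.control_b)
        chi2, p = assoc.pearson_chi2_2x2(al.case_a, al.case_b, al.control_a, al.control_b)
        hwe = assoc.hwe_test(g.control, snp_id=g.snp_id, group="control")
        rows.append({
            "snp_id": g.snp_id,
            "alleles": f"{g.effect_allele}/{g.other_allele}",
            "case_a": al.case_a, "case_b": al.case_b,
            "control_a": al.control_a, "control_b": al.control_b,
            "maf_case": al.maf("case"), "maf_control": al.maf("control"),
            "hwe_p_exact": hwe.p_exact, "hwe_p_chi2": hwe.p_chi2,
            "odds_ratio": or_, "ci_low": lo, "ci_high": hi,
            "chi2": chi2, "p": p,
            "or_95ci": fmt_or(or_, lo, hi), "p_display": fmt_p(p),
        })
    return pd.DataFrame(rows)


def genetic_model_table(
    cohort: pd.DataFrame, snp_ids: list[str], covariates: list[str] | None = None
) -> pd.DataFrame:
    """Table-3-style genetic-model fits: crude and adjusted ORs, model P, AIC/BIC."""
    adjust_sets = [[]] if not covariates else [[], list(covariates)]
    rows = []
    for sid in snp_ids:
        for model in assoc.GENETIC_MODELS:
            for adj in adjust_sets:
                fit = assoc.fit_genetic_model(cohort, sid, model, adj or None)
                for c in fit.contrasts:
                    rows.append({
                        "snp_id": sid, "model": model,
                        "adjusted": "+".join(adj) if adj else "crude",
                        "contrast": c.label,
                        "odds_ratio": c.odds_ratio, "ci_low": c.ci_low,
                        "ci_high": c.ci_high, "contrast_p": c.p,
                        "or_95ci": fmt_or(c.odds_ratio, c.ci_low, c.ci_high),
                        "model_p": fit.model_p, "model_p_display": fmt_p(fit.model_p),
                        "aic": fit.aic, "bic": fit.bic,
                        "n": fit.n, "warnings": "; ".join(fit.warnings),
                    })
    return pd.DataFrame(rows)


def stage1_table(
    cohort: pd.DataFrame,
    snp_alleles: dict[str, tuple[str, str]],
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Table-4-style per-SNP stage-1 fits of LTL on dosage."""
    rows = []
    for sid, (ea, oa) in snp_alleles.items():
        r = mr.stage1_fit(cohort, sid, covariates, effect_allele=ea, other_allele=oa)
        rows.append({"snp_id": sid, "effect_allele": ea, "other_allele": oa,
                     "beta": r.beta, "se": r.se, "p": r.p, "n": r.n, "f": r.f_stat})
    return pd.DataFrame(rows)


def mr_table(
    cohort: pd.DataFrame,
    instruments: mr.InstrumentSet,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Table-5-style MR summary: one row per single-SNP instrument, the
    all-SNP (PRS) row, and leave-one-out companions."""
    rows = []
    for r in instruments.instruments:
        est = mr.two_stage_estimate(cohort, r.snp_id, covariates)
        rows.append({"instrument": r.snp_id, "kind": "single-SNP 2SLS",
                     "beta": est.beta, "se": est.se, "or": est.odds_ratio,
                     "ci_low": est.ci_low, "ci_high": est.ci_high, "p": est.p,
                     "or_95ci": fmt_or(est.odds_ratio, est.ci_low, est.ci_high),
                     "p_display": fmt_p(est.p), "stage1_f": est.stage1_f})
    for est in mr.leave_one_out(cohort, instruments, covariates):
        kind = "all-SNP PRS 2SLS" if est.label == "All SNPs" else "leave-one-out"
        rows.append({"instrument": est.label, "kind": kind,
                     "beta": est.beta, "se": est.se, "or": est.odds_ratio,
                     "ci_low": est.ci_low, "ci_high": est.ci_high, "p": est.p,
                     "or_95ci": fmt_or(est.odds_ratio, est.ci_low, est.ci_high),
                     "p_display": fmt_p(est.p), "stage1_f": est.stage1_f})
    return pd.DataFrame(rows)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, out: Path, name: str, manifest: dict) -> None:
    tsv = out / f"{name}.tsv"
    df.to_csv(tsv, sep="\t", index=False, float_format="%.6g")
    (out / f"{name}.json").write_text(df.to_json(orient="records", indent=1))
    manifest["outputs"][tsv.name] = {"sha256": _digest(tsv), "rows": len(df)}
    manifest["outputs"][f"{name}.json"] = {"sha256": _digest(out / f"{name}.json"),
                                           "rows": len(df)}


def run_pipeline(
    out_dir,
    config: SimulationConfig | None = None,
    cohort: pd.DataFrame | None = None,
    adjust: list[str] | None = None,
    snp_alleles: dict[str, tuple[str, str]] | None = None,
    p_threshold: float = 0.05,
) -> dict:
    """Run simulate (optional) -> ltl summary -> association -> LD -> MR -> report.

    Provide either a SimulationConfig (a cohort is generated) or a validated
    cohort table.  Writes table1..table6.tsv/.json, ld.tsv and manifest.json
    into ``out_dir``; returns the manifest.
    """
    if (config is None) == (cohort is None):
        raise ValueError("provide exactly one of config or cohort")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    adjust = list(adjust) if adjust is not None else list(mr.ADJUST_PRESET)
    alleles = snp_alleles or dict(datasets.SNP_ALLELES)

    manifest: dict = {"outputs": {}, "warnings": [], "stages": {}}
    if config is not None:
        cohort, meta = generate_cohort(config)
        manifest["simulation"] = {k: v for k, v in meta.items() if k != "config"}
        manifest["config_sha256"] = hashlib.sha256(
            json.dumps(_config_dict(config), sort_keys=True, default=str).encode()
        ).hexdigest()
        manifest["seed"] = config.seed
        cohort_csv = out / "cohort.csv"
        cohort.to_csv(cohort_csv, index=False)
        manifest["outputs"]["cohort.csv"] = {"sha256": _digest(cohort_csv), "rows": len(cohort)}

    snp_ids = [s for s in alleles if s in cohort.columns]
    manifest["warnings"] += validate_cohort(cohort, snp_ids)
    manifest["stages"]["cohort"] = {"n": len(cohort),
                                    "n_cases": int((cohort["status"] == 1).sum()),
                                    "n_controls": int((cohort["status"] == 0).sum())}

    _write(baseline_table(cohort), out, "table1_baseline", manifest)

    counts = [genotype_counts_from_cohort(cohort, sid, *alleles[sid]) for sid in snp_ids]
    t2 = allele_model_table(counts)
    _write(t2, out, "table2_allele_model", manifest)
    for _, row in t2.iterrows():
        if row["hwe_p_exact"] < 0.05:
            manifest["warnings"].append(f"{row['snp_id']}: control HWE exact P < 0.05")

    _write(genetic_model_table(cohort, snp_ids, adjust), out, "table3_genetic_models", manifest)
    _write(ld.ld_all_pairs(cohort, snp_ids, group="control"), out, "ld", manifest)
    _write(stage1_table(cohort, {s: alleles[s] for s in snp_ids}), out,
           "table4_stage1", manifest)

    stage1 = [mr.stage1_fit(cohort, sid, None, *alleles[sid]) for sid in snp_ids]
    try:
        inst = mr.select_instruments(stage1, cohort, p_threshold=p_threshold,
                                     confounders=adjust)
        t5 = mr_table(cohort, inst, covariates=None)
        _write(t5, out, "table5_mr", manifest)
        for _, row in t5.iterrows():
            if row["stage1_f"] < mr.WEAK_F_FLOOR:
                manifest["warnings"].append(
                    f"{row['instrument']}: weak instrument (stage-1 F < {mr.WEAK_F_FLOOR})")
        prs = mr.build_prs(cohort, inst.weights)
        screen_covs = [c for c in SCREEN_COVARIATES if c in cohort.columns]
        _write(mr.confounder_screen(cohort, prs, screen_covs), out,
               "table6_prs_screen", manifest)
    except mr.NoValidInstrumentsError as exc:
        manifest["warnings"].append(f"MR stage skipped: {exc}")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
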