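"""Simulation-based validation protocols for the analysis chain.

Each function runs a self-contained numerical experiment — exact recomputation
of the published count statistics, EM-vs-grid likelihood comparison, stage-1
and causal-effect parameter recovery, and null-calibration of the two-stage
estimator — and returns plain numbers.  The test suite and the reproduction
script both call these, so the checks run identically in either context.
"""

from __future__ import annotations

import numpy as np

from . import datasets
from .association import alleles_from_genotypes, odds_ratio_2x2, pearson_chi2_2x2
from .ld import em_haplotype_freqs, genotype_table_loglik
from .mr import stage1_fit, two_stage_estimate
from .simulate import (
    LtlModel,
    OutcomeModel,
    SnpSpec,
    simulate_genotypes,
    simulate_ltl,
    simulate_outcome,
    substream,
)

__all__ = [
    "published_or_chi2",
    "crude_model_or",
    "em_grid_check",
    "stage1_recovery",
    "two_stage_recovery",
    "two_stage_null_calibration",
]

#: the three instrument SNPs' stage-1 betas and control MAFs
RECOVERY_BETAS = {"rs2853676": -0.179292, "rs2242652": -0.16781, "rs2075786": -0.315562}
RECOVERY_MAFS = {"rs2853676": 0.17, "rs2242652": 0.16, "rs2075786": 0.34}


def published_or_chi2(snp_id: str) -> dict:
    """Allele-model OR, CI, chi-square, P and MAFs from the bundled counts."""
    g = datasets.genotype_count_table(snp_id)
    al = alleles_from_genotypes(g)
    or_, lo, hi = odds_ratio_2x2(al.case_a, al.case_b, al.control_a, al.control_b)
    chi2, p = pearson_chi2_2x2(al.case_a, al.case_b, al.control_a, al.control_b)
    return {
        "odds_ratio": or_, "ci_low": lo, "ci_high": hi, "chi2": chi2, "p": p,
        "maf_case": al.maf("case"), "maf_control": al.maf("control"),
        "allele_counts": (al.case_a, al.case_b, al.control_a, al.control_b),
    }


def crude_model_or(snp_id: str, model: str, contrast: str = "het") -> float:
    """Unadjusted genetic-model OR straight from the bundled genotype counts.

    For the codominant model ``contrast`` picks the heterozygote ("het") or
    minor-homozygote ("hom") column against the major-homozygote reference;
    collapsed models (dominant/recessive/overdominant) ignore it.
    """
    cbb, cab, caa = datasets.GENOTYPE_COUNTS[snp_id]["case"]
    kbb, kab, kaa = datasets.GENOTYPE_COUNTS[snp_id]["control"]
    if model == "codominant":
        a, c = (cab, kab) if contrast == "het" else (caa, kaa)
        cells = (a, cbb, c, kbb)
    elif model == "dominant":
        cells = (cab + caa, cbb, kab + kaa, kbb)
    elif model == "recessive":
        cells = (caa, cbb + cab, kaa, kbb + kab)
    elif model == "overdominant":
        cells = (cab, cbb + caa, kab, kbb + kaa)
    else:
        raise ValueError(f"no closed-form crude OR for model {model!r}")
    return odds_ratio_2x2(*cells)[0]


def _hap_grid(step: float = 0.01) -> np.ndarray:
    """All haplotype-frequency vectors on a simplex grid with the given step."""
    k = int(round(1 / step))
    pts = []
    for i in range(k + 1):
        for j in range(k + 1 - i):
            for l in range(k + 1 - i - j):
                pts.append((i, j, l, k - i - j - l))
    return np.asarray(pts, dtype=float) / k


def _grid_max_loglik(table: np.ndarray, grid: np.ndarray) -> float:
    f = grid
    fab, fAb, faB, fo = f[:, 0], f[:, 1], f[:, 2], f[:, 3]
    p = np.stack(
        [
            fo**2, 2 * faB * fo, faB**2,
            2 * fAb * fo, 2 * fab * fo + 2 * fAb * faB, 2 * fab * faB,
            fAb**2, 2 * fab * fAb, fab**2,
        ],
        axis=1,
    )  # order matches table.ravel() with rows = copies of A ascending
    counts = table.ravel()[None, :].astype(float)
    ll = (counts * np.log(np.maximum(p, 1e-300))).sum(axis=1)
    return float(ll.max())


def em_grid_check(n_tables: int = 100, n: int = 200, seed: int = 0, step: float = 0.01) -> dict:
    """EM vs brute-force grid search on random two-locus genotype tables.

    Random haplotype frequencies (Dirichlet) generate 3x3 dosage tables of n
    subjects; for each, the EM log-likelihood is compared with the maximum over
    a step-spaced haplotype-frequency grid, and the margin-conservation error
    of the EM solution is measured.  Returns the worst deficits.
    """
    rng = np.random.default_rng(seed)
    grid = _hap_grid(step)
    worst_deficit = -np.inf
    worst_margin = 0.0
    for _ in range(n_tables):
        f = rng.dirichlet([1.0, 1.0, 1.0, 1.0])
        # genotype-cell probabilities, rows = copies of A
        p = np.array(
            [
                [f[3] ** 2, 2 * f[2] * f[3], f[2] ** 2],
                [2 * f[1] * f[3], 2 * f[0] * f[3] + 2 * f[1] * f[2], 2 * f[0] * f[2]],
                [f[1] ** 2, 2 * f[0] * f[1], f[0] ** 2],
            ]
        )
        table = rng.multinomial(n, p.ravel()).reshape(3, 3)
        fhat, ll, _ = em_haplotype_freqs(table)
        deficit = _grid_max_loglik(table, grid) - ll
        worst_deficit = max(worst_deficit, deficit)
        t = table.astype(float)
        ntot = t.sum()
        pa_obs = (2 * t[2, :].sum() + t[1, :].sum()) / (2 * ntot)
        pb_obs = (2 * t[:, 2].sum() + t[:, 1].sum()) / (2 * ntot)
        worst_margin = max(
            worst_margin,
            abs((fhat[0] + fhat[1]) - pa_obs),
            abs((fhat[0] + fhat[2]) - pb_obs),
        )
    return {"max_loglik_deficit": worst_deficit, "max_margin_error": worst_margin}


def _recovery_cohort(seed: int, n: int, betas: dict, mafs: dict,
                     causal: float, outcome_intercept: float,
                     residual_sd: float = 0.55):
    """Population-sampled cohort for recovery experiments (no ascertainment)."""
    import pandas as pd

    ages = substream(seed, "age").normal(57.5, 6.5, size=n)
    dosages = {
        sid: simulate_genotypes(SnpSpec(sid, "A", "G", maf), n, substream(seed, f"snp:{sid}"))
        for sid, maf in mafs.items()
    }
    ltl_model = LtlModel(intercept=2.95, snp_betas=betas, age_beta=-0.02,
                         residual_sd=residual_sd)
    ltl, _ = simulate_ltl(dosages, ages, ltl_model, substream(seed, "ltl"))
    out_model = OutcomeModel(intercept=outcome_intercept, ltl_beta=causal)
    status = simulate_outcome(ltl, {}, out_model, substream(seed, "outcome"))
    return pd.DataFrame({"age": ages, **dosages, "ltl": ltl, "status": status})


def stage1_recovery(n_seeds: int = 100, n: int = 627, seed: int = 0) -> float:
    """Fraction of seeds where every re-estimated stage-1 beta lies within
    4 SE of its generating value (instrument SNPs, study sample size)."""
    ok = 0
    for s in range(n_seeds):
        cohort = _recovery_cohort(seed * 100_003 + s, n, RECOVERY_BETAS, RECOVERY_MAFS,
                                  causal=0.0, outcome_intercept=0.0)
        good = True
        for sid, beta in RECOVERY_BETAS.items():
            r = stage1_fit(cohort, sid)
            if abs(r.beta - beta) > 4 * r.se:
                good = False
                break
        ok += good
    return ok / n_seeds


def two_stage_recovery(
    n_seeds: int = 50, n: int = 100_000, causal: float = -1.0, seed: int = 0,
    lo: float = -1.25, hi: float = -0.80,
) -> dict:
    """Causal-effect recovery of the two-stage estimator on population samples.

    Strong instruments (the three instrument SNPs' stage-1 betas at large n);
    the PRS built from refit single-SNP stage-1 betas is the instrument.
    Returns the fraction of seeds with point estimate inside [lo, hi] and the
    mean estimate.
    """
    inside = 0
    estimates = []
    for s in range(n_seeds):
        cohort = _recovery_cohort(seed * 100_003 + s, n, RECOVERY_BETAS, RECOVERY_MAFS,
                                  causal=causal, outcome_intercept=-causal * 1.45)
        weights = {sid: stage1_fit(cohort, sid).beta for sid in RECOVERY_BETAS}
        est = two_stage_estimate(cohort, weights)
        estimates.append(est.beta)
        inside += lo <= est.beta <= hi
    return {"fraction_in_band": inside / n_seeds,
            "mean_estimate": float(np.mean(estimates))}


def two_stage_null_calibration(
    n_seeds: int = 200, n: int = 100_000, alpha: float = 0.05, seed: int = 0
) -> float:
    """Type-I error of the two-stage estimator under a zero causal effect."""
    rejections = 0
    for s in range(n_seeds):
        cohort = _recovery_cohort(seed * 100_003 + s, n, RECOVERY_BETAS, RECOVERY_MAFS,
                                  causal=0.0, outcome_intercept=0.0)
        weights = {sid: stage1_fit(cohort, sid).beta for sid in RECOVERY_BETAS}
        est = two_stage_estimate(cohort, weights)
        rejections += est.p < alpha
    return rejections / n_seeds
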