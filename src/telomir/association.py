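"""Case-control association statistics for candidate biallelic SNPs.

Implements the classical single-SNP toolkit: allele-model 2x2 odds ratios with
Woolf (log-scale Wald) confidence intervals, Pearson chi-square without
continuity correction, Hardy-Weinberg tests (1-df chi-square and the exact
enumeration test), and logistic-regression genetic models (codominant,
dominant, recessive, overdominant, log-additive) with crude or
covariate-adjusted odds ratios, likelihood-ratio model P values and AIC/BIC.

Genotypes are coded as effect-allele dosage 0/1/2, with the effect allele
defined as the minor allele in the control group.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GenotypeCountTable",
    "AlleleCountTable",
    "HweResult",
    "ModelContrast",
    "ModelFitResult",
    "GENETIC_MODELS",
    "alleles_from_genotypes",
    "odds_ratio_2x2",
    "pearson_chi2_2x2",
    "hwe_chi2",
    "hwe_exact_p",
    "hwe_test",
    "fit_genetic_model",
    "bonferroni",
]

GENETIC_MODELS = ("codominant", "dominant", "recessive", "overdominant", "log-additive")


class UndefinedStatisticError(ValueError):
    """A statistic is not defined for the given table (zero margin etc.)."""


@dataclass(frozen=True)
class GenotypeCountTable:
    """Genotype counts (BB, AB, AA) per group; A = effect/minor allele."""

    snp_id: str
    effect_allele: str
    other_allele: str
    case: tuple[int, int, int]
    control: tuple[int, int, int]

    def __post_init__(self) -> None:
        for grp in (self.case, self.control):
            if len(grp) != 3 or any(int(c) != c or c < 0 for c in grp):
                raise ValueError(f"{self.snp_id}: genotype counts must be 3 non-negative integers")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele must differ")

    @property
    def n_cases(self) -> int:
        return sum(self.case)

    @property
    def n_controls(self) -> int:
        return sum(self.control)


@dataclass(frozen=True)
class AlleleCountTable:
    """Chromosome counts of the effect (A) and other (B) allele per group."""

    snp_id: str
    case_a: int
    case_b: int
    control_a: int
    control_b: int

    def maf(self, group: str) -> float:
        a, b = (self.case_a, self.case_b) if group == "case" else (self.control_a, self.control_b)
        return a / (a + b)


@dataclass(frozen=True)
class HweResult:
    snp_id: str
    group: str
    chi2: float
    p_chi2: float
    p_exact: float


@dataclass(frozen=True)
class ModelContrast:
    """One odds ratio within a genetic model (e.g. AB vs BB)."""

    label: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float


@dataclass
class ModelFitResult:
    snp_id: str
    model: str
    adjustment: tuple[str, ...]
    contrasts: list[ModelContrast]
    model_p: float
    aic: float
    bic: float
    n: int
    converged: bool = True
    warnings: list[str] = field(default_factory=list)


def alleles_from_genotypes(g: GenotypeCountTable) -> AlleleCountTable:
    """Collapse genotype counts to chromosome counts: A = 2*AA + AB, B = 2*BB + AB."""
    cbb, cab, caa = g.case
    kbb, kab, kaa = g.control
    return AlleleCountTable(
        snp_id=g.snp_id,
        case_a=2 * caa + cab,
        case_b=2 * cbb + cab,
        control_a=2 * kaa + kab,
        control_b=2 * kbb + kab,
    )


def odds_ratio_2x2(
    a: float, b: float, c: float, d: float, *, haldane: bool = False
) -> tuple[float, float, float]:
    """Odds ratio (a*d)/(b*c) with Woolf 95% CI.

    Parameters are the cells of the 2x2 table: ``a``/``b`` exposed/unexposed
    among cases, ``c``/``d`` among controls.  With ``haldane=True`` (or
    automatically when a single cell is zero but margins are positive) 0.5 is
    added to every cell (Haldane-Anscombe correction).

    Returns ``(odds_ratio, ci_low, ci_high)``.
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValueError("cell counts must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise UndefinedStatisticError("odds ratio undefined: empty row or column")
    if haldane or any(x == 0 for x in cells):
        a, b, c, d = (x + 0.5 for x in cells)
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = or_ * math.exp(-1.959963984540054 * se), or_ * math.exp(1.959963984540054 * se)
    return or_, lo, hi


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) and its P value."""
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise UndefinedStatisticError("chi-square undefined: zero margin")
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return chi2, float(stats.chi2.sf(chi2, df=1))


def hwe_chi2(n_bb: int, n_ab: int, n_aa: int) -> tuple[float, float]:
    """1-df chi-square Hardy-Weinberg test against expected (q^2 n, 2pq n, p^2 n)."""
    n = n_bb + n_ab + n_aa
    if n < 1:
        raise ValueError("empty genotype table")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        raise UndefinedStatisticError("HWE chi-square undefined for monomorphic locus")
    exp = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]) * n
    obs = np.array([n_bb, n_ab, n_aa], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1))


def hwe_exact_p(n_bb: int, n_ab: int, n_aa: int) -> float:
    """Exact Hardy-Weinberg P by full enumeration of heterozygote counts.

    Conditional on the observed allele counts, the probability of each possible
    heterozygote count is computed by recurrence and the two-sided P value is
    the summed probability of all tables no more probable than the observed one
    (no mid-P adjustment).  Monomorphic loci return 1.0.
    """
    n = n_bb + n_ab + n_aa
    n_a = 2 * n_aa + n_ab  # rare-allele copies (orientation does not matter)
    if n_a > n:  # work with the rarer allele
        n_a = 2 * n - n_a
    if n_a == 0:
        return 1.0
    # possible het counts share the parity of n_a
    het_min = n_a % 2
    hets = list(range(het_min, n_a + 1, 2))
    # unnormalised probabilities by recurrence from the smallest het count
    logp = {hets[0]: 0.0}
    for h in hets[:-1]:
        n_rare_hom = (n_a - h) // 2
        n_common_hom = n - h - n_rare_hom
        # P(h+2)/P(h) = 4 * n_rare_hom * n_common_hom / ((h+2)*(h+1))
        ratio = 4.0 * n_rare_hom * n_common_hom / ((h + 2.0) * (h + 1.0))
        logp[h + 2] = logp[h] + math.log(ratio)
    mx = max(logp.values())
    probs = {h: math.exp(v - mx) for h, v in logp.items()}
    total = sum(probs.values())
    obs = n_ab if n_ab in probs else min(probs, key=lambda h: abs(h - n_ab))
    p_obs = probs[obs]
    p = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p)


def hwe_test(
    counts: tuple[int, int, int], snp_id: str = "", group: str = ""
) -> HweResult:
    """Hardy-Weinberg test for one group's (BB, AB, AA) genotype counts.

    Reports both the 1-df chi-square and the exact enumeration P; the exact P
    is the recommended headline value.  Monomorphic loci yield a NaN chi-square
    and exact P = 1.
    """
    n_bb, n_ab, n_aa = counts
    try:
        chi2, p_chi2 = hwe_chi2(n_bb, n_ab, n_aa)
    except UndefinedStatisticError:
        chi2, p_chi2 = float("nan"), float("nan")
    return HweResult(snp_id=snp_id, group=group, chi2=chi2, p_chi2=p_chi2,
                     p_exact=hwe_exact_p(n_bb, n_ab, n_aa))


def _model_design(dosage: np.ndarray, model: str) -> tuple[np.ndarray, list[str]]:
    """Genotype encoding columns and contrast labels for one genetic model."""
    if model == "codominant":
        return np.column_stack([dosage == 1, dosage == 2]).astype(float), ["AB vs BB", "AA vs BB"]
    if model == "dominant":
        return (dosage >= 1).astype(float)[:, None], ["AB+AA vs BB"]
    if model == "recessive":
        return (dosage == 2).astype(float)[:, None], ["AA vs AB+BB"]
    if model == "overdominant":
        return (dosage == 1).astype(float)[:, None], ["AB vs BB+AA"]
    if model == "log-additive":
        return dosage.astype(float)[:, None], ["per A allele"]
    raise ValueError(f"unknown genetic model {model!r}; choose from {GENETIC_MODELS}")


def fit_genetic_model(
    cohort: pd.DataFrame,
    snp_id: str,
    model: str,
    covariates: list[str] | None = None,
    status_col: str = "status",
) -> ModelFitResult:
    """Logistic regression of case status on one SNP under a genetic model.

    ``cohort[snp_id]`` must hold effect-allele dosages 0/1/2.  Complete-case
    analysis over status, genotype and covariates.  Returns per-contrast Wald
    odds ratios with 95% CIs, the likelihood-ratio model P versus the
    genotype-free null, and AIC / BIC.  Quasi-separation or non-convergence is
    flagged in ``warnings`` rather than raised.
    """
    covariates = list(covariates or [])
    cols = [status_col, snp_id, *covariates]
    data = cohort[cols].dropna()
    y = data[status_col].to_numpy(dtype=float)
    dosage = data[snp_id].to_numpy()
    geno, labels = _model_design(dosage, model)
    covs = data[covariates].to_numpy(dtype=float) if covariates else np.empty((len(data), 0))
    x_full = sm.add_constant(np.column_stack([geno, covs]), has_constant="add")
    x_null = sm.add_constant(covs, has_constant="add")

    notes: list[str] = []
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, x_full).fit(disp=0, maxiter=200)
            fit_null = sm.Logit(y, x_null).fit(disp=0, maxiter=200)
            converged = bool(fit.mle_retvals.get("converged", True))
        except Exception as exc:  # separation / singular design
            raise UndefinedStatisticError(f"logistic fit failed for {snp_id}/{model}: {exc}") from exc
    if not converged:
        notes.append("logistic fit did not converge; estimates unreliable")
    if np.abs(fit.params).max() > 15:
        notes.append("possible quasi-separation (|log-OR| > 15)")

    k_geno = geno.shape[1]
    params = fit.params[1 : 1 + k_geno]
    ses = fit.bse[1 : 1 + k_geno]
    pvals = fit.pvalues[1 : 1 + k_geno]
    z = 1.959963984540054
    contrasts = [
        ModelContrast(
            label=lab,
            odds_ratio=float(np.exp(b)),
            ci_low=float(np.exp(b - z * s)),
            ci_high=float(np.exp(b + z * s)),
            p=float(p),
        )
        for lab, b, s, p in zip(labels, params, ses, pvals)
    ]
    lr = 2.0 * (fit.llf - fit_null.llf)
    model_p = float(stats.chi2.sf(max(lr, 0.0), df=k_geno))
    return ModelFitResult(
        snp_id=snp_id,
        model=model,
        adjustment=tuple(covariates),
        contrasts=contrasts,
        model_p=model_p,
        aic=float(fit.aic),
        bic=float(fit.bic),
        n=len(data),
        converged=converged,
        warnings=notes,
    )


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-adjusted P values: min(1, m * p)."""
    p = np.asarray(p_values, dtype=float)
    m = int(m) if m is not None else p.size
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, m * p)
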