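"""One-sample Mendelian randomization of a continuous exposure on a binary outcome.

The exposure here is relative leukocyte telomere length (LTL, T/S units) and
the outcome is case/control disease status.  The engine implements:

* stage-1 fits — OLS of LTL on effect-allele dosage (optionally
  covariate-adjusted), one SNP at a time;
* instrument selection — Bonferroni-adjusted stage-1 P threshold, with an
  audit-only genotype-vs-covariate confounder screen;
* allele-score (PRS) construction — weighted dosage sums using the signed
  stage-1 betas, so the score is the fitted genetic value of LTL;
* two-stage estimation — stage 1 OLS of exposure on the instrument, stage 2
  logistic regression of status on the stage-1 fitted exposure; the reported
  effect is the stage-2 coefficient (log-OR of disease per unit T/S);
* leave-one-out sensitivity — the composite score is rebuilt without each
  instrument in turn and the two-stage fit repeated;
* a PRS-confounder screen (per-covariate regression on the score).

Stage-2 standard errors are the conventional ML ones from the logistic fit;
they ignore first-stage estimation error and therefore understate uncertainty
when the causal effect is non-zero.  A nonparametric bootstrap SE is available
via ``n_bootstrap``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "Stage1Result",
    "InstrumentSet",
    "TwoStageResult",
    "NoValidInstrumentsError",
    "stage1_fit",
    "select_instruments",
    "build_prs",
    "two_stage_estimate",
    "leave_one_out",
    "confounder_screen",
]

#: conventional weak-instrument rule of thumb on the stage-1 F statistic
WEAK_F_FLOOR = 10.0

#: the study's stage-1 adjustment preset
ADJUST_PRESET = ("age", "sex", "bmi", "smoking", "drinking")


class NoValidInstrumentsError(ValueError):
    pass


@dataclass(frozen=True)
class Stage1Result:
    """OLS of exposure on one SNP's dosage: beta (T/S per allele), SE, P."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    p: float
    n: int
    f_stat: float


@dataclass
class InstrumentSet:
    """Selected instruments with their stage-1 fits and the selection audit."""

    instruments: list[Stage1Result]
    p_threshold: float
    bonferroni_m: int
    confounder_audit: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        ids = [r.snp_id for r in self.instruments]
        if not ids:
            raise NoValidInstrumentsError("instrument set may not be empty")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate instruments")

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.instruments]

    @property
    def weights(self) -> dict[str, float]:
        return {r.snp_id: r.beta for r in self.instruments}


@dataclass
class TwoStageResult:
    label: str
    beta: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    stage1_f: float
    stage1_beta: float
    warnings: list[str] = field(default_factory=list)
    bootstrap_se: float | None = None


def _ols(y: np.ndarray, x_cols: np.ndarray):
    x = sm.add_constant(x_cols, has_constant="add")
    return sm.OLS(y, x).fit()


def stage1_fit(
    cohort: pd.DataFrame,
    snp_id: str,
    covariates: list[str] | None = None,
    effect_allele: str = "",
    other_allele: str = "",
    exposure_col: str = "ltl",
) -> Stage1Result:
    """OLS of the exposure on effect-allele dosage, optionally adjusted."""
    covariates = list(covariates or [])
    data = cohort[[exposure_col, snp_id, *covariates]].dropna()
    g = data[snp_id].to_numpy(dtype=float)
    if np.all(g == g[0]):
        raise ValueError(f"{snp_id}: constant dosage, stage-1 fit undefined")
    covs = data[covariates].to_numpy(dtype=float) if covariates else np.empty((len(data), 0))
    fit = _ols(data[exposure_col].to_numpy(dtype=float), np.column_stack([g, covs]))
    beta, se, p = float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])
    f_stat = float((beta / se) ** 2) if se > 0 else float("inf")
    return Stage1Result(
        snp_id=snp_id,
        effect_allele=effect_allele,
        other_allele=other_allele,
        beta=beta,
        se=se,
        p=p,
        n=len(data),
        f_stat=f_stat,
    )


def _confounder_audit(cohort: pd.DataFrame, snp_ids, covariates) -> pd.DataFrame:
    """Genotype-vs-covariate screen: ANOVA across genotype groups for
    continuous covariates, chi-square (Fisher if sparse) for binary ones."""
    rows = []
    for sid in snp_ids:
        for cov in covariates:
            sub = cohort[[sid, cov]].dropna()
            groups = [v[cov].to_numpy(dtype=float) for _, v in sub.groupby(sid)]
            groups = [g for g in groups if len(g) > 1]
            vals = sub[cov].dropna().unique()
            if set(np.unique(vals)).issubset({0, 1}):
                tab = pd.crosstab(sub[sid], sub[cov]).to_numpy()
                if tab.size == 0 or tab.shape[1] < 2:
                    p = float("nan")
                else:
                    exp = stats.contingency.expected_freq(tab)
                    if tab.shape == (2, 2) and (exp < 5).any():
                        p = float(stats.fisher_exact(tab)[1])
                    else:
                        p = float(stats.chi2_contingency(tab, correction=False)[1])
                test = "chi2/fisher"
            elif len(groups) >= 2:
                p = float(stats.f_oneway(*groups)[1])
                test = "anova"
            else:
                p, test = float("nan"), "none"
            rows.append((sid, cov, test, p))
    return pd.DataFrame(rows, columns=["snp_id", "covariate", "test", "p"])


def select_instruments(
    stage1_results: list[Stage1Result],
    cohort: pd.DataFrame | None = None,
    p_threshold: float = 0.05,
    confounders: list[str] | None = None,
    bonferroni_m: int | None = None,
) -> InstrumentSet:
    """Keep SNPs whose Bonferroni-adjusted stage-1 P is below the threshold.

    The confounder screen (genotype vs each covariate) is attached as an audit
    record on the returned set; findings are reported, not auto-exclusionary.
    Raises NoValidInstrumentsError when nothing passes.
    """
    if not stage1_results:
        raise ValueError("no stage-1 results supplied")
    m = bonferroni_m if bonferroni_m is not None else len(stage1_results)
    kept = [r for r in stage1_results if min(1.0, m * r.p) < p_threshold]
    if not kept:
        raise NoValidInstrumentsError(
            f"no instruments with Bonferroni-adjusted P < {p_threshold} (m={m})"
        )
    audit = None
    if cohort is not None and confounders:
        audit = _confounder_audit(cohort, [r.snp_id for r in kept], confounders)
    return InstrumentSet(instruments=kept, p_threshold=p_threshold, bonferroni_m=m,
                         confounder_audit=audit)


def build_prs(cohort: pd.DataFrame, weights: dict[str, float]) -> pd.Series:
    """Allele score: PRS_i = sum_j w_j * dosage_ij (complete-case).

    Subjects missing any weighted genotype are dropped (the returned Series
    carries the dropped count in ``attrs['n_dropped']``).
    """
    cols = list(weights)
    sub = cohort[cols].dropna()
    w = np.array([weights[c] for c in cols], dtype=float)
    prs = pd.Series(sub.to_numpy(dtype=float) @ w, index=sub.index, name="prs")
    prs.attrs["n_dropped"] = len(cohort) - len(sub)
    return prs


def two_stage_estimate(
    cohort: pd.DataFrame,
    instrument,
    covariates: list[str] | None = None,
    label: str | None = None,
    status_col: str = "status",
    exposure_col: str = "ltl",
    weak_f_floor: float = WEAK_F_FLOOR,
    n_bootstrap: int = 0,
    bootstrap_seed: int = 0,
) -> TwoStageResult:
    """Two-stage causal estimate of the exposure's effect on disease.

    ``instrument`` is a dosage column name, a pandas Series aligned to the
    cohort (e.g. a PRS), or a dict of PRS weights.  Stage 1: OLS of the
    exposure on the instrument (+ covariates).  Stage 2: logistic regression of
    status on the stage-1 fitted exposure (+ covariates); the returned ``beta``
    is the stage-2 coefficient, i.e. the log-OR of disease per unit exposure.
    A stage-1 F below ``weak_f_floor`` attaches a weak-instrument warning.
    """
    covariates = list(covariates or [])
    if isinstance(instrument, str):
        inst = cohort[instrument].rename("instrument")
        label = label or instrument
    elif isinstance(instrument, dict):
        inst = build_prs(cohort, instrument).rename("instrument")
        label = label or "PRS"
    elif isinstance(instrument, pd.Series):
        inst = instrument.rename("instrument")
        label = label or str(instrument.name or "instrument")
    else:
        raise TypeError("instrument must be a column name, PRS weights dict, or Series")

    data = cohort[[status_col, exposure_col, *covariates]].join(inst, how="inner").dropna()
    z = data["instrument"].to_numpy(dtype=float)
    if np.all(z == z[0]):
        raise ValueError("instrument is constant")
    covs = data[covariates].to_numpy(dtype=float) if covariates else np.empty((len(data), 0))
    y = data[status_col].to_numpy(dtype=float)
    x = data[exposure_col].to_numpy(dtype=float)

    def fit_once(y_, x_, z_, covs_):
        s1 = _ols(x_, np.column_stack([z_, covs_]))
        fitted = s1.fittedvalues
        design = sm.add_constant(np.column_stack([fitted, covs_]), has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s2 = sm.Logit(y_, design).fit(disp=0, maxiter=200)
        return s1, s2

    s1, s2 = fit_once(y, x, z, covs)
    beta1, se1 = float(s1.params[1]), float(s1.bse[1])
    f_stat = float((beta1 / se1) ** 2) if se1 > 0 else float("inf")
    beta, se, p = float(s2.params[1]), float(s2.bse[1]), float(s2.pvalues[1])
    notes = []
    if f_stat < weak_f_floor:
        notes.append(f"weak instrument: stage-1 F = {f_stat:.2f} < {weak_f_floor}")
    if not s2.mle_retvals.get("converged", True):
        notes.append("stage-2 logistic fit did not converge")
    notes.append("stage-2 SE is the conventional ML SE and ignores first-stage "
                 "estimation error")

    boot_se = None
    if n_bootstrap > 0:
        rng = np.random.default_rng(bootstrap_seed)
        n = len(y)
        draws = []
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            try:
                _, s2b = fit_once(y[idx], x[idx], z[idx], covs[idx])
                draws.append(float(s2b.params[1]))
            except Exception:
                continue
        if len(draws) > 1:
            boot_se = float(np.std(draws, ddof=1))

    zcrit = 1.959963984540054
    return TwoStageResult(
        label=label,
        beta=beta,
        se=se,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - zcrit * se)),
        ci_high=float(np.exp(beta + zcrit * se)),
        p=p,
        n=len(data),
        stage1_f=f_stat,
        stage1_beta=beta1,
        warnings=notes,
        bootstrap_se=boot_se,
    )


def leave_one_out(
    cohort: pd.DataFrame,
    instruments: InstrumentSet,
    covariates: list[str] | None = None,
    **kw,
) -> list[TwoStageResult]:
    """Leave-one-out sensitivity: rebuild the allele score without each SNP.

    Stage-1 weights for the remaining SNPs are re-fit on the same data (one
    SNP at a time, matching how the full score's weights were obtained).  The
    first returned element is the full-set (all-instruments) estimate, followed
    by one estimate per omitted SNP, labelled ``"without <snp>"``.
    """
    if len(instruments.instruments) < 2:
        raise ValueError("leave-one-out undefined for fewer than 2 instruments")
    covariates = list(covariates or [])
    results = [two_stage_estimate(cohort, instruments.weights, covariates,
                                  label="All SNPs", **kw)]
    for omit in instruments.snp_ids:
        remaining = [r for r in instruments.instruments if r.snp_id != omit]
        weights = {
            r.snp_id: stage1_fit(cohort, r.snp_id, covariates or None).beta
            for r in remaining
        }
        results.append(
            two_stage_estimate(cohort, weights, covariates, label=f"without {omit}", **kw)
        )
    return results


def confounder_screen(
    cohort: pd.DataFrame, prs: pd.Series, covariates: list[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Regress each covariate on the allele score: OLS for continuous
    covariates, logistic for binary ones.  Returns one row per covariate with
    beta, SE, P and a flag for P < alpha."""
    rows = []
    for cov in covariates:
        sub = cohort[[cov]].join(prs.rename("prs"), how="inner").dropna()
        v = sub[cov].to_numpy(dtype=float)
        z = sub["prs"].to_numpy(dtype=float)
        binary = set(np.unique(v)).issubset({0.0, 1.0})
        design = sm.add_constant(z, has_constant="add")
        if binary:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(v, design).fit(disp=0, maxiter=200)
            kind = "logistic"
        else:
            fit = sm.OLS(v, design).fit()
            kind = "ols"
        rows.append((cov, kind, float(fit.params[1]), float(fit.bse[1]),
                     float(fit.pvalues[1]), bool(fit.pvalues[1] < alpha)))
    return pd.DataFrame(rows, columns=["covariate", "test", "beta", "se", "p", "flagged"])
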