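# Methods

This note documents the statistical models implemented in `telomir`, the
defaults of the synthetic-cohort generator, the numerical choices made where
the design was genuinely open, and what the simulation-based checks do and do
not establish about real data.

## Study design being modelled

A candidate-gene case-control study: five biallelic TERT SNPs genotyped in
CSVD cases and healthy controls, relative leukocyte telomere length (LTL)
measured by qPCR in everyone, and a one-sample Mendelian randomization (MR)
asking whether LTL causally affects CSVD risk. Genotypes are coded as
effect-allele dosage g ∈ {0, 1, 2}, with the effect allele defined as the
minor allele **in the control group** (ties at 0.5 broken alphabetically).

## Association statistics

* **Allele model.** Chromosome counts A = 2·AA + AB, B = 2·BB + AB per group;
  OR = (a·d)/(b·c) with the Woolf (log-scale Wald) 95% CI
  exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d)). Pearson χ² on the 2×2 allele table is
  computed **without** continuity correction — this choice reproduces the
  published statistics (6.508, 7.442, 3.614 …) exactly from the printed
  counts. When a single cell is zero (the rs2736122 A/A cells are 1 and 4),
  the Haldane–Anscombe +0.5 correction is applied to all four cells and the
  result flagged.
* **Hardy–Weinberg.** Both a 1-df χ² against expectations n·(q², 2pq, p²) and
  the exact test by full enumeration of heterozygote counts conditional on
  the allele counts (probability recurrence, two-sided "sum of tables no more
  probable than observed", no mid-P). The exact P is the headline value: the
  study's printed control-group HWE column (0.180, 0.840, 0.390, 0.260,
  0.490) agrees with the exact test to rounding, not with the χ².
* **Genetic models.** Logistic regression of status on a genotype encoding —
  codominant (two indicators), dominant, recessive, overdominant,
  log-additive (dosage) — optionally plus covariates, complete cases only.
  Per-contrast Wald ORs with 95% CIs; the model P is the likelihood-ratio
  test against the genotype-free null (2 df for codominant, else 1);
  AIC = −2ℓ + 2k and BIC = −2ℓ + k·ln n. Non-convergence or |log-OR| > 15
  (quasi-separation) is flagged on the result, never silently dropped.
* **Multiplicity.** Bonferroni: p_adj = min(1, m·p).

## Linkage disequilibrium

Pairwise LD from unphased genotypes uses the standard two-locus EM: all phase
is observed except in double heterozygotes, which are split between coupling
(AB/ab) and repulsion (Ab/aB) with posterior weight
f_AB·f_ab / (f_AB·f_ab + f_Ab·f_aB) at each E-step. The log-likelihood is
asserted non-decreasing at every iteration. Convergence: max frequency change
< 1e-8, cap 1000 iterations. Initialisation is the linkage-equilibrium point
(products of observed allele frequencies) plus one coupling-perturbed
restart; the better likelihood wins. The restart matters: an
all-double-heterozygote table makes the LE point a symmetric saddle with two
equal D′ = 1 maxima, and plain EM would not leave it. Margins of the EM
solution equal the observed allele frequencies by construction of the M-step.
From the four haplotype frequencies: D = f_AB − p_A p_B; D′ = |D|/D_max with
D_max = min(p_A q_B, q_A p_B) for D > 0 and min(p_A p_B, q_A q_B) for D < 0;
r² = D²/(p_A q_A p_B q_B). A "strong LD" flag (D′ ≥ 0.8 and r² ≥ 0.5) is a
reporting convenience only — it is not a haplotype-block definition, and no
block partitioning is implemented. LD defaults to the control group, the
usual LD reference set; the pooled sample is available by option.

## Telomere length

Relative LTL is the Livak relative quantification: ΔCt = Ct_tel − Ct_ref per
sample, ΔΔCt against a designated calibrator sample, T/S = 2^(−ΔΔCt). A
calibrator-sample convention (rather than a standard curve) is assumed.
Replicate Cts are averaged before ΔCt; a replicate SD above 0.5 cycles is
flagged for QC. No amplification-efficiency or plate-effect correction is
applied. Group comparisons default to Welch's t (Student's by option);
LTL–age association is the Pearson correlation with the usual t-transform P.

## Mendelian randomization

* **Stage 1 (G→X).** OLS of LTL on dosage, one SNP at a time, optionally
  adjusted (the study preset: age, sex, BMI, smoking, drinking). The per-SNP
  F statistic is (β/SE)²; F < 10 attaches a weak-instrument warning.
* **Instrument selection.** SNPs with Bonferroni-adjusted stage-1 P below the
  threshold (default 0.05, m = number of candidate SNPs). A genotype-versus-
  covariate screen (ANOVA for continuous, χ²/Fisher for binary covariates) is
  attached as an audit record; findings are reported, not auto-exclusionary,
  because exclusion on measured covariates is a judgement call the analyst
  should see, not an automatic rule.
* **Allele score.** PRS_i = Σ_j β_j g_ij with the signed single-SNP stage-1
  betas as weights — i.e. the score is a fitted genetic value of LTL, which
  makes the internal check "OLS slope of LTL on PRS ≈ 1" hold by
  construction.
* **Two-stage estimator.** Stage 1: OLS of LTL on the instrument (a dosage
  column or the PRS), plus covariates if requested. Stage 2: logistic
  regression of case status on the stage-1 fitted exposure (plus the same
  covariates). The causal estimate is the stage-2 coefficient: θ_x = log OR
  of CSVD per unit T/S. For a single SNP and no covariates this equals the
  Wald ratio (logistic reduced-form coefficient ÷ stage-1 coefficient)
  exactly, because replacing a regressor by an affine transform rescales the
  logistic coefficient by the inverse slope; the test suite asserts this
  against an independently coded ratio.
* **Standard errors.** The reported SE is the conventional ML SE from the
  stage-2 fit. It ignores first-stage estimation error and therefore
  understates uncertainty when the causal effect is non-zero (under the null
  it is asymptotically correct, which is why the type-I error calibration
  holds). A nonparametric bootstrap SE (default B = 500 when enabled) is
  available.
* **Leave-one-out.** For each selected SNP the allele score is rebuilt from
  the remaining instruments (weights refit on the same data) and the
  two-stage fit repeated; the all-instruments estimate is reported alongside,
  unchanged.
* **Ascertainment caveat.** Stage-1 fits run on all subjects (cases +
  controls) by default, matching the study layout; a controls-only stage 1
  can be requested by subsetting, since case-control ascertainment can bias
  G→X estimates.

Out of scope by design: two-sample/summary-statistic MR (IVW, MR-Egger,
weighted median), control-function estimators, and pleiotropy tests beyond
the confounder screen and leave-one-out.

## Synthetic cohorts

The generator reproduces the causal chain the analysis assumes:

1. genotypes: i.i.d. HWE dosages, P(g = 2) = maf², P(1) = 2·maf(1−maf);
2. age ~ Normal(57.5, 6.5) years in the source population;
3. LTL = intercept + Σ_j β_j g_j + β_age·age + ε, ε ~ Normal(0, σ);
   negative draws are truncated at 0 (T/S is non-negative) and the truncation
   count is reported in the metadata;
4. status ~ Bernoulli(logit⁻¹(α + θ·LTL + 0.08·age));
5. ascertainment: population chunks are simulated until the requested case
   and control counts accrue (capped attempts), so the outcome intercept is a
   prevalence parameter and is deliberately not recoverable from the sample;
6. non-causal baseline covariates (anthropometry, blood chemistry, lifestyle,
   sex) are drawn conditional on the realized group from group-specific
   Normal/Bernoulli distributions. This reproduces the observed case-control
   baseline differences without asserting a causal model the study does not
   state; it also means these covariates are, by construction, independent of
   genotype given group.

Defaults are the study conditions: 307 cases / 320 controls; the five TERT
SNPs; per-allele LTL effects (−0.179, −0.168, −0.316, +0.060, −0.104 T/S);
causal log-OR θ = −1.427 per unit T/S; residual SD 0.55 chosen so total LTL
SD ≈ 0.62; β_age = −0.02 T/S per year giving the negative LTL-age
correlation; the age coefficient 0.08 on the log-odds scale reproducing the
~4-year case-control age gap. Two calibrated constant sets deserve note:

* the LTL intercept (2.875) is set so the ascertained **control** group mean
  lands on the study's 1.492 T/S;
* source-population MAFs equal the study control MAFs **plus a measured
  ascertainment shift** (up to +0.017 for rs2075786): ascertainment removes
  LTL-shortening alleles from controls, so feeding the control MAFs in
  directly would make sampled control groups systematically too low.

RNG discipline: one root seed, independent named substreams per variable
(SeedSequence keyed on seed + CRC32 of the name), so adding a SNP or
covariate leaves all other draws untouched; identical configs give
byte-identical cohorts. An optional two-locus mode samples explicit haplotype
pairs at a user-chosen D′ for LD testing; by default SNPs are simulated
independently, consistent with the study's finding of no strong LD.

What the generator does **not** emulate: population stratification,
relatedness, genotyping error, qPCR plate effects, and any direct
(non-LTL-mediated) genotype effect on disease. Passing parameter-recovery
tests therefore demonstrates the estimators' correctness under the assumed
model, not robustness to those violations. Note also that with θ = −1.427 and
the full LTL variance the simulated case-control LTL gap (~0.5 T/S) is larger
than the study's observed 0.214 — the study's point estimates are not jointly
consistent with this simple structural model, and the generator follows the
causal parameter rather than the descriptive gap.

## Validation experiment sizes

The packaged validation protocols (used by the test suite and the
reproduction script) run at: 100 random tables of n = 200 for the EM-vs-grid
check (0.01 grid step, tolerance 1e-6); 100 seeds of n = 627 for stage-1
recovery (4·SE criterion per coefficient); 50 seeds of n = 100 000 for causal
recovery (band [−1.25, −0.80] around the generating −1.0, the width covering
the non-collapsibility attenuation of a logistic second stage, analytically
≈ 0.95 attenuation factor here); 200 seeds of n = 100 000 for the null
type-I-error calibration (5% ± 2% at α = 0.05); and 1000 replicates of
n = 100 000 for the HWE-test calibration of generated genotypes.

## Known limitations

* Two-stage logistic MR estimates a conditional-on-fitted-exposure log-OR;
  because the logistic model is non-collapsible the estimand is mildly
  attenuated relative to the structural coefficient (documented above), and
  reported ML SEs understate uncertainty away from the null.
* The exact HWE P is conservative near small minor-allele counts, as exact
  conditional tests are.
* The EM LD estimator assumes random mating within the analysed group.
* The VCF reader is deliberately minimal: biallelic SNP rows, GT field only;
  half-calls and `./.` are missing.
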