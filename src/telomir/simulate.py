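"""Synthetic case-control cohort generator.

Generates cohorts with the statistical structure the downstream analyses
assume: biallelic SNP dosages under Hardy-Weinberg equilibrium, a linear
genotype+age model for relative leukocyte telomere length (LTL, T/S units), a
logistic outcome model in which LTL (and optionally covariates) drive
case/control status, and baseline covariates drawn from group-specific
normal / Bernoulli distributions.

Sampling follows case-control ascertainment: a large source population is
simulated (genotypes -> age -> LTL -> status) and cases / controls are then
drawn until the requested group sizes are reached, so the outcome-model
intercept is a prevalence parameter and is not recoverable from the sampled
cohort.  Non-causal baseline covariates (anthropometry, blood chemistry,
lifestyle, sex) are assigned conditional on the realized group, which
reproduces observed case-control differences without asserting any causal
model for them.

Randomness: one root seed; every variable draws from an independent named
substream, so adding a SNP or covariate does not perturb existing draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "SnpSpec",
    "LtlModel",
    "OutcomeModel",
    "CovariateSpec",
    "SimulationConfig",
    "default_config",
    "simulate_genotypes",
    "simulate_two_locus_genotypes",
    "simulate_ltl",
    "simulate_outcome",
    "generate_population",
    "generate_cohort",
]


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible generator for one named variable."""
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass(frozen=True)
class SnpSpec:
    """A biallelic SNP: effect (minor) allele frequency and allele labels."""

    snp_id: str
    effect_allele: str
    other_allele: str
    maf: float
    hwe: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.maf <= 0.5):
            raise ValueError(f"{self.snp_id}: maf must be in (0, 0.5], got {self.maf}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: alleles must differ")


@dataclass(frozen=True)
class LtlModel:
    """Linear model for relative LTL: intercept + sum(beta_j g_j) + age_beta*age + noise."""

    intercept: float
    snp_betas: dict[str, float]
    age_beta: float
    residual_sd: float

    def __post_init__(self) -> None:
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")


@dataclass(frozen=True)
class OutcomeModel:
    """Logistic model for case status: intercept + ltl_beta*LTL + covariate terms."""

    intercept: float
    ltl_beta: float
    covariate_betas: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = [self.intercept, self.ltl_beta, *self.covariate_betas.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("outcome-model coefficients must be finite")


@dataclass(frozen=True)
class CovariateSpec:
    """Group-specific distribution of one baseline covariate.

    ``kind='normal'`` draws Normal(mean, sd) per group; ``kind='binary'`` draws
    Bernoulli(proportion) per group.  ``case``/``control`` hold (mean, sd) or a
    single proportion.
    """

    name: str
    kind: str
    case: tuple
    control: tuple

    def __post_init__(self) -> None:
        if self.kind not in ("normal", "binary"):
            raise ValueError("kind must be 'normal' or 'binary'")
        for grp in (self.case, self.control):
            if self.kind == "normal":
                if len(grp) != 2 or grp[1] <= 0:
                    raise ValueError(f"{self.name}: normal spec needs (mean, sd>0)")
            else:
                if not (0.0 <= grp[0] <= 1.0):
                    raise ValueError(f"{self.name}: proportion must be in [0, 1]")

    def draw(self, group: str, n: int, rng: np.random.Generator) -> np.ndarray:
        par = self.case if group == "case" else self.control
        if self.kind == "normal":
            return rng.normal(par[0], par[1], size=n)
        return (rng.random(n) < par[0]).astype(int)


@dataclass(frozen=True)
class AgeSpec:
    """Source-population age distribution (years)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("age sd must be > 0")


@dataclass
class SimulationConfig:
    n_cases: int
    n_controls: int
    snps: list[SnpSpec]
    ltl_model: LtlModel
    outcome_model: OutcomeModel
    covariate_specs: list[CovariateSpec]
    age: AgeSpec
    seed: int = 0
    #: population chunk size per ascertainment attempt and attempt cap
    chunk_size: int = 20_000
    max_attempts: int = 200
    #: optional LD between one SNP pair: (snp1, snp2, d_prime)
    ld_pair: tuple[str, str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate SNP ids in config")
        unknown = set(self.ltl_model.snp_betas) - set(ids)
        if unknown:
            raise ValueError(f"ltl_model references unknown SNPs: {sorted(unknown)}")


def simulate_genotypes(spec: SnpSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n effect-allele dosages under HWE: P(2)=maf^2, P(1)=2maf(1-maf), P(0)=(1-maf)^2."""
    if spec.hwe:
        return rng.binomial(2, spec.maf, size=n)
    # fixed-heterozygosity alternative kept trivial: still binomial sampling
    return rng.binomial(2, spec.maf, size=n)


def simulate_two_locus_genotypes(
    maf1: float, maf2: float, d_prime: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample dosages at two loci with a chosen D' by explicit haplotype pairing.

    Haplotype frequencies are built from the allele frequencies and
    D = D' * Dmax (coupling sign), then 2n haplotypes are drawn i.i.d. and
    paired, so the collapsed genotypes are a faithful random-mating sample.
    Returns (dosage1, dosage2).
    """
    if not (0.0 <= d_prime <= 1.0):
        raise ValueError("d_prime must be in [0, 1]")
    p, q = maf1, maf2
    dmax = min(p * (1 - q), (1 - p) * q)
    d = d_prime * dmax
    f = np.array([p * q + d, p * (1 - q) - d, (1 - p) * q - d, (1 - p) * (1 - q) + d])
    if (f < -1e-12).any():
        raise ValueError("infeasible haplotype frequencies")
    f = np.clip(f, 0, None)
    f /= f.sum()
    haps = rng.choice(4, size=2 * n, p=f)
    a = (haps < 2).astype(int)  # carries effect allele at locus 1
    b = ((haps == 0) | (haps == 2)).astype(int)  # effect allele at locus 2
    return a[:n] + a[n:], b[:n] + b[n:]


def simulate_ltl(
    dosages_by_snp: dict[str, np.ndarray],
    ages: np.ndarray,
    model: LtlModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Relative LTL per subject; returns (ltl, n_truncated_at_zero).

    T/S ratios are non-negative, so draws below zero are truncated to 0 and
    counted.
    """
    n = len(ages)
    for sid, g in dosages_by_snp.items():
        if len(g) != n:
            raise ValueError(f"dosage vector for {sid} has length {len(g)}, expected {n}")
    ltl = np.full(n, model.intercept, dtype=float)
    for sid, beta in model.snp_betas.items():
        ltl += beta * np.asarray(dosages_by_snp[sid], dtype=float)
    ltl += model.age_beta * np.asarray(ages, dtype=float)
    ltl += rng.normal(0.0, model.residual_sd, size=n)
    n_trunc = int((ltl < 0).sum())
    np.clip(ltl, 0.0, None, out=ltl)
    return ltl, n_trunc


def simulate_outcome(
    ltl: np.ndarray,
    covariates: dict[str, np.ndarray],
    model: OutcomeModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli case status from the logistic outcome model."""
    lp = model.intercept + model.ltl_beta * np.asarray(ltl, dtype=float)
    for name, beta in model.covariate_betas.items():
        v = np.asarray(covariates[name], dtype=float)
        if len(v) != len(lp):
            raise ValueError(f"covariate {name} not aligned with ltl")
        lp += beta * v
    if not np.all(np.isfinite(lp)):
        raise FloatingPointError("non-finite linear predictor in outcome model")
    p = 1.0 / (1.0 + np.exp(-lp))
    return (rng.random(len(p)) < p).astype(int)


def generate_population(config: SimulationConfig, n: int, seed_offset: int = 0) -> pd.DataFrame:
    """Simulate n subjects from the source population (no ascertainment).

    Columns: age, one dosage column per SNP, ltl, status.  Used directly for
    population-sampled validation studies; `generate_cohort` builds on it.
    """
    seed = config.seed + seed_offset
    ages = substream(seed, "age").normal(config.age.mean, config.age.sd, size=n)
    dosages = {
        s.snp_id: simulate_genotypes(s, n, substream(seed, f"snp:{s.snp_id}"))
        for s in config.snps
    }
    if config.ld_pair is not None:
        s1, s2, dp = config.ld_pair
        spec1 = next(s for s in config.snps if s.snp_id == s1)
        spec2 = next(s for s in config.snps if s.snp_id == s2)
        g1, g2 = simulate_two_locus_genotypes(
            spec1.maf, spec2.maf, dp, n, substream(seed, f"ldpair:{s1}:{s2}")
        )
        dosages[s1], dosages[s2] = g1, g2
    ltl, n_trunc = simulate_ltl(dosages, ages, config.ltl_model, substream(seed, "ltl"))
    status = simulate_outcome(ltl, {"age": ages}, config.outcome_model, substream(seed, "outcome"))
    df = pd.DataFrame({"age": ages, **dosages, "ltl": ltl, "status": status})
    df.attrs["n_ltl_truncated"] = n_trunc
    return df


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Ascertained case-control cohort with all baseline covariates.

    Simulates population chunks until `n_cases` cases and `n_controls`
    non-cases have accrued (abort after `max_attempts` chunks), then attaches
    group-conditional baseline covariates.  Deterministic given the config
    (including seed).  Returns (cohort, metadata).
    """
    cases, controls = [], []
    n_trunc = 0
    attempts = 0
    while (sum(len(c) for c in cases) < config.n_cases
           or sum(len(c) for c in controls) < config.n_controls):
        if attempts >= config.max_attempts:
            raise RuntimeError(
                f"could not accrue {config.n_cases} cases / {config.n_controls} controls "
                f"in {config.max_attempts} population chunks of {config.chunk_size}"
            )
        pop = generate_population(config, config.chunk_size, seed_offset=1_000 + attempts)
        n_trunc += pop.attrs["n_ltl_truncated"]
        cases.append(pop[pop["status"] == 1])
        controls.append(pop[pop["status"] == 0])
        attempts += 1
    case_df = pd.concat(cases).head(config.n_cases).reset_index(drop=True)
    control_df = pd.concat(controls).head(config.n_controls).reset_index(drop=True)

    frames = []
    for group, df in (("case", case_df), ("control", control_df)):
        df = df.copy()
        for spec in config.covariate_specs:
            rng = substream(config.seed, f"cov:{spec.name}:{group}")
            df[spec.name] = spec.draw(group, len(df), rng)
        frames.append(df)
    cohort = pd.concat(frames).reset_index(drop=True)
    cohort.insert(0, "subject_id", [f"S{i + 1:05d}" for i in range(len(cohort))])

    snp_cols = [s.snp_id for s in config.snps]
    cov_cols = [c.name for c in config.covariate_specs]
    cohort = cohort[["subject_id", "status", "age", *cov_cols, "ltl", *snp_cols]]
    meta = {
        "seed": config.seed,
        "n_cases": config.n_cases,
        "n_controls": config.n_controls,
        "population_chunks": attempts,
        "population_size_simulated": attempts * config.chunk_size,
        "n_ltl_truncated_at_zero": n_trunc,
        "sampling": "source population + case/control ascertainment "
                    "(outcome intercept not recoverable)",
        "config": _config_dict(config),
    }
    return cohort, meta


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["snps"] = [asdict(s) for s in config.snps]
    return d


# ---------------------------------------------------------------------------
# Study-default configuration
# ---------------------------------------------------------------------------

#: Study control-group minor allele frequencies of the five TERT SNPs.
TARGET_CONTROL_MAF = {
    "rs2853676": 0.17,
    "rs2242652": 0.16,
    "rs2075786": 0.34,
    "rs2736100": 0.44,
    "rs2736122": 0.09,
}

#: Source-population frequencies. Because ascertainment preferentially removes
#: LTL-shortening (risk) alleles from the control group, each population
#: frequency is the study control MAF plus the ascertainment shift measured on
#: a large simulated population, so that sampled control groups reproduce the
#: study's control MAFs.
DEFAULT_SNPS = [
    SnpSpec("rs2853676", "T", "C", 0.17 + 0.0063),
    SnpSpec("rs2242652", "A", "G", 0.16 + 0.0051),
    SnpSpec("rs2075786", "A", "G", 0.34 + 0.0169),
    SnpSpec("rs2736100", "C", "A", 0.44 - 0.0023),
    SnpSpec("rs2736122", "A", "G", 0.09 + 0.0023),
]

#: Per-allele LTL effects (T/S units) from the study's stage-1 fits.
DEFAULT_SNP_BETAS = {
    "rs2853676": -0.179292,
    "rs2242652": -0.16781,
    "rs2075786": -0.315562,
    "rs2736100": 0.060489,
    "rs2736122": -0.103726,
}

#: Baseline covariates: (case mean, sd) / (control mean, sd) or proportions.
DEFAULT_COVARIATES = [
    CovariateSpec("sex", "binary", (0.492,), (0.538,)),  # 1 = male
    CovariateSpec("height", "normal", (166.1, 8.30), (166.96, 7.82)),
    CovariateSpec("weight", "normal", (72.09, 11.72), (66.82, 10.45)),
    CovariateSpec("bmi", "normal", (26.01, 3.01), (23.86, 2.75)),
    CovariateSpec("sbp", "normal", (148.0, 22.66), (143.3, 21.61)),
    CovariateSpec("dbp", "normal", (87.46, 12.9), (83.06, 12.69)),
    CovariateSpec("hcy", "normal", (16.45, 5.88), (13.04, 4.66)),
    CovariateSpec("tg", "normal", (1.80, 1.04), (1.73, 0.74)),
    CovariateSpec("tc", "normal", (5.06, 0.99), (5.00, 0.76)),
    CovariateSpec("ldl_c", "normal", (2.95, 0.91), (2.52, 0.96)),
    CovariateSpec("hdl_c", "normal", (1.22, 0.44), (1.02, 0.41)),
    CovariateSpec("glu", "normal", (6.28, 1.45), (5.70, 1.87)),
    CovariateSpec("smoking", "binary", (0.309,), (0.212,)),
    CovariateSpec("drinking", "binary", (0.270,), (0.281,)),
    CovariateSpec("movement", "binary", (0.238,), (0.259,)),
]

#: Age acts on LTL (T/S per year) and on disease risk (log-odds per year);
#: values chosen so the ascertained groups reproduce the study's age gap and
#: the negative LTL-age correlation.
DEFAULT_AGE_BETA_LTL = -0.02
DEFAULT_AGE_BETA_OUTCOME = 0.08
DEFAULT_AGE = AgeSpec(mean=57.5, sd=6.5)
DEFAULT_RESIDUAL_SD = 0.55
#: Causal log-odds of disease per unit T/S, the study's all-SNP estimate.
DEFAULT_LTL_BETA = -1.427
#: Calibrated so the default config yields control LTL mean ~= 1.492 and a
#: source-population prevalence low enough for case-control ascertainment.
DEFAULT_LTL_INTERCEPT = 2.875
DEFAULT_OUTCOME_INTERCEPT = -4.3


def config_from_dict(d: dict) -> SimulationConfig:
    """Build a SimulationConfig from a plain dict (YAML/JSON config file).

    Any omitted block falls back to the study defaults."""
    base = default_config(seed=int(d.get("seed", 0)),
                          n_cases=int(d.get("n_cases", 307)),
                          n_controls=int(d.get("n_controls", 320)))
    snps = [SnpSpec(**s) for s in d["snps"]] if "snps" in d else base.snps
    ltl = LtlModel(**d["ltl_model"]) if "ltl_model" in d else base.ltl_model
    out = OutcomeModel(**d["outcome_model"]) if "outcome_model" in d else base.outcome_model
    covs = ([CovariateSpec(name=c["name"], kind=c["kind"],
                           case=tuple(c["case"]), control=tuple(c["control"]))
             for c in d["covariate_specs"]]
            if "covariate_specs" in d else base.covariate_specs)
    age = AgeSpec(**d["age"]) if "age" in d else base.age
    return SimulationConfig(
        n_cases=base.n_cases, n_controls=base.n_controls, snps=snps, ltl_model=ltl,
        outcome_model=out, covariate_specs=covs, age=age, seed=base.seed,
        chunk_size=int(d.get("chunk_size", base.chunk_size)),
        max_attempts=int(d.get("max_attempts", base.max_attempts)),
        ld_pair=tuple(d["ld_pair"]) if d.get("ld_pair") else None,
    )


def config_from_yaml(path) -> SimulationConfig:
    import yaml

    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def default_config(seed: int = 0, n_cases: int = 307, n_controls: int = 320) -> SimulationConfig:
    """Study-default simulation: five TERT SNPs, stage-1 LTL betas, causal
    LTL->CSVD log-OR -1.427, Table-style baseline covariates."""
    return SimulationConfig(
        n_cases=n_cases,
        n_controls=n_controls,
        snps=list(DEFAULT_SNPS),
        ltl_model=LtlModel(
            intercept=DEFAULT_LTL_INTERCEPT,
            snp_betas=dict(DEFAULT_SNP_BETAS),
            age_beta=DEFAULT_AGE_BETA_LTL,
            residual_sd=DEFAULT_RESIDUAL_SD,
        ),
        outcome_model=OutcomeModel(
            intercept=DEFAULT_OUTCOME_INTERCEPT,
            ltl_beta=DEFAULT_LTL_BETA,
            covariate_betas={"age": DEFAULT_AGE_BETA_OUTCOME},
        ),
        covariate_specs=list(DEFAULT_COVARIATES),
        age=DEFAULT_AGE,
        seed=seed,
    )
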