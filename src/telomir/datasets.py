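"""Bundled reference data for the TERT / cerebral small vessel disease case-control study.

Genotype counts, allele counts and stage-1 summary statistics published for the
five candidate TERT SNPs (307 CSVD cases, 320 healthy controls, Chinese Han
population).  These printed tables are the only public form of the study data
(the individual-level records are private), so they serve two roles here:

* exact-reproduction inputs — every allele-model OR, chi-square and MAF can be
  recomputed from the genotype counts alone;
* default parameters for the synthetic-cohort generator.

Counts are stored per SNP as ``(BB, AB, AA)`` where ``A`` is the effect (minor,
control-group) allele and ``B`` the major allele.
"""

from __future__ import annotations

from .association import GenotypeCountTable

#: Study group sizes.
N_CASES = 307
N_CONTROLS = 320

#: Effect (minor-in-controls) / other allele per SNP.
SNP_ALLELES: dict[str, tuple[str, str]] = {
    "rs2853676": ("T", "C"),
    "rs2242652": ("A", "G"),
    "rs2075786": ("A", "G"),
    "rs2736100": ("C", "A"),
    "rs2736122": ("A", "G"),
}

#: Genotype counts (BB, AB, AA) by group, A = effect allele.
GENOTYPE_COUNTS: dict[str, dict[str, tuple[int, int, int]]] = {
    "rs2853676": {"case": (185, 102, 20), "control": (222, 85, 13)},
    "rs2242652": {"case": (204, 90, 13), "control": (225, 86, 9)},
    "rs2075786": {"case": (100, 157, 50), "control": (134, 152, 34)},
    "rs2736100": {"case": (107, 161, 39), "control": (94, 169, 57)},
    "rs2736122": {"case": (265, 38, 4), "control": (265, 54, 1)},
}

#: Published allele counts (case A, case B, control A, control B).
ALLELE_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "rs2853676": (142, 472, 111, 529),
    "rs2242652": (116, 498, 104, 536),
    "rs2075786": (257, 357, 220, 420),
    "rs2736100": (239, 375, 283, 357),
    "rs2736122": (46, 568, 56, 584),
}

#: Published minor allele frequencies (case, control), 2 dp.
MAF: dict[str, tuple[float, float]] = {
    "rs2853676": (0.23, 0.17),
    "rs2242652": (0.19, 0.16),
    "rs2075786": (0.42, 0.34),
    "rs2736100": (0.39, 0.44),
    "rs2736122": (0.07, 0.09),
}

#: Published allele-model odds ratios and 1-df chi-square statistics.
ALLELE_MODEL_OR: dict[str, float] = {
    "rs2853676": 1.43,
    "rs2242652": 1.20,
    "rs2075786": 1.37,
    "rs2736100": 0.80,
    "rs2736122": 0.84,
}
ALLELE_MODEL_CHI2: dict[str, float] = {
    "rs2853676": 6.508,
    "rs2242652": 1.513,
    "rs2075786": 7.442,
    "rs2736100": 3.614,
    "rs2736122": 0.664,
}

#: Stage-1 (genotype -> relative LTL) regression summaries: beta, SE, P
#: in T/S units per effect-allele copy.
STAGE1_SUMMARY: dict[str, tuple[float, float, float]] = {
    "rs2853676": (-0.179292, 0.04043, 1.09e-5),
    "rs2242652": (-0.16781, 0.043753, 1.38e-4),
    "rs2075786": (-0.315562, 0.033672, 7.12e-21),
    "rs2736100": (0.060489, 0.036192, 0.0952),
    "rs2736122": (-0.103726, 0.061953, 0.0946),
}

#: Reported mean +/- SD of relative LTL (T/S ratio) by group.
LTL_GROUP_MEANS = {"case": (1.278, 0.634), "control": (1.492, 0.618)}

#: Reported causal log-OR of CSVD per unit T/S ratio from the all-SNP
#: (PRS-instrumented) two-stage analysis, with its SE.
CAUSAL_LOGOR_ALL_SNPS = (-1.427, 0.356)


def genotype_count_table(snp_id: str) -> GenotypeCountTable:
    """Return the published genotype counts for one SNP as a count table."""
    a, b = SNP_ALLELES[snp_id]
    case = GENOTYPE_COUNTS[snp_id]["case"]
    control = GENOTYPE_COUNTS[snp_id]["control"]
    return GenotypeCountTable(
        snp_id=snp_id, effect_allele=a, other_allele=b, case=case, control=control
    )


def all_genotype_count_tables() -> list[GenotypeCountTable]:
    return [genotype_count_table(s) for s in GENOTYPE_COUNTS]
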