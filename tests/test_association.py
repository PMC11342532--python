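"""Unit tests for allele/genotype association statistics and HWE tests."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from telomir import datasets
from telomir.association import (
    GenotypeCountTable,
    UndefinedStatisticError,
    alleles_from_genotypes,
    bonferroni,
    fit_genetic_model,
    hwe_chi2,
    hwe_exact_p,
    hwe_test,
    odds_ratio_2x2,
    pearson_chi2_2x2,
)


class TestAllelesFromGenotypes:
    @pytest.mark.parametrize("snp_id", list(datasets.GENOTYPE_COUNTS))
    def test_reproduces_published_allele_counts(self, snp_id):
        al = alleles_from_genotypes(datasets.genotype_count_table(snp_id))
        assert (al.case_a, al.case_b, al.control_a, al.control_b) == datasets.ALLELE_COUNTS[snp_id]

    def test_all_major_homozygotes_give_zero_effect_alleles(self):
        g = GenotypeCountTable("x", "A", "G", case=(50, 0, 0), control=(60, 0, 0))
        al = alleles_from_genotypes(g)
        assert al.case_a == 0 and al.control_a == 0
        assert al.case_b == 100 and al.control_b == 120


class TestOddsRatio:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((142, 472, 111, 529), 1.43),  # rs2853676 allele model
            ((50, 257, 34, 286), 1.64),    # rs2075786 recessive
            ((102, 185, 85, 222), 1.44),   # rs2853676 codominant heterozygote
        ],
    )
    def test_known_tables(self, cells, expected):
        or_, lo, hi = odds_ratio_2x2(*cells)
        assert round(or_, 2) == expected
        assert lo < or_ < hi

    def test_symmetric_table_gives_unity(self):
        or_, lo, hi = odds_ratio_2x2(7, 7, 7, 7)
        assert or_ == 1.0 and lo < 1.0 < hi

    @given(st.tuples(*[st.integers(1, 500)] * 4))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_reciprocal_property(self, cells):
        a, b, c, d = cells
        assert odds_ratio_2x2(a, b, c, d)[0] * odds_ratio_2x2(b, a, d, c)[0] == pytest.approx(1.0)

    def test_zero_cell_uses_haldane_correction(self):
        or_, lo, hi = odds_ratio_2x2(0, 10, 5, 10)
        assert or_ == pytest.approx((0.5 * 10.5) / (10.5 * 5.5))

    def test_empty_margin_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            odds_ratio_2x2(0, 0, 5, 10)


class TestPearsonChi2:
    @pytest.mark.parametrize(
        "cells,expected",
        [
            ((142, 472, 111, 529), 6.508),
            ((239, 375, 283, 357), 3.614),
            ((116, 498, 104, 536), 1.513),
        ],
    )
    def test_published_allele_tables(self, cells, expected):
        chi2, p = pearson_chi2_2x2(*cells)
        assert round(chi2, 3) == expected
        assert 0 < p < 1

    def test_proportional_table_gives_zero(self):
        chi2, p = pearson_chi2_2x2(20, 80, 10, 40)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)


class TestHwe:
    def test_perfect_hwe_integer_table(self):
        chi2, p = hwe_chi2(490, 420, 90)  # p(minor)=0.3 exactly
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert hwe_exact_p(490, 420, 90) > 0.5

    def test_monomorphic_locus(self):
        res = hwe_test((100, 0, 0), "x", "control")
        assert math.isnan(res.chi2)
        assert res.p_exact == 1.0

    @pytest.mark.parametrize(
        "snp_id,printed",
        [("rs2853676", 0.180), ("rs2242652", 0.840), ("rs2075786", 0.390),
         ("rs2736100", 0.260), ("rs2736122", 0.490)],
    )
    def test_control_groups_match_published_exact_p(self, snp_id, printed):
        """The published control-group HWE P column matches the exact test."""
        res = hwe_test(datasets.GENOTYPE_COUNTS[snp_id]["control"], snp_id, "control")
        assert res.p_exact == pytest.approx(printed, abs=0.011)
        assert res.p_exact > 0.05  # no control group deviates from HWE

    def _brute_force_exact(self, n_bb, n_ab, n_aa):
        """Independent oracle: direct conditional multinomial enumeration."""
        n = n_bb + n_ab + n_aa
        n_a = 2 * n_aa + n_ab
        n_b = 2 * n - n_a

        rare = min(n_a, n_b)

        def prob(h):
            # P(h hets | allele counts) = n! / (hom_rare! h! hom_common!)
            #                             * 2^h * rare!(2n-rare)! / (2n)!
            hom_rare = (rare - h) // 2
            hom_common = n - h - hom_rare
            return (
                math.factorial(n)
                / (math.factorial(hom_rare) * math.factorial(h) * math.factorial(hom_common))
                * 2**h
                * math.factorial(rare) * math.factorial(2 * n - rare)
                / math.factorial(2 * n)
            )

        probs = {h: prob(h) for h in range(rare % 2, rare + 1, 2)}
        total = sum(probs.values())
        obs = probs[n_ab]
        return sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total

    def test_exact_p_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(10, 80))
            p = rng.uniform(0.05, 0.5)
            g = rng.binomial(2, p, size=n)
            counts = [(g == k).sum() for k in (0, 1, 2)]
            got = hwe_exact_p(*counts)
            want = self._brute_force_exact(*counts)
            assert got == pytest.approx(want, rel=1e-9)

    def test_chi2_matches_expected_count_oracle(self):
        n_bb, n_ab, n_aa = datasets.GENOTYPE_COUNTS["rs2853676"]["control"]
        n = n_bb + n_ab + n_aa
        q = (2 * n_aa + n_ab) / (2 * n)
        exp = [n * (1 - q) ** 2, n * 2 * q * (1 - q), n * q**2]
        want = sum((o - e) ** 2 / e for o, e in zip((n_bb, n_ab, n_aa), exp))
        assert hwe_chi2(n_bb, n_ab, n_aa)[0] == pytest.approx(want)


class TestGeneticModels:
    @pytest.mark.parametrize(
        "snp_id,model,ors",
        [
            ("rs2853676", "codominant", [1.44, 1.85]),
            ("rs2853676", "dominant", [1.49]),
            ("rs2075786", "codominant", [1.38, 1.97]),
            ("rs2075786", "recessive", [1.64]),
            ("rs2736122", "codominant", [0.70, 4.00]),
            ("rs2736100", "log-additive", [0.79]),
        ],
    )
    def test_crude_fits_match_published(self, count_cohorts, snp_id, model, ors):
        fit = fit_genetic_model(count_cohorts[snp_id], snp_id, model)
        assert [round(c.odds_ratio, 2) for c in fit.contrasts] == ors

    def test_published_aic_bic(self, count_cohorts):
        fit = fit_genetic_model(count_cohorts["rs2853676"], "rs2853676", "codominant")
        assert fit.aic == pytest.approx(868.8, abs=0.05)
        assert fit.bic == pytest.approx(882.1, abs=0.05)
        assert fit.model_p == pytest.approx(0.046, abs=0.0005)

    @pytest.mark.parametrize("model", ["dominant", "recessive", "overdominant"])
    def test_two_parameter_models_equal_closed_form_or(self, count_cohorts, model):
        """Crude logistic OR equals the 2x2 table OR to >= 6 significant digits."""
        for snp_id, coh in count_cohorts.items():
            cbb, cab, caa = datasets.GENOTYPE_COUNTS[snp_id]["case"]
            kbb, kab, kaa = datasets.GENOTYPE_COUNTS[snp_id]["control"]
            if model == "dominant":
                cells = (cab + caa, cbb, kab + kaa, kbb)
            elif model == "recessive":
                cells = (caa, cbb + cab, kaa, kbb + kab)
            else:
                cells = (cab, cbb + caa, kab, kbb + kaa)
            fit = fit_genetic_model(coh, snp_id, model)
            assert fit.contrasts[0].odds_ratio == pytest.approx(
                odds_ratio_2x2(*cells)[0], rel=1e-6
            )

    def test_codominant_is_saturated_in_genotype(self, count_cohorts):
        """Fitted genotype-specific case probabilities equal observed proportions."""
        snp_id = "rs2075786"
        coh = count_cohorts[snp_id]
        fit = fit_genetic_model(coh, snp_id, "codominant")
        b0 = math.log(fit.contrasts[0].odds_ratio)  # AB log-OR
        obs_bb = coh.loc[coh[snp_id] == 0, "status"].mean()
        obs_ab = coh.loc[coh[snp_id] == 1, "status"].mean()
        alpha = math.log(obs_bb / (1 - obs_bb))
        fitted_ab = 1 / (1 + math.exp(-(alpha + b0)))
        assert fitted_ab == pytest.approx(obs_ab, abs=1e-6)

    def test_null_simulation_gives_unit_ors(self):
        rng = np.random.default_rng(5)
        import pandas as pd

        n = 30_000
        coh = pd.DataFrame({"status": rng.integers(0, 2, n), "snp": rng.binomial(2, 0.3, n)})
        fit = fit_genetic_model(coh, "snp", "log-additive")
        assert fit.contrasts[0].odds_ratio == pytest.approx(1.0, abs=0.06)
        assert fit.model_p > 0.001

    def test_adjusted_fit_uses_complete_cases(self, default_cohort):
        cohort = default_cohort.copy()
        cohort.loc[cohort.index[:10], "bmi"] = np.nan
        fit = fit_genetic_model(cohort, "rs2075786", "dominant", ["age", "bmi"])
        assert fit.n == len(cohort) - 10
        assert fit.adjustment == ("age", "bmi")


def test_bonferroni_caps_and_scales():
    out = bonferroni([0.001, 0.02, 0.2, 0.4], m=5)
    assert out == pytest.approx([0.005, 0.1, 1.0, 1.0])
    assert bonferroni([0.01], m=5)[0] == pytest.approx(0.05)
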