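"""Tests for stage-1 fits, instrument selection, PRS and two-stage MR."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from telomir.mr import (
    InstrumentSet,
    NoValidInstrumentsError,
    Stage1Result,
    build_prs,
    confounder_screen,
    leave_one_out,
    select_instruments,
    stage1_fit,
    two_stage_estimate,
)
from telomir.simulate import SnpSpec, simulate_genotypes, substream


def _stage1(snp_id, beta, p):
    return Stage1Result(snp_id=snp_id, effect_allele="A", other_allele="G",
                        beta=beta, se=0.04, p=p, n=627, f_stat=(beta / 0.04) ** 2)


STUDY_STAGE1 = [
    _stage1("rs2853676", -0.179292, 1.09e-5),
    _stage1("rs2242652", -0.16781, 1.38e-4),
    _stage1("rs2075786", -0.315562, 7.12e-21),
    _stage1("rs2736100", 0.060489, 0.0952),
    _stage1("rs2736122", -0.103726, 0.0946),
]


def wald_ratio_oracle(cohort, snp_id):
    """Independent single-instrument estimate: logistic reduced-form
    coefficient of status on dosage divided by the OLS stage-1 coefficient."""
    g = sm.add_constant(cohort[snp_id].to_numpy(dtype=float))
    rf = sm.Logit(cohort["status"].to_numpy(dtype=float), g).fit(disp=0)
    s1 = sm.OLS(cohort["ltl"].to_numpy(dtype=float), g).fit()
    return rf.params[1] / s1.params[1]


class TestStage1Fit:
    def test_noise_free_deterministic_limit(self):
        g = np.tile([0, 1, 2], 50)
        coh = pd.DataFrame({"ltl": 1.5 - 0.3 * g, "g": g})
        r = stage1_fit(coh, "g")
        assert r.beta == pytest.approx(-0.3, abs=1e-12)
        assert r.se == pytest.approx(0.0, abs=1e-10)

    def test_study_scale_recovery(self):
        n = 627
        rng = substream(13, "g")
        g = simulate_genotypes(SnpSpec("s", "A", "G", 0.34), n, rng)
        ltl = 1.6 - 0.315562 * g + substream(13, "e").normal(0, 0.55, n)
        r = stage1_fit(pd.DataFrame({"ltl": ltl, "s": g}), "s")
        assert abs(r.beta - (-0.315562)) < 4 * r.se

    def test_null_p_values_uniform(self):
        """Permuted dosages: stage-1 P over 200 seeds passes a KS uniformity
        test at alpha = 0.01."""
        n = 400
        g0 = simulate_genotypes(SnpSpec("s", "A", "G", 0.3), n, substream(0, "g"))
        ltl = substream(0, "e").normal(1.5, 0.6, n)
        ps = []
        for s in range(200):
            g = substream(s, "perm").permutation(g0)
            ps.append(stage1_fit(pd.DataFrame({"ltl": ltl, "s": g}), "s").p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_dosage_rejected(self):
        coh = pd.DataFrame({"ltl": [1.0, 2.0, 3.0], "s": [1, 1, 1]})
        with pytest.raises(ValueError, match="constant dosage"):
            stage1_fit(coh, "s")


class TestSelectInstruments:
    def test_study_p_vector_selects_three(self):
        inst = select_instruments(STUDY_STAGE1, p_threshold=0.05)
        assert inst.snp_ids == ["rs2853676", "rs2242652", "rs2075786"]
        assert inst.bonferroni_m == 5

    def test_all_null_raises(self):
        nulls = [_stage1(f"rs{i}", 0.01, 1.0) for i in range(3)]
        with pytest.raises(NoValidInstrumentsError):
            select_instruments(nulls)

    def test_threshold_one_keeps_all(self):
        inst = select_instruments(STUDY_STAGE1, p_threshold=1.0 + 1e-9)
        assert len(inst.snp_ids) == 5

    def test_confounder_audit_attached(self, default_cohort):
        s1 = [stage1_fit(default_cohort, s) for s in
              ("rs2853676", "rs2242652", "rs2075786", "rs2736100", "rs2736122")]
        inst = select_instruments(s1, default_cohort, confounders=["age", "bmi", "smoking"])
        assert inst.confounder_audit is not None
        assert set(inst.confounder_audit["covariate"]) == {"age", "bmi", "smoking"}


class TestBuildPrs:
    def test_zero_weights_give_zero_score(self, default_cohort):
        prs = build_prs(default_cohort, {"rs2853676": 0.0, "rs2075786": 0.0})
        assert (prs == 0).all()

    def test_single_snp_linearity(self):
        coh = pd.DataFrame({"s": [0, 1, 2]})
        prs = build_prs(coh, {"s": -0.3156})
        assert prs.tolist() == pytest.approx([0.0, -0.3156, -0.6312])

    def test_missing_genotype_dropped_and_logged(self, default_cohort):
        coh = default_cohort.copy()
        coh.loc[coh.index[:7], "rs2853676"] = np.nan
        prs = build_prs(coh, {"rs2853676": -0.18, "rs2075786": -0.32})
        assert prs.attrs["n_dropped"] == 7
        assert len(prs) == len(coh) - 7

    def test_ltl_on_prs_slope_is_one(self, default_cohort):
        """With weights equal to the refit single-SNP stage-1 betas, the
        regression of LTL on the PRS has slope ~ 1 (the OLS fitted-value
        property, up to cross-SNP sampling noise)."""
        snps = ["rs2853676", "rs2242652", "rs2075786"]
        weights = {s: stage1_fit(default_cohort, s).beta for s in snps}
        prs = build_prs(default_cohort, weights)
        fit = sm.OLS(default_cohort["ltl"], sm.add_constant(prs)).fit()
        assert abs(fit.params.iloc[1] - 1.0) < 4 * fit.bse.iloc[1]


class TestTwoStage:
    def test_null_effect_recovered(self):
        n = 10_000
        g = simulate_genotypes(SnpSpec("s", "A", "G", 0.3), n, substream(21, "g"))
        ltl = 1.5 - 0.3 * g + substream(21, "e").normal(0, 0.5, n)
        status = (substream(21, "o").random(n) < 0.4).astype(int)
        coh = pd.DataFrame({"status": status, "ltl": ltl, "s": g})
        est = two_stage_estimate(coh, "s")
        assert abs(est.beta) < 4 * est.se

    def test_instrument_equal_to_exposure_degenerates_to_logistic(self, default_cohort):
        """Noise-free stage 1 (instrument = exposure) reduces the two-stage
        estimate to the ordinary logistic coefficient of LTL."""
        est = two_stage_estimate(default_cohort, default_cohort["ltl"].rename("self"))
        x = sm.add_constant(default_cohort["ltl"].to_numpy())
        direct = sm.Logit(default_cohort["status"].to_numpy(dtype=float), x).fit(disp=0)
        assert est.beta == pytest.approx(direct.params[1], rel=1e-8)

    def test_matches_wald_ratio_oracle(self, default_cohort):
        """Single-SNP two-stage estimate equals the independent Wald ratio to
        at least 4 significant digits (no covariates)."""
        for snp in ("rs2853676", "rs2075786"):
            est = two_stage_estimate(default_cohort, snp)
            assert est.beta == pytest.approx(wald_ratio_oracle(default_cohort, snp), rel=1e-4)

    def test_sign_propagation_under_allele_flip(self, default_cohort):
        """Recoding dosage to the other allele flips the stage-1 beta but
        leaves the causal estimate invariant."""
        coh = default_cohort.copy()
        coh["flipped"] = 2 - coh["rs2075786"]
        est1 = two_stage_estimate(default_cohort, "rs2075786")
        est2 = two_stage_estimate(coh, "flipped")
        assert est2.stage1_beta == pytest.approx(-est1.stage1_beta, rel=1e-9)
        assert est2.beta == pytest.approx(est1.beta, rel=1e-9)

    def test_weak_instrument_warning(self):
        n = 500
        g = simulate_genotypes(SnpSpec("s", "A", "G", 0.3), n, substream(23, "g"))
        ltl = substream(23, "e").normal(1.5, 0.6, n)  # instrument irrelevant
        status = (substream(23, "o").random(n) < 0.5).astype(int)
        coh = pd.DataFrame({"status": status, "ltl": ltl, "s": g})
        est = two_stage_estimate(coh, "s")
        assert est.stage1_f < 10
        assert any("weak instrument" in w for w in est.warnings)

    def test_bootstrap_se_available(self, default_cohort):
        est = two_stage_estimate(default_cohort, "rs2075786", n_bootstrap=25,
                                 bootstrap_seed=3)
        assert est.bootstrap_se is not None and est.bootstrap_se > 0


class TestLeaveOneOut:
    def _instruments(self, cohort, snps):
        return InstrumentSet([stage1_fit(cohort, s) for s in snps],
                             p_threshold=0.05, bonferroni_m=len(snps))

    def test_cardinality(self, default_cohort):
        inst = self._instruments(default_cohort, ["rs2853676", "rs2242652", "rs2075786"])
        out = leave_one_out(default_cohort, inst)
        assert len(out) == 4
        assert out[0].label == "All SNPs"
        assert {r.label for r in out[1:]} == {
            "without rs2853676", "without rs2242652", "without rs2075786"}

    def test_single_instrument_rejected(self, default_cohort):
        inst = self._instruments(default_cohort, ["rs2075786"])
        with pytest.raises(ValueError, match="leave-one-out"):
            leave_one_out(default_cohort, inst)

    def test_duplicated_instruments_equal_full_estimate(self, default_cohort):
        """Dropping one of several identical instruments leaves the composite
        score proportional to the full score, so estimates coincide."""
        coh = default_cohort.copy()
        coh["dup1"] = coh["rs2075786"]
        coh["dup2"] = coh["rs2075786"]
        coh["dup3"] = coh["rs2075786"]
        inst = self._instruments(coh, ["dup1", "dup2", "dup3"])
        out = leave_one_out(coh, inst)
        full = out[0].beta
        for r in out[1:]:
            assert r.beta == pytest.approx(full, rel=1e-6)

    def test_dropping_null_instrument_changes_little(self, default_cohort):
        """A zero-weight instrument contributes nothing: removing it moves the
        estimate by far less than its SE."""
        coh = default_cohort.copy()
        coh["null_snp"] = simulate_genotypes(
            SnpSpec("null_snp", "A", "G", 0.3), len(coh), substream(31, "null"))
        inst = self._instruments(coh, ["rs2853676", "rs2075786", "null_snp"])
        out = {r.label: r for r in leave_one_out(coh, inst)}
        assert abs(out["without null_snp"].beta - out["All SNPs"].beta) \
            < 4 * out["All SNPs"].se


class TestConfounderScreen:
    def test_linear_function_recovered(self, default_cohort):
        coh = default_cohort.copy()
        prs = build_prs(coh, {"rs2075786": -0.3156})
        coh["fake"] = 2.0 + 3.0 * prs
        out = confounder_screen(coh, prs, ["fake"])
        row = out.iloc[0]
        assert row["beta"] == pytest.approx(3.0, abs=1e-9)
        assert row["p"] < 1e-10 and row["flagged"]

    def test_screen_shape_matches_study_table(self, default_cohort):
        covs = ["age", "sex", "height", "weight", "sbp", "dbp", "hcy", "tg", "tc",
                "ldl_c", "hdl_c", "glu", "smoking", "drinking", "movement"]
        snps = ["rs2853676", "rs2242652", "rs2075786"]
        prs = build_prs(default_cohort, {s: stage1_fit(default_cohort, s).beta for s in snps})
        out = confounder_screen(default_cohort, prs, covs)
        assert list(out.columns) == ["covariate", "test", "beta", "se", "p", "flagged"]
        assert len(out) == 15

    def test_null_calibration(self):
        """Covariates independent of genotype are flagged at ~ the nominal 5%
        rate (pooled over 200 screens)."""
        flags = 0
        total = 0
        for s in range(200):
            n = 500
            g = simulate_genotypes(SnpSpec("s", "A", "G", 0.3), n, substream(s, "g0"))
            coh = pd.DataFrame({
                "s": g,
                "c1": substream(s, "c1").normal(0, 1, n),
                "c2": substream(s, "c2").normal(5, 2, n),
            })
            prs = build_prs(coh, {"s": -0.3})
            out = confounder_screen(coh, prs, ["c1", "c2"])
            flags += int(out["flagged"].sum())
            total += len(out)
        assert 0.03 <= flags / total <= 0.07
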