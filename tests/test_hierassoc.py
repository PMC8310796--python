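"""Hierarchical nested models, early-AR definition, SNP scan, adjusted means."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from adrebound import hierassoc, mimpute


def _level1_frame(rng, n=500):
    return pd.DataFrame({
        "center": rng.integers(0, 2, n).astype(float),
        "maternal_age": rng.normal(30, 4.7, n),
        "maternal_edu_years": rng.normal(14, 2.6, n),
        "paternal_edu_years": rng.normal(13.3, 2.6, n),
        "risk_score": rng.normal(21.6, 3.2, n),
        "maternal_bmi": rng.normal(23, 4.4, n),
        "paternal_bmi": rng.normal(25, 3.6, n),
        "gwg_kg": rng.normal(13.3, 4.7, n),
        "smoking": (rng.random(n) < 0.2).astype(float),
        "preterm": (rng.random(n) < 0.06).astype(float),
        "bw_z": rng.normal(0, 1.1, n),
        "sex_female": (rng.random(n) < 0.5).astype(float),
    }).assign(bw_z_sq=lambda d: d.bw_z**2)


class TestEarlyAR:
    def test_type7_quantile_by_hand(self):
        ages = pd.Series(np.arange(1.0, 11.0))
        threshold, early = hierassoc.early_ar_indicator(ages)
        assert threshold == pytest.approx(2.8)
        assert early.sum() == 2 and set(ages[early == 1.0]) == {1.0, 2.0}

    def test_all_tied_means_nobody_early(self):
        threshold, early = hierassoc.early_ar_indicator(pd.Series([5.0] * 8))
        assert early.sum() == 0

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            hierassoc.early_ar_indicator(pd.Series([1.0, 2.0]))

    def test_normal_quantile_anchor(self):
        """AR ~ N(5.45, 1.35) gives a first-quintile threshold near
        mean - 0.8416 sd = 4.31 y."""
        rng = np.random.default_rng(8)
        ages = pd.Series(rng.normal(5.45, 1.35, 4000))
        threshold, _ = hierassoc.early_ar_indicator(ages)
        assert threshold == pytest.approx(5.45 - 0.8416 * 1.35, abs=0.1)


class TestNestedStructure:
    def test_design_columns_are_supersets(self):
        spec = hierassoc.default_hier_spec()
        hierassoc.assert_nested(spec)
        cols = hierassoc.nested_columns(spec)
        assert set(cols["A"]) < set(cols["B"]) < set(cols["C"]) < set(cols["D"])

    def test_duplicate_variable_rejected(self):
        with pytest.raises(ValueError):
            hierassoc.HierSpec(levels=(("a", "b"), ("b",)))


class TestHierLinear:
    def test_exact_linear_outcome_recovered(self):
        """Outcome an exact linear function of level-1 variables: model A
        reproduces the coefficients with ~zero residual."""
        rng = np.random.default_rng(5)
        df = _level1_frame(rng, 300)
        df["ar_days"] = (
            2000.0 - 50.0 * df.center + 3.0 * df.maternal_age
            + 15.0 * df.maternal_edu_years - 7.0 * df.paternal_edu_years
        )
        out = hierassoc.fit_hier_linear([df, df.copy()])
        a = out["models"]["A"].set_index("term")
        assert a.loc["center", "estimate"] == pytest.approx(-50.0, abs=1e-8)
        assert a.loc["maternal_edu_years", "estimate"] == pytest.approx(15.0, abs=1e-8)

    def test_identical_datasets_match_single_fit(self):
        """With duplicated complete datasets, pooling reduces to the single
        OLS fit (B = 0, T = W)."""
        rng = np.random.default_rng(6)
        df = _level1_frame(rng, 400)
        df["ar_days"] = 2000 + 10 * df.maternal_edu_years + rng.normal(0, 300, 400)
        out = hierassoc.fit_hier_linear([df, df.copy()])
        d = out["models"]["D"]
        assert np.allclose(d.B, 0.0, atol=1e-18)
        cols = hierassoc.nested_columns(hierassoc.default_hier_spec())["D"]
        X = sm.add_constant(df[cols].to_numpy())
        single = sm.OLS(df.ar_days.to_numpy(), X).fit()
        assert np.allclose(d.estimate.to_numpy(), single.params, atol=1e-10)
        assert np.allclose(d.se.to_numpy(), single.bse, atol=1e-10)

    def test_headline_reports_first_entry_model(self):
        rng = np.random.default_rng(7)
        df = _level1_frame(rng, 200)
        df["ar_days"] = rng.normal(2000, 400, 200)
        out = hierassoc.fit_hier_linear([df, df.copy()])
        head = out["headline"]
        assert head.term.is_unique
        assert head.loc[head.term == "maternal_edu_years", "model"].iloc[0] == "A"
        assert head.loc[head.term == "risk_score", "model"].iloc[0] == "B"
        assert head.loc[head.term == "bw_z", "model"].iloc[0] == "D"

    def test_rank_deficiency_raises(self):
        rng = np.random.default_rng(8)
        df = _level1_frame(rng, 100)
        df["paternal_edu_years"] = df["maternal_edu_years"]
        df["ar_days"] = rng.normal(2000, 400, 100)
        with pytest.raises(ValueError, match="rank"):
            hierassoc.fit_hier_linear([df, df.copy()])


class TestHierLogistic:
    def test_degenerate_outcome_rejected(self):
        rng = np.random.default_rng(9)
        df = _level1_frame(rng, 100)
        df["early_ar"] = 0.0
        with pytest.raises(ValueError, match="one class"):
            hierassoc.fit_hier_logistic([df, df.copy()])

    def test_odds_ratio_recovery(self):
        """A balanced binary exposure doubling the odds of early AR is
        recovered within 2 pooled SE."""
        rng = np.random.default_rng(10)
        df = _level1_frame(rng, 4000)
        logit = -1.5 + np.log(2.0) * df.smoking
        df["early_ar"] = (rng.random(4000) < 1 / (1 + np.exp(-logit))).astype(float)
        out = hierassoc.fit_hier_logistic([df, df.copy()])
        c = out["models"]["C"].set_index("term").loc["smoking"]
        assert abs(c.estimate - np.log(2.0)) < 2 * c.se
        assert c.or_lo < 2.0 < c.or_hi


class TestPerSNPScan:
    def test_effect_recovery_and_monomorphic_flag(self):
        rng = np.random.default_rng(11)
        n = 3000
        g = rng.binomial(2, 0.4, n).astype(float)
        df = pd.DataFrame({
            "ar_days": 2000.0 - 30.0 * g + rng.normal(0, 400, n),
            "rs_effect": g,
            "rs_mono": np.zeros(n),
        })
        scan = hierassoc.per_snp_scan(df, ["rs_effect", "rs_mono"])
        eff = scan.set_index("snp_id").loc["rs_effect"]
        assert eff.testable
        assert abs(eff.beta_days_per_allele + 30.0) < 2 * eff.se
        assert not scan.set_index("snp_id").loc["rs_mono"].testable


class TestAdjustedMeans:
    def test_indicator_only_model_gives_raw_class_means(self):
        rng = np.random.default_rng(12)
        n = 600
        cls = rng.choice(["SGA", "AGA", "LGA"], n, p=[0.13, 0.77, 0.10])
        df = pd.DataFrame({
            "size_class": cls,
            "i_sga": (cls == "SGA").astype(float),
            "i_lga": (cls == "LGA").astype(float),
            "ar_days": 2000.0 - 90.0 * (cls == "SGA") + 10.0 * (cls == "LGA")
                        + rng.normal(0, 300, n),
        })
        means, contrasts = hierassoc.adjusted_means_by_category(
            [df, df.copy()], category_linked=("i_sga", "i_lga"),
            columns=["i_sga", "i_lga"],
        )
        raw = df.groupby("size_class")["ar_days"].mean()
        got = means.set_index("category")["estimate"]
        for c in ("SGA", "AGA", "LGA"):
            assert got[c] == pytest.approx(raw[c], abs=1e-8)

    def test_contrast_invariant_to_centring_covariates(self):
        rng = np.random.default_rng(13)
        n = 500
        df = _level1_frame(rng, n)
        df["ar_days"] = 2000 + 24 * df.bw_z - 14 * df.bw_z_sq + rng.normal(0, 300, n)
        df["size_class"] = np.where(
            df.bw_z <= -1.2816, "SGA", np.where(df.bw_z > 1.2816, "LGA", "AGA")
        )
        _, con_a = hierassoc.adjusted_means_by_category([df, df.copy()])
        df2 = df.copy()
        df2["maternal_age"] = df2["maternal_age"] - df2["maternal_age"].mean()
        _, con_b = hierassoc.adjusted_means_by_category([df2, df2.copy()])
        assert np.allclose(
            con_a["estimate"].to_numpy(), con_b["estimate"].to_numpy(), atol=1e-8
        )
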