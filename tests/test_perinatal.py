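"""Customized birth-weight z-scores and derived perinatal covariates."""

import numpy as np
import pandas as pd
import pytest

from adrebound import perinatal


def _record(**kw):
    base = dict(
        child_id="c0", sex="female", gestational_age_weeks=40.0, parity=0.0,
        maternal_weight_kg=65.0, maternal_height_m=1.63, birth_weight_kg=3.3,
    )
    base.update(kw)
    return pd.DataFrame([base])


class TestCustomizedZScore:
    def test_observed_equal_expected_gives_zero(self):
        model = perinatal.default_centile_model()
        rec = _record()
        e = perinatal.expected_weight(model, ["female"], [40.0], [0.0], [65.0], [1.63])
        z = perinatal.customized_zscore(rec.assign(birth_weight_kg=e), model)
        assert z.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_one_cv_above_expected_gives_one(self):
        model = perinatal.default_centile_model()
        e = perinatal.expected_weight(model, ["male"], [38.0], [1.0], [70.0], [1.70])
        rec = _record(sex="male", gestational_age_weeks=38.0, parity=1.0,
                      maternal_weight_kg=70.0, maternal_height_m=1.70,
                      birth_weight_kg=float(e[0] * (1 + model.cv)))
        assert perinatal.customized_zscore(rec, model).iloc[0] == pytest.approx(1.0)

    def test_independent_formula_recomputation(self):
        """Spreadsheet-style recomputation of the same linear-predictor and
        proportion formulas on a fixture record."""
        m = perinatal.default_centile_model()
        ga, parity, mw, mh = 37.5, 2.0, 58.0, 1.58
        term = (m.base_weight_g + m.sex_male_g * 1 + m.parity_2plus_g
                + m.per_kg_maternal_weight_g * (mw - 65.0)
                + m.per_cm_maternal_height_g * (mh * 100 - 163.0))
        d = ga - 40.0
        expected = term * (1 + m.prop_linear * d + m.prop_quadratic * d * d) / 1000.0
        obs = 2.9
        z_hand = (obs - expected) / (m.cv * expected)
        rec = _record(sex="male", gestational_age_weeks=ga, parity=parity,
                      maternal_weight_kg=mw, maternal_height_m=mh,
                      birth_weight_kg=obs)
        assert perinatal.customized_zscore(rec, m).iloc[0] == pytest.approx(z_hand)

    def test_gestational_age_support(self):
        with pytest.raises(ValueError, match="support"):
            perinatal.customized_zscore(_record(gestational_age_weeks=24.0))

    def test_doubling_cv_halves_z(self):
        m1 = perinatal.default_centile_model()
        m2 = perinatal.CentileModel(cv=2 * m1.cv)
        rec = _record(birth_weight_kg=3.9)
        z1 = perinatal.customized_zscore(rec, m1).iloc[0]
        z2 = perinatal.customized_zscore(rec, m2).iloc[0]
        assert z2 == pytest.approx(z1 / 2.0)


class TestClassifySize:
    @pytest.mark.parametrize(
        "z, expected",
        [
            (0.0, "AGA"),
            (perinatal.SGA_Z_CUT, "SGA"),            # 10th centile: <= rule
            (perinatal.SGA_Z_CUT + 1e-9, "AGA"),
            (perinatal.LGA_Z_CUT, "AGA"),            # 90th centile still AGA
            (perinatal.LGA_Z_CUT + 1e-9, "LGA"),
        ],
    )
    def test_boundaries(self, z, expected):
        assert perinatal.classify_size([z])[0] == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            perinatal.classify_size([np.nan])

    def test_monotone_in_birth_weight(self):
        m = perinatal.default_centile_model()
        weights = np.linspace(1.8, 5.0, 40)
        recs = pd.concat([_record(birth_weight_kg=w) for w in weights],
                         ignore_index=True)
        z = perinatal.customized_zscore(recs, m)
        assert (np.diff(z) > 0).all()
        order = {"SGA": 0, "AGA": 1, "LGA": 2}
        cls = [order[c] for c in perinatal.classify_size(z)]
        assert (np.diff(cls) >= 0).all()

    def test_reference_population_calibration(self):
        """Records drawn from the model's own assumptions land ~10% SGA and
        ~10% LGA."""
        rng = np.random.default_rng(31)
        n = 20000
        m = perinatal.default_centile_model()
        rec = pd.DataFrame({
            "sex": np.where(rng.random(n) < 0.5, "male", "female"),
            "gestational_age_weeks": np.clip(rng.normal(39.3, 1.5, n), 30, 43),
            "parity": rng.choice([0.0, 1.0, 2.0], n),
            "maternal_weight_kg": rng.normal(63, 10, n),
            "maternal_height_m": rng.normal(1.63, 0.065, n),
        })
        e = perinatal.expected_weight(
            m, rec.sex, rec.gestational_age_weeks, rec.parity,
            rec.maternal_weight_kg, rec.maternal_height_m,
        )
        rec["birth_weight_kg"] = e * (1 + m.cv * rng.normal(0, 1, n))
        cls = perinatal.classify_size(perinatal.customized_zscore(rec, m))
        frac = pd.Series(cls).value_counts(normalize=True)
        assert frac["SGA"] == pytest.approx(0.10, abs=0.01)
        assert frac["LGA"] == pytest.approx(0.10, abs=0.01)


class TestDeriveCovariates:
    def test_bmi_preterm_and_class_columns(self):
        df = pd.DataFrame(
            {
                "child_id": ["a", "b"],
                "sex": ["male", "female"],
                "gestational_age_weeks": [37.0, 36.9],
                "parity": [0.0, 1.0],
                "maternal_weight_kg": [81.0, 60.0],
                "maternal_height_m": [1.80, 1.60],
                "paternal_weight_kg": [80.0, np.nan],
                "paternal_height_m": [1.80, 1.75],
                "birth_weight_kg": [3.2, 2.9],
            }
        )
        out = perinatal.derive_covariates(df)
        assert out.loc[0, "maternal_bmi"] == pytest.approx(25.0)
        assert out.loc[0, "preterm"] == 0.0      # 37.0 weeks: strict '<'
        assert out.loc[1, "preterm"] == 1.0
        assert np.isnan(out.loc[1, "paternal_bmi"])
        assert out.loc[0, "bw_z_sq"] == pytest.approx(out.loc[0, "bw_z"] ** 2)
        assert out.loc[0, "size_class"] in {"SGA", "AGA", "LGA"}

    def test_non_positive_height_rejected(self):
        df = pd.DataFrame({"maternal_weight_kg": [60.0], "maternal_height_m": [0.0]})
        with pytest.raises(ValueError, match="height"):
            perinatal.derive_covariates(df)
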