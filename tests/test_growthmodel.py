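"""Eligibility filtering and the mixed-effects cubic growth model."""

import numpy as np
import pandas as pd
import pytest

from adrebound import growthmodel, simcohort


def _cubic_records(coefs, ages, child_ids, noise=0.0, rng=None):
    rows = []
    for cid in child_ids:
        c0, c1, c2, c3 = coefs[cid] if isinstance(coefs, dict) else coefs
        y = c0 + c1 * ages + c2 * ages**2 + c3 * ages**3
        if noise and rng is not None:
            y = y + rng.normal(0, noise, len(ages))
        rows.append(pd.DataFrame({"child_id": cid, "age_days": ages, "bmi": np.exp(y)}))
    return pd.concat(rows, ignore_index=True)


class TestEligibility:
    def _table(self, spec):
        # spec: {child_id: list of ages}
        return pd.concat(
            [pd.DataFrame({"child_id": cid, "age_days": ages, "bmi": 16.0})
             for cid, ages in spec.items()],
            ignore_index=True,
        )

    def test_window_and_count_rules(self):
        tab = self._table({
            "two_in_window": [100, 600, 700],          # 2 inside [548, 4748]
            "three_in_window": [548, 2000, 4748],       # boundary ages count
            "all_before_window": [10, 50, 200, 400, 547],
            "plenty": [600, 900, 1500, 2500, 3500],
        })
        eligible, log = growthmodel.eligibility_filter(tab)
        assert set(eligible) == {"three_in_window", "plenty"}
        reasons = dict(zip(log.child_id, log.reason))
        assert reasons["two_in_window"] == "only_2_measurements_in_window"
        assert reasons["all_before_window"] == "no_measurements_in_window"

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            growthmodel.eligibility_filter(
                pd.DataFrame(columns=["child_id", "age_days", "bmi"])
            )


class TestFitCubicMixed:
    def test_sample_size_floor(self):
        ages = np.linspace(100, 4000, 8)
        tab = _cubic_records((2.7, 1e-5, -1e-8, 2e-12), ages, [f"c{i}" for i in range(5)])
        with pytest.raises(ValueError, match="at least 30"):
            growthmodel.fit_cubic_mixed(tab)

    def test_noiseless_fixed_cubic_identified(self):
        """Zero random-effect variance, zero noise: fixed effects equal the
        generating day-scale coefficients to 1e-6 relative."""
        true = np.array([2.74, 3.4e-5, -1.5e-7, 4.45e-11])
        ages = np.linspace(50, 4700, 12)
        tab = _cubic_records(tuple(true), ages, [f"c{i}" for i in range(40)])
        fit = growthmodel.fit_cubic_mixed(tab)
        assert fit.method == "zero_residual_limit"
        curves = growthmodel.predict_curves(fit)
        est = curves[["c0", "c1", "c2", "c3"]].to_numpy()
        rel = np.abs(est - true) / np.abs(true)
        assert rel.max() < 1e-6

    def test_dense_noiseless_interpolates_observations(self):
        """Dense noise-free data: fitted curves reproduce observed log-BMI
        at every measurement age."""
        cfg = simcohort.SimConfig(
            n_children=25, seed=5, noise_sd=0.0, schedule="daily",
            daily_step_days=60.0,
        )
        anthro, *_ = simcohort.generate_cohort(cfg)
        fit = growthmodel.fit_cubic_mixed(anthro, min_children=10)
        curves = growthmodel.predict_curves(fit).set_index("child_id")
        merged = anthro.assign(logbmi=np.log(anthro.weight_kg / anthro.height_m**2))
        for cid, grp in merged.groupby("child_id"):
            c = curves.loc[cid, ["c0", "c1", "c2", "c3"]].to_numpy()
            a = grp.age_days.to_numpy()
            pred = c[0] + c[1] * a + c[2] * a**2 + c[3] * a**3
            assert np.max(np.abs(pred - grp.logbmi.to_numpy())) < 1e-4

    def test_blup_centring_in_degenerate_limit(self):
        """When random effects are exactly centred (noise-free per-child
        fits), the mean individual curve equals the fixed-effects curve."""
        rng = np.random.default_rng(3)
        ages = np.linspace(50, 4700, 10)
        coefs = {
            f"c{i}": (2.74 + rng.normal(0, 0.05), 3.4e-5 + rng.normal(0, 5e-6),
                      -1.5e-7, 4.45e-11)
            for i in range(35)
        }
        tab = _cubic_records(coefs, ages, list(coefs))
        fit = growthmodel.fit_cubic_mixed(tab)
        re_mat = np.vstack(list(fit.random_effects.values()))
        assert np.abs(re_mat.mean(axis=0)).max() < 1e-6 * (1 + np.abs(re_mat).max())

    def test_row_permutation_invariance(self, small_cohort):
        _, anthro, *_ = small_cohort
        eligible, _ = growthmodel.eligibility_filter(anthro)
        rec = anthro[anthro.child_id.isin(eligible) & (anthro.sex == "male")]
        fit_a = growthmodel.fit_cubic_mixed(rec)
        shuffled = rec.sample(frac=1.0, random_state=9).reset_index(drop=True)
        fit_b = growthmodel.fit_cubic_mixed(shuffled)
        assert np.allclose(fit_a.fixed_effects, fit_b.fixed_effects, atol=1e-8)
        assert np.isclose(fit_a.sigma2, fit_b.sigma2, atol=1e-8)

    def test_noise_inflates_residual_variance(self):
        sig = {}
        for noise in (0.02, 0.06):
            cfg = simcohort.SimConfig(n_children=150, seed=21, noise_sd=noise)
            anthro, *_ = simcohort.generate_cohort(cfg)
            eligible, _ = growthmodel.eligibility_filter(anthro)
            fit = growthmodel.fit_cubic_mixed(
                anthro[anthro.child_id.isin(eligible)], sex="male"
            )
            sig[noise] = fit.sigma2
        assert sig[0.06] > sig[0.02]

    def test_translation_covariance(self, small_cohort):
        """Shifting every measurement age by +delta shifts each child's
        estimated nadir age by delta, up to REML optimizer precision."""
        from adrebound import rebound

        _, anthro, *_ = small_cohort
        eligible, _ = growthmodel.eligibility_filter(anthro)
        rec = anthro[anthro.child_id.isin(eligible) & (anthro.sex == "female")]
        delta = 100.0
        shifted = rec.assign(age_days=rec.age_days + delta)
        c_a = growthmodel.predict_curves(growthmodel.fit_cubic_mixed(rec))
        c_b = growthmodel.predict_curves(growthmodel.fit_cubic_mixed(shifted))
        merged = c_a.merge(c_b, on="child_id", suffixes=("_a", "_b"))
        n_checked = 0
        for _, r in merged.head(40).iterrows():
            ra = rebound.estimate_ar((r.c0_a, r.c1_a, r.c2_a, r.c3_a),
                                     window=(548, 4748))
            rb = rebound.estimate_ar((r.c0_b, r.c1_b, r.c2_b, r.c3_b),
                                     window=(548 + delta, 4748 + delta))
            if ra.status == rb.status == "estimated":
                # exact in exact arithmetic; in practice limited by the REML
                # optimizer's stopping tolerance (well under one day)
                assert rb.ar_age_days - ra.ar_age_days == pytest.approx(delta, abs=0.5)
                n_checked += 1
        assert n_checked >= 20
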