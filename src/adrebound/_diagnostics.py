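"""Validation computations: oracle checks, parameter-recovery and
calibration runs used by the test suite and the reproduction script.

Each function regenerates its inputs from a seed, runs the package's own
estimators, and returns plain numbers; nothing here is precomputed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from ._constants import ELIGIBILITY_WINDOW_DAYS
from . import growthmodel, hierassoc, perinatal, rebound, simcohort

__all__ = [
    "grid_oracle_check",
    "noiseless_recovery",
    "noisy_recovery",
    "effect_recovery",
    "null_calibration",
    "truth_anchor",
]


def _random_curves(rng: np.random.Generator, n: int) -> np.ndarray:
    """Cubic curves from the simulator's peak-then-nadir family, spanning
    the full AR range including out-of-window and capped cases."""
    ar = rng.uniform(700.0, 4600.0, n)
    peak = np.clip(rng.normal(270.0, 40.0, n), 60.0, 0.5 * ar)
    c3 = 2.0e-11 * np.exp(rng.normal(0.0, 0.4, n))
    c2 = -1.5 * c3 * (peak + ar)
    c1 = 3.0 * c3 * peak * ar
    c0 = rng.normal(2.74, 0.05, n)
    return np.column_stack([c0, c1, c2, c3])


def grid_oracle_check(seed: int, n: int = 10000, chunk: int = 500) -> dict:
    """Analytic AR versus an exhaustive 1-day grid search for the last
    in-window local minimum, over ``n`` random cubic curves."""
    rng = np.random.default_rng([seed, 1])
    curves = _random_curves(rng, n)
    lo, hi = ELIGIBILITY_WINDOW_DAYS
    ages = np.arange(lo, hi + 0.5, 1.0)
    worst = 0.0
    n_estimated = 0
    for start in range(0, n, chunk):
        block = curves[start:start + chunk]
        vals = (
            block[:, [0]] + block[:, [1]] * ages + block[:, [2]] * ages**2
            + block[:, [3]] * ages**3
        )
        is_min = (vals[:, 1:-1] < vals[:, :-2]) & (vals[:, 1:-1] <= vals[:, 2:])
        for i, c in enumerate(block):
            res = rebound.estimate_ar(c)
            idx = np.flatnonzero(is_min[i])
            grid = ages[idx[-1] + 1] if idx.size else None
            if res.status == "estimated":
                assert grid is not None, "grid found no minimum where analytic did"
                worst = max(worst, abs(res.ar_age_days - grid))
                n_estimated += 1
            else:
                assert grid is None, "analytic missed a grid minimum"
    return {"max_discrepancy_days": worst, "n": n, "n_estimated": n_estimated}


def noiseless_recovery(seed: int, n_children: int = 40) -> dict:
    """Dense daily sampling, zero measurement noise: the fitted individual
    curves must return every child's true AR to < 1 day."""
    cfg = simcohort.SimConfig(
        n_children=n_children, seed=seed, noise_sd=0.0, schedule="daily",
        daily_step_days=1.0, ar_sd_years=0.9, missing_rates={},
    )
    anthro, _, _, truth = simcohort.generate_cohort(cfg)
    fit = growthmodel.fit_cubic_mixed(anthro, min_children=10)
    curves = growthmodel.predict_curves(fit)
    table, _ = rebound.ar_for_cohort(curves)
    merged = table.merge(truth, on="child_id")
    est = merged[merged.status == "estimated"]
    assert len(est) == n_children, "noiseless dense fit lost a child"
    err = np.abs(est.ar_age_days - est.true_ar_days)
    return {"max_abs_error_days": float(err.max()), "n": n_children}


def noisy_recovery(seed: int, n_children: int = 500) -> dict:
    """AR recovery under the default study conditions (~10 noisy
    measurements per child on the clinic-visit schedule)."""
    cfg = simcohort.SimConfig(n_children=n_children, seed=seed)
    anthro, _, _, truth = simcohort.generate_cohort(cfg)
    eligible, exclusions = growthmodel.eligibility_filter(anthro)
    records = anthro[anthro.child_id.isin(eligible)]
    curves = pd.concat(
        [
            growthmodel.predict_curves(growthmodel.fit_cubic_mixed(records, sex=s))
            for s in ("male", "female")
        ],
        ignore_index=True,
    )
    table, _ = rebound.ar_for_cohort(curves, exclusions)
    merged = table[table.status == "estimated"].merge(truth, on="child_id")
    err = (merged.ar_age_days - merged.true_ar_days).to_numpy()
    return {
        "median_abs_error_days": float(np.median(np.abs(err))),
        "bias_days": float(err.mean()),
        "bias_ci_half_days": float(1.96 * err.std(ddof=1) / np.sqrt(len(err))),
        "n": int(len(err)),
    }


def _analysis_from_truth(truth: pd.DataFrame) -> pd.DataFrame:
    """Analysis covariate table built from pre-missingness truth, with the
    true AR as outcome (isolates the association machinery from growth-curve
    estimation error)."""
    df = perinatal.derive_covariates(truth)
    df["sex_female"] = (df["sex"] == "female").astype(float)
    df["risk_score"] = df["risk_score_true"]
    df["ar_days"] = df["true_ar_days"]
    df["ar_years"] = df["true_ar_years"]
    return df


def effect_recovery(seed: int, n_children: int = 5000) -> dict:
    """Recovery of the generating risk-score effect (-9.2 d/allele) and a
    built-in SGA deficit (-90 d) by the pooled hierarchical models."""
    cfg = simcohort.SimConfig(
        n_children=n_children, seed=seed, sga_deficit_days=-90.0,
        simulate_anthropometry=False, missing_rates={},
        genotype_missing_rate=0.0,
    )
    _, _, _, truth = simcohort.generate_cohort(cfg)
    df = _analysis_from_truth(truth)
    datasets = [df, df.copy()]
    linear = hierassoc.fit_hier_linear(datasets)
    head = linear["headline"].set_index("term")
    _, contrasts = hierassoc.adjusted_means_by_category(datasets)
    con = contrasts.set_index("contrast")
    sga_aga = -con.loc["AGA-SGA", "estimate"]
    sga_aga_se = con.loc["AGA-SGA", "se"]
    return {
        "score_effect": float(head.loc["risk_score", "estimate"]),
        "score_se": float(head.loc["risk_score", "se"]),
        "score_truth": cfg.score_effect,
        "sga_aga_contrast": float(sga_aga),
        "sga_aga_se": float(sga_aga_se),
        "sga_aga_truth": -90.0,
        "n": n_children,
    }


def null_calibration(seed: int, reps: int = 400, n_children: int = 250) -> dict:
    """Type-I error of the hierarchical models and uniformity of per-SNP
    null p-values when no covariate or SNP affects AR."""
    effects = {k: 0.0 for k in simcohort.default_true_effects()}
    reject: dict[str, int] = {}
    snp_pvals: list[float] = []
    snps = None
    for r in range(reps):
        cfg = simcohort.SimConfig(
            n_children=n_children, seed=int((seed * 100003 + r) % 2**31),
            true_effects=effects, score_effect=0.0,
            bw_z_linear=0.0, bw_z_quadratic=0.0,
            base_ar_years={"male": 5.45, "female": 5.45}, ar_sd_years=1.3,
            simulate_anthropometry=False, missing_rates={},
            genotype_missing_rate=0.0,
        )
        _, _, geno, truth = simcohort.generate_cohort(cfg)
        df = _analysis_from_truth(truth)
        head = hierassoc.fit_hier_linear([df, df.copy()])["headline"]
        for _, row in head.iterrows():
            reject[row.term] = reject.get(row.term, 0) + (row.p < 0.05)
        if snps is None:
            snps = [c for c in geno.columns if c.startswith("rs")]
        scan = hierassoc.per_snp_scan(
            df.merge(geno, on="child_id"), snps
        )
        snp_pvals.extend(scan.loc[scan.testable, "p"].tolist())
    rates = {k: v / reps for k, v in reject.items()}
    ks = stats.kstest(np.asarray(snp_pvals), "uniform")
    return {
        "rejection_rates": rates,
        "rate_min": min(rates.values()),
        "rate_max": max(rates.values()),
        "rate_mean": float(np.mean(list(rates.values()))),
        "snp_ks_p": float(ks.pvalue),
        "n_snp_pvals": len(snp_pvals),
        "reps": reps,
    }


def truth_anchor(seed: int, n_children: int = 2000) -> dict:
    """AR distribution anchors under the default generating conditions:
    per-sex means/SDs and the first-quintile (early AR) threshold."""
    cfg = simcohort.SimConfig(
        n_children=n_children, seed=seed, simulate_anthropometry=False,
    )
    _, _, _, truth = simcohort.generate_cohort(cfg)
    boys = truth.loc[truth.sex == "male", "true_ar_years"]
    girls = truth.loc[truth.sex == "female", "true_ar_years"]
    threshold, _ = hierassoc.early_ar_indicator(truth["true_ar_years"])
    return {
        "mean_boys": float(boys.mean()), "sd_boys": float(boys.std(ddof=1)),
        "mean_girls": float(girls.mean()), "sd_girls": float(girls.std(ddof=1)),
        "first_quintile_years": float(threshold),
        "n": n_children,
    }
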