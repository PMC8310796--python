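"""Synthetic mother-child cohort generator with known true AR ages.

Every downstream stage (growth modelling, AR estimation, scoring,
imputation, hierarchical association) is testable against the truth table
this module emits.  A child's latent age at adiposity rebound is built
additively from sex, mean-centred covariate effects, the risk-allele score
and a quadratic birth-weight-z term, plus Gaussian noise; the child's cubic
log-BMI curve is then solved so its last minimum sits exactly at that age.

Defaults emulate a French birth-cohort setting: ~10 irregular weight/height
measurements per child from birth to 13 years concentrated around routine
clinic visits, mean AR 5.5 y (boys) / 5.4 y (girls) with total SD ~1.3 y,
risk-allele effect -9.2 days per allele, and MAR missingness in covariates
driven by recruitment centre and maternal education.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from ._constants import DAYS_PER_YEAR, ELIGIBILITY_WINDOW_DAYS
from . import genetics, perinatal

__all__ = [
    "SimConfig",
    "default_true_effects",
    "generate_cohort",
    "inject_missingness",
    "implied_sga_contrast",
]


def default_true_effects() -> dict[str, float]:
    """Generating covariate effects on AR age, in days per unit.

    Keys name analysis-table covariates; values are the multivariable
    coefficients used as simulation truth (education in days/year of study,
    BMI in days per kg/m^2, gestational weight gain days/kg, smoking and
    preterm as days for the indicator).
    """
    return {
        "center": 0.0,
        "maternal_age": 2.8,
        "maternal_edu_years": 15.7,
        "paternal_edu_years": 14.4,
        "maternal_bmi": -15.9,
        "paternal_bmi": -15.6,
        "gwg_kg": -7.5,
        "smoking": -72.1,
        "preterm": 39.4,
    }


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort."""

    n_children: int = 1000
    seed: int = 0
    #: negative-binomial mean of per-child measurement counts
    mean_measurements: float = 10.0
    nb_dispersion: float = 4.0
    count_range: tuple[int, int] = (1, 25)
    measurement_window: tuple[float, float] = (0.0, ELIGIBILITY_WINDOW_DAYS[1])
    #: 'visits' (routine clinic ages + health records), 'uniform', or 'daily'
    schedule: str = "visits"
    daily_step_days: float = 1.0
    #: mean AR per sex, years
    base_ar_years: dict = field(default_factory=lambda: {"male": 5.5, "female": 5.4})
    #: residual SD of true AR, years (total SD with covariate effects ~1.3 y)
    ar_sd_years: float = 1.26
    #: SD of the log-BMI measurement residual
    noise_sd: float = 0.04
    #: days of AR per risk allele
    score_effect: float = -9.2
    true_effects: dict = field(default_factory=default_true_effects)
    #: birth-weight z effects (days): linear and quadratic terms
    bw_z_linear: float = 24.1
    bw_z_quadratic: float = -14.4
    #: if set, rescale the two z terms so the implied SGA-AGA contrast (days)
    #: equals this value under the generating z distribution
    sga_deficit_days: float | None = None
    #: generating distribution of the customized birth-weight z-score
    bw_z_mean: float = -0.05
    bw_z_sd: float = 1.1
    allele_freqs: np.ndarray | None = None
    genotype_missing_rate: float = 0.30
    missing_rates: dict = field(
        default_factory=lambda: {
            "paternal_weight_kg": 0.10,
            "paternal_height_m": 0.10,
            "paternal_edu_years": 0.04,
            "gwg_kg": 0.06,
            "smoking": 0.03,
            "maternal_weight_kg": 0.02,
            "maternal_height_m": 0.02,
        }
    )
    #: cubic coefficient scale of the log-BMI trajectory (per day^3); each
    #: child's curve is parameterized by its infancy BMI-peak age and its AR
    #: age, which fixes the quadratic and linear terms (see generate_cohort)
    cubic_coef: float = 2.0e-11
    cubic_coef_log_sd: float = 0.12
    #: infancy BMI peak age (days): mean and SD across children
    peak_age_days: tuple[float, float] = (270.0, 40.0)
    nadir_bmi: float = 15.5
    nadir_bmi_log_sd: float = 0.05
    simulate_anthropometry: bool = True
    centile_model: perinatal.CentileModel = field(
        default_factory=perinatal.default_centile_model
    )

    def __post_init__(self) -> None:
        if self.n_children < 1:
            raise ValueError("n_children must be >= 1")
        if self.measurement_window[0] < 0:
            raise ValueError("measurement window lower bound must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.allele_freqs is None:
            self.allele_freqs = genetics.default_panel()["freq"].to_numpy()
        freqs = np.asarray(self.allele_freqs, dtype=float)
        if np.any((freqs <= 0) | (freqs >= 1)):
            raise ValueError("allele frequencies must lie strictly inside (0, 1)")
        for col, rate in self.missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missingness rate for {col} outside [0, 1]")


def implied_sga_contrast(
    lin: float, quad: float, z_mean: float, z_sd: float
) -> float:
    """E[AR | SGA] - E[AR | AGA] (days) implied by a quadratic z effect.

    Classes cut the generating normal z ~ N(z_mean, z_sd) at the customized
    10th/90th centile z values; conditional first and second moments come
    from the truncated normal.
    """
    def moments(a, b):
        d = stats.truncnorm((a - z_mean) / z_sd, (b - z_mean) / z_sd,
                            loc=z_mean, scale=z_sd)
        m = d.mean()
        return m, d.var() + m * m

    m_s, s_s = moments(-np.inf, perinatal.SGA_Z_CUT)
    m_a, s_a = moments(perinatal.SGA_Z_CUT, perinatal.LGA_Z_CUT)
    return lin * (m_s - m_a) + quad * (s_s - s_a)


def _bw_z_terms(config: SimConfig) -> tuple[float, float]:
    """Generating (linear, quadratic) z coefficients, rescaled to match a
    requested SGA-AGA deficit when ``sga_deficit_days`` is set."""
    lin, quad = config.bw_z_linear, config.bw_z_quadratic
    if config.sga_deficit_days is not None:
        base = implied_sga_contrast(lin, quad, config.bw_z_mean, config.bw_z_sd)
        if base == 0.0:
            raise ValueError("cannot scale zero z-effect to a nonzero deficit")
        s = config.sga_deficit_days / base
        lin, quad = lin * s, quad * s
    return lin, quad


# ages (days) of routine measurement occasions outside the four clinic visits
_RECORD_POOL = np.array(
    [30, 61, 91, 122, 152, 183, 274, 456, 548, 639, 730, 912, 1278, 1461,
     1642, 2191, 2556, 2922, 3287, 3652, 4018, 4383, 4700], dtype=float
)
_CLINIC_VISITS = np.array([10.0, 365.0, 1095.0, 1825.0])


def _measurement_ages(rng: np.random.Generator, count: int,
                      window: tuple[float, float], schedule: str,
                      daily_step: float) -> np.ndarray:
    lo, hi = window
    if schedule == "daily":
        return np.arange(lo, hi + daily_step / 2, daily_step)
    if schedule == "uniform":
        return np.sort(rng.uniform(lo, hi, count))
    core = _CLINIC_VISITS + rng.normal(0.0, 20.0, len(_CLINIC_VISITS))
    if count <= len(core):
        ages = rng.choice(core, size=count, replace=False)
    else:
        n_extra = min(count - len(core), len(_RECORD_POOL))
        extra = rng.choice(_RECORD_POOL, size=n_extra, replace=False)
        extra = extra + rng.normal(0.0, 25.0, n_extra)
        ages = np.concatenate([core, extra])
    return np.sort(np.clip(ages, lo, hi))


def _height_m(age_days: np.ndarray) -> np.ndarray:
    """Crude median stature curve (m) used only to decompose BMI into
    weight and height; BMI = weight/height^2 recovers the simulated value
    exactly whatever the stature curve."""
    a = np.asarray(age_days, dtype=float)
    return 0.52 + 0.60 * (1.0 - np.exp(-a / 1100.0)) + 5.5e-5 * a


def _simulate_genotypes(
    rng: np.random.Generator, n: int, panel: pd.DataFrame
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray, np.ndarray]:
    freqs = panel["freq"].to_numpy()
    k = len(freqs)
    mother = rng.binomial(2, freqs, size=(n, k)).astype(float)
    father = rng.binomial(2, freqs, size=(n, k)).astype(float)
    # each parent transmits one allele, probability dosage/2 of the risk allele
    child = (
        rng.binomial(1, mother / 2.0).astype(float)
        + rng.binomial(1, father / 2.0).astype(float)
    )
    return child, mother.sum(axis=1), father.sum(axis=1), child.sum(axis=1)


def generate_cohort(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort.

    Returns ``(anthropometry, covariates, genotypes, truth)``:

    - anthropometry: long table child_id, sex, age_days, weight_kg, height_m
      (empty when ``simulate_anthropometry`` is off);
    - covariates: one row per child, raw perinatal fields, after MAR
      missingness injection;
    - genotypes: child_id + one dosage column per panel SNP (whole rows
      withheld for a configured fraction of children);
    - truth: pre-missingness covariates, true curve coefficients c0..c3,
      true AR age (days), true scores and parental scores.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_children
    panel = genetics.default_panel()
    panel = panel.assign(freq=np.asarray(config.allele_freqs, dtype=float))

    child_id = np.array([f"C{i:05d}" for i in range(n)])
    sex = np.where(rng.random(n) < 0.527, "male", "female")
    center = rng.integers(0, 2, n).astype(float)          # 0 = Poitiers ref
    maternal_age = rng.normal(29.9, 4.7, n)
    maternal_edu = rng.normal(14.0, 2.6, n)
    paternal_edu = rng.normal(13.3, 2.6, n)
    maternal_height = rng.normal(1.63, 0.065, n)
    maternal_bmi = np.clip(rng.normal(23.1, 4.4, n), 16.0, None)
    maternal_weight = maternal_bmi * maternal_height**2
    paternal_height = rng.normal(1.76, 0.07, n)
    paternal_bmi = np.clip(rng.normal(25.1, 3.6, n), 16.0, None)
    paternal_weight = paternal_bmi * paternal_height**2
    gwg = rng.normal(13.3, 4.7, n)
    smoking = (rng.random(n) < 0.214).astype(float)
    parity = rng.choice([0.0, 1.0, 2.0], size=n, p=[0.43, 0.35, 0.22])
    gest_age = np.clip(rng.normal(39.3, 1.5, n), 30.0, 43.0)
    preterm = (gest_age < 37.0).astype(float)

    z_true = rng.normal(config.bw_z_mean, config.bw_z_sd, n)
    expected = perinatal.expected_weight(
        config.centile_model, sex, gest_age, parity, maternal_weight, maternal_height
    )
    birth_weight = expected * (1.0 + config.centile_model.cv * z_true)

    child_dos, mother_score, father_score, child_score = _simulate_genotypes(
        rng, n, panel
    )
    weighted_true = child_dos @ panel["weight"].to_numpy()

    # --- latent AR: base + mean-centred effects + noise -------------------
    base = np.array(
        [config.base_ar_years[s] for s in sex], dtype=float
    ) * DAYS_PER_YEAR
    covs = {
        "center": center,
        "maternal_age": maternal_age,
        "maternal_edu_years": maternal_edu,
        "paternal_edu_years": paternal_edu,
        "maternal_bmi": maternal_bmi,
        "paternal_bmi": paternal_bmi,
        "gwg_kg": gwg,
        "smoking": smoking,
        "preterm": preterm,
    }
    ar = base.copy()
    for name, eff in config.true_effects.items():
        if name not in covs:
            raise KeyError(f"unknown covariate in true_effects: {name}")
        x = covs[name]
        ar = ar + eff * (x - x.mean())
    ar = ar + config.score_effect * (child_score - child_score.mean())
    lin, quad = _bw_z_terms(config)
    ar = ar + lin * (z_true - z_true.mean()) + quad * (z_true**2 - (z_true**2).mean())
    ar = ar + rng.normal(0.0, config.ar_sd_years * DAYS_PER_YEAR, n)

    lo_w, hi_w = config.measurement_window
    outside = (ar <= lo_w) | (ar >= hi_w)
    if outside.mean() > 0.05:
        warnings.warn(
            f"{outside.mean():.1%} of true AR ages fall outside the "
            "measurement window", stacklevel=2
        )

    # --- curve: peak-then-nadir cubic with the nadir exactly at AR --------
    # derivative 3*c3*(a - peak)(a - AR) with c3 > 0 and peak < AR puts the
    # BMI maximum at the infancy peak and the minimum at AR for every child
    peak_mu, peak_sd = config.peak_age_days
    peak = np.clip(rng.normal(peak_mu, peak_sd, n), 60.0, 0.5 * ar)
    c3 = config.cubic_coef * np.exp(rng.normal(0.0, config.cubic_coef_log_sd, n))
    log_nadir = np.log(config.nadir_bmi) + rng.normal(0.0, config.nadir_bmi_log_sd, n)
    # cap the cubic term so the post-rebound rise projected to the end of the
    # window stays below BMI ~50 (a cubic extrapolates steeply for the
    # earliest rebounds); the rise from nadir to age H is
    # c3 * (L^3 + 1.5 (AR - peak) L^2) with L = H - AR
    L = np.maximum(hi_w - ar, 0.0)
    rise_unit = L**3 + 1.5 * (ar - peak) * L**2
    with np.errstate(divide="ignore"):
        c3_cap = np.where(
            rise_unit > 0, (np.log(50.0) - log_nadir) / rise_unit, np.inf
        )
    c3 = np.minimum(c3, c3_cap)
    c2 = -1.5 * c3 * (peak + ar)
    c1 = 3.0 * c3 * peak * ar
    c0 = log_nadir - (c1 * ar + c2 * ar**2 + c3 * ar**3)

    # --- anthropometry ----------------------------------------------------
    if config.simulate_anthropometry:
        mean_m, k = config.mean_measurements, config.nb_dispersion
        counts = rng.negative_binomial(k, k / (k + mean_m), n)
        counts = np.clip(counts, *config.count_range)
        frames = []
        for i in range(n):
            ages = _measurement_ages(
                rng, int(counts[i]), config.measurement_window,
                config.schedule, config.daily_step_days,
            )
            log_bmi = (
                c0[i] + c1[i] * ages + c2[i] * ages**2 + c3[i] * ages**3
                + rng.normal(0.0, config.noise_sd, len(ages))
            )
            bmi = np.exp(log_bmi)
            h = _height_m(ages)
            frames.append(
                pd.DataFrame(
                    {
                        "child_id": child_id[i],
                        "sex": sex[i],
                        "age_days": ages,
                        "weight_kg": bmi * h**2,
                        "height_m": h,
                    }
                )
            )
        anthro = pd.concat(frames, ignore_index=True)
    else:
        anthro = pd.DataFrame(
            columns=["child_id", "sex", "age_days", "weight_kg", "height_m"]
        )

    covariates = pd.DataFrame(
        {
            "child_id": child_id,
            "sex": sex,
            "center": center,
            "maternal_age": maternal_age,
            "maternal_edu_years": maternal_edu,
            "paternal_edu_years": paternal_edu,
            "maternal_weight_kg": maternal_weight,
            "maternal_height_m": maternal_height,
            "paternal_weight_kg": paternal_weight,
            "paternal_height_m": paternal_height,
            "gwg_kg": gwg,
            "smoking": smoking,
            "parity": parity,
            "gestational_age_weeks": gest_age,
            "birth_weight_kg": birth_weight,
            "mother_score": mother_score,
            "father_score": father_score,
        }
    )

    withheld = rng.random(n) < config.genotype_missing_rate
    dos = child_dos.copy()
    dos[withheld, :] = np.nan
    genotypes = pd.DataFrame(dos, columns=panel["snp_id"].tolist())
    genotypes.insert(0, "child_id", child_id)

    truth = covariates.drop(columns=["mother_score", "father_score"]).copy()
    truth["preterm"] = preterm
    truth["bw_z_true"] = z_true
    truth["risk_score_true"] = child_score
    truth["weighted_score_true"] = weighted_true
    truth["mother_score"] = mother_score
    truth["father_score"] = father_score
    truth["genotypes_withheld"] = withheld
    truth["true_ar_days"] = ar
    truth["true_ar_years"] = ar / DAYS_PER_YEAR
    truth["c0"] = c0
    truth["c1"] = c1
    truth["c2"] = c2
    truth["c3"] = c3
    truth["ar_outside_window"] = outside
    truth.attrs["ar_outside_window_frac"] = float(outside.mean())
    truth.attrs["bw_z_terms"] = (lin, quad)

    covariates = inject_missingness(
        covariates, config.missing_rates, seed=rng.integers(0, 2**31 - 1)
    )
    return anthro, covariates, genotypes, truth


def inject_missingness(
    table: pd.DataFrame,
    rates: dict[str, float],
    seed: int,
    depends_on: tuple[str, str] = ("center", "maternal_edu_years"),
) -> pd.DataFrame:
    """Mask covariate cells missing-at-random at the requested rates.

    The missingness probability for each cell follows a logistic model in
    the (always-observed) dependence covariates -- recruitment centre and
    maternal education by default -- with the intercept solved so the
    marginal rate matches ``rates[column]`` exactly in expectation.  Rate 0
    leaves a column untouched; rate 1 empties it.
    """
    for col, rate in rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for {col} outside [0, 1]")
    rng = np.random.default_rng(seed)
    out = table.copy()
    slopes = (0.5, -0.4)
    linpred = np.zeros(len(table))
    for col, beta in zip(depends_on, slopes):
        if col in table.columns:
            x = table[col].to_numpy(dtype=float)
            x = np.where(np.isnan(x), np.nanmean(x), x)
            sd = x.std()
            linpred = linpred + beta * ((x - x.mean()) / sd if sd > 0 else 0.0)
    for col, rate in rates.items():
        if col not in table.columns or rate == 0.0:
            continue
        if rate == 1.0:
            out[col] = np.nan
            continue
        a = optimize.brentq(
            lambda a: special.expit(a + linpred).mean() - rate, -30.0, 30.0
        )
        mask = rng.random(len(table)) < special.expit(a + linpred)
        out.loc[mask, col] = np.nan
    return out
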