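"""Sex-stratified mixed-effects cubic growth model for log-BMI.

The model, fitted separately for boys and girls with age in days,

    log(BMI) = (b0 + u0) + (b1 + u1) Age + (b2 + u2) Age^2 + (b3 + u3) Age^3 + e

has fixed effects b0..b3, child-level random effects u0..u3 with
unstructured 4x4 covariance G, and residual e.  Each child's individual
curve is c_k = b_k + u_k with u the predicted (BLUP) random effects; the
rebound module locates the curve's last minimum.

Age is centred and scaled (days / 1000) internally for conditioning;
exported coefficients are always on the raw days scale.  Estimation is
REML via statsmodels MixedLM with a defined fallback chain (ML, then
dropping the cubic random effect); a zero-residual degenerate limit (dense
noiseless data) is served by the per-child least-squares solution, which is
the BLUP limit as the residual variance goes to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._constants import ELIGIBILITY_WINDOW_DAYS

__all__ = [
    "GrowthModelFit",
    "eligibility_filter",
    "fit_cubic_mixed",
    "predict_curves",
]

_AGE_SCALE = 1000.0  # days per internal age unit
_BMI_RANGE = (5.0, 60.0)


@dataclass
class GrowthModelFit:
    """Converged growth-model fit for one sex.

    ``fixed_effects`` and the per-child ``random_effects`` are on the
    internal (centred, days/1000) age scale; ``predict_curves`` returns
    day-scale coefficients.  ``method`` records the estimation path
    actually used ('reml', 'ml', 'reml_quad_re', 'ml_quad_re',
    'zero_residual_limit').
    """

    sex: str | None
    fixed_effects: np.ndarray
    cov_re: np.ndarray
    sigma2: float
    random_effects: dict
    age_center: float
    n_children: int
    n_obs: int
    converged: bool
    method: str
    warnings_log: list = dc_field(default_factory=list)

    def summary_dict(self) -> dict:
        return {
            "sex": self.sex,
            "fixed_effects_scaled": self.fixed_effects.tolist(),
            "cov_re": self.cov_re.tolist(),
            "sigma2": self.sigma2,
            "age_center_days": self.age_center,
            "n_children": self.n_children,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "method": self.method,
            "warnings": self.warnings_log,
        }


def _bmi_column(records: pd.DataFrame) -> pd.Series:
    if "bmi" in records.columns:
        return records["bmi"].astype(float)
    if {"weight_kg", "height_m"}.issubset(records.columns):
        return records["weight_kg"] / records["height_m"] ** 2
    raise ValueError("records need a 'bmi' column or 'weight_kg'/'height_m'")


def eligibility_filter(
    records: pd.DataFrame,
    window: tuple[float, float] = ELIGIBILITY_WINDOW_DAYS,
    min_count: int = 3,
) -> tuple[list, pd.DataFrame]:
    """Children with at least ``min_count`` BMI measurements inside the
    18-month-to-13-year window (inclusive bounds).

    Returns ``(eligible_ids, exclusion_log)``; the log has one row per
    excluded child with the reason.
    """
    if records.empty:
        raise ValueError("empty anthropometry table")
    lo, hi = window
    age = records["age_days"].astype(float)
    in_win = (age >= lo) & (age <= hi)
    counts_in = records.loc[in_win].groupby("child_id").size()
    all_ids = pd.Index(records["child_id"].unique())
    eligible = counts_in[counts_in >= min_count].index
    rows = []
    for cid in all_ids.difference(eligible):
        k = int(counts_in.get(cid, 0))
        reason = (
            "no_measurements_in_window" if k == 0
            else f"only_{k}_measurements_in_window"
        )
        rows.append((cid, k, reason))
    log = pd.DataFrame(rows, columns=["child_id", "n_in_window", "reason"])
    return [cid for cid in all_ids if cid in set(eligible)], log


def _shift_poly(coefs: np.ndarray, center: float, scale: float) -> np.ndarray:
    """Re-express p(t), t = (a - center)/scale, as a polynomial in a (days)."""
    p = np.polynomial.Polynomial(coefs)
    q = p(np.polynomial.Polynomial([-center / scale, 1.0 / scale]))
    out = np.zeros(4)
    out[: len(q.coef)] = q.coef
    return out


def _per_child_ols(y, X, ids):
    """Per-child least-squares cubics; returns (coef matrix, pooled RSS, dof)."""
    uids = pd.unique(ids)
    coefs, rss, dof = {}, 0.0, 0
    for cid in uids:
        m = ids == cid
        Xi, yi = X[m], y[m]
        if Xi.shape[0] >= 4 and np.linalg.matrix_rank(Xi) == 4:
            b, res, *_ = np.linalg.lstsq(Xi, yi, rcond=None)
            coefs[cid] = b
            rss += float(res[0]) if res.size else float(((yi - Xi @ b) ** 2).sum())
            dof += Xi.shape[0] - 4
        else:
            coefs[cid] = None
    return coefs, rss, dof


def fit_cubic_mixed(
    records: pd.DataFrame,
    sex: str | None = None,
    min_children: int = 30,
    zero_residual_tol: float = 1e-12,
) -> GrowthModelFit:
    """Fit the mixed-effects cubic to log-BMI for one sex.

    ``records``: long table with child_id, age_days and bmi (or weight/
    height); pass ``sex`` to subset a mixed-sex table.  Raises on fewer
    than ``min_children`` children or if every fallback fails to converge.
    """
    df = records
    if sex is not None:
        df = df[df["sex"] == sex]
    if df.empty:
        raise ValueError("no records for requested sex")
    bmi = _bmi_column(df).to_numpy(dtype=float)
    if np.any(bmi <= _BMI_RANGE[0]) or np.any(bmi >= _BMI_RANGE[1]):
        warnings.warn("BMI values outside the plausible (5, 60) range", stacklevel=2)
    ids = df["child_id"].to_numpy()
    n_children = pd.unique(ids).size
    if n_children < min_children:
        raise ValueError(
            f"{n_children} children supplied; at least {min_children} required"
        )
    age = df["age_days"].to_numpy(dtype=float)
    center = float(age.mean())
    t = (age - center) / _AGE_SCALE
    y = np.log(bmi)
    X = np.column_stack([np.ones_like(t), t, t**2, t**3])

    # degenerate zero-residual limit: per-child exact cubics
    coefs, rss, dof = _per_child_ols(y, X, ids)
    fitted_all = all(c is not None for c in coefs.values())
    if fitted_all and dof > 0 and rss / dof < zero_residual_tol:
        mat = np.vstack([coefs[c] for c in coefs])
        beta = mat.mean(axis=0)
        re = {cid: coefs[cid] - beta for cid in coefs}
        return GrowthModelFit(
            sex=sex, fixed_effects=beta,
            cov_re=np.cov(mat.T) if len(mat) > 1 else np.zeros((4, 4)),
            sigma2=rss / dof if dof else 0.0,
            random_effects=re, age_center=center,
            n_children=n_children, n_obs=len(y),
            converged=True, method="zero_residual_limit",
            warnings_log=["residual variance below tolerance; "
                          "per-child least-squares limit used"],
        )

    # powell first: near the G boundary (small higher-order RE variance) the
    # gradient-based flag is unstable while powell converges reproducibly
    attempts = [
        ("reml", X, True, "powell"),
        ("reml_lbfgs", X, True, "lbfgs"),
        ("ml", X, False, "powell"),
        ("reml_quad_re", X[:, :3], True, "lbfgs"),
        ("ml_quad_re", X[:, :3], False, "lbfgs"),
    ]
    log: list[str] = []
    for name, Xre, reml, opt in attempts:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                model = sm.MixedLM(y, X, groups=ids, exog_re=Xre)
                res = model.fit(reml=reml, method=opt, maxiter=2000)
            except (np.linalg.LinAlgError, ValueError) as err:
                log.append(f"{name}: raised {err!r}")
                continue
        msgs = [str(w.message) for w in caught]
        if not res.converged:
            log.append(f"{name}: did not converge")
            continue
        if name != "reml":
            log.append(f"fallback used: {name}")
        log.extend(msgs)
        q = Xre.shape[1]
        re = {}
        for cid, u in res.random_effects.items():
            v = np.zeros(4)
            v[:q] = np.asarray(u, dtype=float)
            re[cid] = v
        cov = np.zeros((4, 4))
        cov[:q, :q] = np.asarray(res.cov_re)
        return GrowthModelFit(
            sex=sex, fixed_effects=np.asarray(res.fe_params, dtype=float),
            cov_re=cov, sigma2=float(res.scale), random_effects=re,
            age_center=center, n_children=n_children, n_obs=len(y),
            converged=True, method=name, warnings_log=log,
        )
    raise RuntimeError(
        "mixed-model estimation failed after all fallbacks: " + "; ".join(log)
    )


def predict_curves(fit: GrowthModelFit, child_ids=None) -> pd.DataFrame:
    """Per-child cubic coefficients c0..c3 on the log-BMI vs age-in-days scale.

    c_k = beta_k + u_k on the internal scale, then back-transformed to days.
    Requesting a child absent from the fit raises KeyError.
    """
    ids = list(fit.random_effects) if child_ids is None else list(child_ids)
    rows = []
    for cid in ids:
        if cid not in fit.random_effects:
            raise KeyError(f"child {cid!r} not in fitted model")
        c_scaled = fit.fixed_effects + fit.random_effects[cid]
        rows.append((cid, *_shift_poly(c_scaled, fit.age_center, _AGE_SCALE)))
    out = pd.DataFrame(rows, columns=["child_id", "c0", "c1", "c2", "c3"])
    out.attrs["scale"] = "log_bmi_vs_age_days"
    return out
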