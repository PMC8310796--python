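"""Chained-equations multiple imputation and Rubin pooling.

Missing covariate cells are filled by fully conditional specification
(FCS): cycling variable-by-variable, each incomplete variable is regressed
on all others and its missing cells are replaced by *stochastic draws* from
the fitted conditional (never conditional means), so that between-dataset
variability reflects imputation uncertainty.  Conditional models:

- continuous  -> Bayesian linear regression draw (sigma^2 from the scaled
  inverse-chi-square posterior, beta from its normal posterior, then
  y = X beta* + N(0, sigma*));
- binary      -> logistic regression with a normal draw of the coefficient
  vector, then Bernoulli draws;
- fallback    -> predictive mean matching (PMM, 5 donors), also used when a
  conditional fit fails (e.g. separation), with the fallback logged.

Downstream estimates from the M completed datasets are combined with
Rubin's rules: pooled estimate q-bar, within-variance W, between-variance
B, total T = W + (1 + 1/M) B, and Barnard-Rubin small-sample degrees of
freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
import statsmodels.api as sm

__all__ = ["ImputationPlan", "fcs_impute", "rubin_pool"]


@dataclass
class ImputationPlan:
    """Settings for one FCS run.

    ``methods`` maps column -> 'linear' | 'logistic' | 'pmm'; unlisted
    incomplete columns get an automatic choice (binary -> logistic, else
    linear).  ``predictors`` restricts the conditioning set (default: every
    other column, including auxiliaries such as parental scores and the
    analysis outcome).  Per-dataset RNG streams derive from ``seed``.
    """

    m: int = 40
    n_iter: int = 10
    seed: int = 0
    methods: dict = field(default_factory=dict)
    predictors: dict = field(default_factory=dict)
    pmm_donors: int = 5

    def __post_init__(self) -> None:
        if self.m < 2:
            raise ValueError("at least M = 2 imputed datasets required")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")


def _is_binary(s: pd.Series) -> bool:
    vals = s.dropna().unique()
    return len(vals) <= 2 and set(np.asarray(vals, dtype=float)) <= {0.0, 1.0}


def _design(df: pd.DataFrame, cols: list[str]) -> np.ndarray:
    X = df[cols].to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    X = X[:, keep]
    return np.column_stack([np.ones(len(df)), X])


def _draw_linear(rng, y_obs, X_obs, X_mis):
    n, p = X_obs.shape
    b, _, rank, _ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ b
    df_resid = max(n - rank, 1)
    sigma2_star = float(resid @ resid) / stats.chi2.rvs(df_resid, random_state=rng)
    XtX = X_obs.T @ X_obs
    cov = sigma2_star * np.linalg.pinv(XtX)
    b_star = rng.multivariate_normal(b, cov, method="svd", check_valid="ignore")
    return X_mis @ b_star + rng.normal(0.0, np.sqrt(sigma2_star), len(X_mis))


def _draw_pmm(rng, y_obs, X_obs, X_mis, donors):
    n, p = X_obs.shape
    b, _, rank, _ = np.linalg.lstsq(X_obs, y_obs, rcond=None)
    resid = y_obs - X_obs @ b
    df_resid = max(n - rank, 1)
    sigma2_star = float(resid @ resid) / stats.chi2.rvs(df_resid, random_state=rng)
    cov = sigma2_star * np.linalg.pinv(X_obs.T @ X_obs)
    b_star = rng.multivariate_normal(b, cov, method="svd", check_valid="ignore")
    pred_obs = X_obs @ b
    pred_mis = X_mis @ b_star
    out = np.empty(len(X_mis))
    k = min(donors, len(y_obs))
    for j, pm in enumerate(pred_mis):
        nearest = np.argpartition(np.abs(pred_obs - pm), k - 1)[:k]
        out[j] = y_obs[nearest[rng.integers(k)]]
    return out


def _draw_logistic(rng, y_obs, X_obs, X_mis):
    res = sm.Logit(y_obs, X_obs).fit(disp=0, maxiter=100)
    if not res.mle_retvals.get("converged", False):
        raise RuntimeError("logistic conditional did not converge")
    cov = np.asarray(res.cov_params())
    if not np.all(np.isfinite(cov)):
        raise RuntimeError("singular logistic information")
    b_star = rng.multivariate_normal(
        np.asarray(res.params), cov, method="svd", check_valid="ignore"
    )
    p = special.expit(X_mis @ b_star)
    return rng.binomial(1, p).astype(float)


def fcs_impute(
    table: pd.DataFrame, plan: ImputationPlan
) -> tuple[list[pd.DataFrame], dict]:
    """Produce M completed copies of ``table``.

    Observed cells are never altered.  Non-numeric columns (ids, labels)
    pass through untouched and are excluded from the conditioning set.
    Returns ``(datasets, report)`` where the report records per-variable
    missingness, the conditional model used, and any fallbacks.
    """
    numeric = [c for c in table.columns
               if pd.api.types.is_numeric_dtype(table[c])]
    incomplete = [c for c in numeric if table[c].isna().any()]
    for c in incomplete:
        if table[c].isna().all():
            raise ValueError(f"column {c!r} is 100% missing; no model can be fitted")
    methods = {}
    for c in incomplete:
        methods[c] = plan.methods.get(
            c, "logistic" if _is_binary(table[c]) else "linear"
        )
    # impute in order of increasing missingness (standard FCS visit order)
    incomplete.sort(key=lambda c: table[c].isna().sum())
    report = {
        "m": plan.m,
        "n_iter": plan.n_iter,
        "variables": {
            c: {"missing": int(table[c].isna().sum()), "method": methods[c],
                "fallbacks": 0}
            for c in incomplete
        },
    }
    datasets = []
    for m_idx in range(plan.m):
        rng = np.random.default_rng([plan.seed, m_idx])
        df = table.copy()
        if not incomplete:
            datasets.append(df)
            continue
        # initial fill: random draws from the observed margins
        for c in incomplete:
            mis = df[c].isna()
            obs = df.loc[~mis, c].to_numpy(dtype=float)
            df.loc[mis, c] = rng.choice(obs, size=int(mis.sum()), replace=True)
        masks = {c: table[c].isna().to_numpy() for c in incomplete}
        for _ in range(plan.n_iter):
            for c in incomplete:
                mis = masks[c]
                preds = plan.predictors.get(
                    c, [x for x in numeric if x != c]
                )
                X = _design(df, preds)
                y_obs = df.loc[~mis, c].to_numpy(dtype=float)
                X_obs, X_mis = X[~mis], X[mis]
                method = methods[c]
                try:
                    if method == "linear":
                        vals = _draw_linear(rng, y_obs, X_obs, X_mis)
                    elif method == "logistic":
                        vals = _draw_logistic(rng, y_obs, X_obs, X_mis)
                    else:
                        vals = _draw_pmm(rng, y_obs, X_obs, X_mis, plan.pmm_donors)
                except (RuntimeError, np.linalg.LinAlgError, ValueError):
                    vals = _draw_pmm(rng, y_obs, X_obs, X_mis, plan.pmm_donors)
                    report["variables"][c]["fallbacks"] += 1
                df.loc[mis, c] = vals
        datasets.append(df)
    return datasets, report


def rubin_pool(
    estimates,
    variances,
    df_com: float | None = None,
    names: list[str] | None = None,
) -> pd.DataFrame:
    """Combine per-dataset estimates with Rubin's rules.

    ``estimates`` and ``variances`` are (M,) or (M, k) arrays of point
    estimates and their squared standard errors.  Returns one row per
    coefficient with q-bar, W, B, T = W + (1 + 1/M) B, the Barnard-Rubin
    degrees of freedom (infinite-complete-data limit when ``df_com`` is
    None) and the two-sided t/normal p-value.
    """
    q = np.atleast_2d(np.asarray(estimates, dtype=float))
    u = np.atleast_2d(np.asarray(variances, dtype=float))
    if np.asarray(estimates).ndim == 1:
        q, u = q.T, u.T
    m, k = q.shape
    if m < 2:
        raise ValueError("Rubin pooling requires M >= 2 datasets")
    if np.any(u <= 0):
        raise ValueError("variances must be positive")
    qbar = q.mean(axis=0)
    w = u.mean(axis=0)
    b = q.var(axis=0, ddof=1)
    t = w + (1.0 + 1.0 / m) * b
    lam = np.divide((1.0 + 1.0 / m) * b, t, out=np.zeros(k), where=t > 0)
    with np.errstate(divide="ignore"):
        df_old = np.where(lam > 0, (m - 1) / lam**2, np.inf)
        if df_com is None:
            dof = df_old
        else:
            df_obs = (df_com + 1.0) / (df_com + 3.0) * df_com * (1.0 - lam)
            dof = 1.0 / (1.0 / df_old + 1.0 / df_obs)
    se = np.sqrt(t)
    tstat = qbar / se
    pval = np.where(
        np.isinf(dof),
        2 * stats.norm.sf(np.abs(tstat)),
        2 * stats.t.sf(np.abs(tstat), np.where(np.isinf(dof), 1, dof)),
    )
    out = pd.DataFrame(
        {
            "estimate": qbar, "W": w, "B": b, "T": t,
            "se": se, "df": dof, "t": tstat, "p": pval,
        }
    )
    if names is not None:
        out.insert(0, "term", names)
    return out
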