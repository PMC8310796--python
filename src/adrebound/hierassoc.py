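"""Four-level hierarchical nested association models for age at AR.

Distal-to-proximal modelling: four strictly nested regressions A - D add
variable blocks in order of assumed causal distance from the outcome
(socio-demographics -> parental obesity/genetics -> intrauterine exposures
-> newborn characteristics).  A variable's *headline* coefficient is taken
from the first model in which it enters, so proximal intermediates cannot
absorb distal effects.  Linear models take AR age in days as outcome;
logistic models take the early-AR indicator (rebound before the first
in-sample quintile of AR age).  Each model is fitted on every imputed
dataset and pooled with Rubin's rules.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .mimpute import rubin_pool

__all__ = [
    "HierSpec",
    "default_hier_spec",
    "nested_columns",
    "assert_nested",
    "early_ar_indicator",
    "fit_hier_linear",
    "fit_hier_logistic",
    "per_snp_scan",
    "adjusted_means_by_category",
    "plot_adjusted_means",
]

MODEL_NAMES = ("A", "B", "C", "D")


@dataclass(frozen=True)
class HierSpec:
    """Variable blocks per hierarchical level (most distal first)."""

    levels: tuple = (
        ("center", "maternal_age", "maternal_edu_years", "paternal_edu_years"),
        ("risk_score", "maternal_bmi", "paternal_bmi"),
        ("gwg_kg", "smoking"),
        ("preterm", "bw_z", "bw_z_sq", "sex_female"),
    )

    def __post_init__(self) -> None:
        flat = [v for lvl in self.levels for v in lvl]
        if len(set(flat)) != len(flat):
            raise ValueError("a variable appears in more than one level")
        lvl4 = self.levels[-1] if self.levels else ()
        if ("bw_z_sq" in lvl4) != ("bw_z" in lvl4) and (
            "bw_z_sq" in flat or "bw_z" in flat
        ):
            raise ValueError("bw_z_sq must accompany bw_z")


def default_hier_spec() -> HierSpec:
    return HierSpec()


def nested_columns(spec: HierSpec) -> dict[str, list[str]]:
    """Cumulative design columns of models A..D."""
    out, acc = {}, []
    for name, lvl in zip(MODEL_NAMES, spec.levels):
        acc = acc + list(lvl)
        out[name] = list(acc)
    return out


def assert_nested(spec: HierSpec) -> None:
    """Structural invariant: each model's columns are a superset of its
    predecessor's."""
    cols = nested_columns(spec)
    prev: set = set()
    for name in MODEL_NAMES[: len(spec.levels)]:
        cur = set(cols[name])
        if not prev <= cur:
            raise AssertionError(f"model {name} is not nested in its predecessor")
        prev = cur


def early_ar_indicator(ar_years: pd.Series) -> tuple[float, pd.Series]:
    """Early-AR definition: rebound strictly before the first quintile.

    The threshold is the in-sample 20th percentile of estimated AR age
    (linear-interpolation / type-7 quantile); at least 5 values required.
    With all values tied, nobody is early (strict '<').
    """
    vals = ar_years.dropna()
    if len(vals) < 5:
        raise ValueError("need at least 5 estimated AR ages for a quintile")
    threshold = float(np.quantile(vals.to_numpy(dtype=float), 0.20))
    return threshold, (ar_years < threshold).astype(float)


def _fit_pooled(
    datasets: list[pd.DataFrame],
    columns: list[str],
    outcome: str,
    family: str,
) -> pd.DataFrame:
    params, variances = [], []
    names = ["const"] + columns
    for df in datasets:
        sub = df[[outcome] + columns].dropna()
        y = sub[outcome].to_numpy(dtype=float)
        X = sm.add_constant(sub[columns].to_numpy(dtype=float), has_constant="add")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("rank-deficient design matrix")
        if family == "linear":
            res = sm.OLS(y, X).fit()
        else:
            if len(np.unique(y)) < 2:
                raise ValueError("degenerate outcome: only one class present")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        params.append(np.asarray(res.params))
        variances.append(np.asarray(res.bse) ** 2)
    n = len(datasets[0][[outcome] + columns].dropna())
    df_com = n - len(names) if family == "linear" else None
    pooled = rubin_pool(np.vstack(params), np.vstack(variances),
                        df_com=df_com, names=names)
    pooled.insert(1, "n", n)
    return pooled


def _headline(per_model: dict[str, pd.DataFrame], spec: HierSpec) -> pd.DataFrame:
    rows = []
    for name, lvl in zip(MODEL_NAMES, spec.levels):
        tab = per_model[name]
        for var in lvl:
            row = tab[tab.term == var].iloc[0].copy()
            row["model"] = name
            row["level"] = MODEL_NAMES.index(name) + 1
            rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True)


def fit_hier_linear(
    datasets: list[pd.DataFrame],
    spec: HierSpec | None = None,
    outcome: str = "ar_days",
) -> dict:
    """Models A-D on AR age (days), pooled over imputed datasets.

    Returns ``{'models': {A..D: pooled table}, 'headline': table}`` where
    the headline table reports each variable from its first-entry model.
    """
    if spec is None:
        spec = default_hier_spec()
    assert_nested(spec)
    cols = nested_columns(spec)
    per_model = {
        name: _fit_pooled(datasets, cols[name], outcome, "linear")
        for name in MODEL_NAMES[: len(spec.levels)]
    }
    return {"models": per_model, "headline": _headline(per_model, spec)}


def fit_hier_logistic(
    datasets: list[pd.DataFrame],
    spec: HierSpec | None = None,
    outcome: str = "early_ar",
) -> dict:
    """Models A-D with logit link on the early-AR indicator.

    Pooled tables gain OR and 95% CI columns (exponentiated pooled log-odds).
    """
    if spec is None:
        spec = default_hier_spec()
    assert_nested(spec)
    cols = nested_columns(spec)
    per_model = {}
    for name in MODEL_NAMES[: len(spec.levels)]:
        tab = _fit_pooled(datasets, cols[name], outcome, "logistic")
        crit = np.where(np.isinf(tab["df"]), 1.959964,
                        [float(sm_t) for sm_t in _t_crit(tab["df"])])
        tab["or"] = np.exp(tab["estimate"])
        tab["or_lo"] = np.exp(tab["estimate"] - crit * tab["se"])
        tab["or_hi"] = np.exp(tab["estimate"] + crit * tab["se"])
        per_model[name] = tab
    return {"models": per_model, "headline": _headline(per_model, spec)}


def _t_crit(dof):
    from scipy import stats

    return [stats.t.ppf(0.975, d) if np.isfinite(d) else 1.959964 for d in dof]


def per_snp_scan(
    table: pd.DataFrame,
    snp_cols: list[str],
    outcome: str = "ar_days",
) -> pd.DataFrame:
    """Single-SNP co-dominant regressions of AR age on dosage (0/1/2).

    Complete cases per SNP; beta is the change in days of AR per additional
    risk allele.  Monomorphic SNPs are flagged not-testable.  No
    multiplicity adjustment (each test is reported at its nominal p).
    """
    rows = []
    for snp in snp_cols:
        sub = table[[outcome, snp]].dropna()
        g = sub[snp].to_numpy(dtype=float)
        if len(sub) < 3 or np.unique(g).size < 2:
            rows.append((snp, len(sub), np.nan, np.nan, np.nan, False))
            continue
        X = sm.add_constant(g)
        res = sm.OLS(sub[outcome].to_numpy(dtype=float), X).fit()
        rows.append((snp, len(sub), res.params[1], res.bse[1], res.pvalues[1], True))
    return pd.DataFrame(
        rows, columns=["snp_id", "n", "beta_days_per_allele", "se", "p", "testable"]
    )


def adjusted_means_by_category(
    datasets: list[pd.DataFrame],
    category_col: str = "size_class",
    category_linked: tuple[str, ...] = ("bw_z", "bw_z_sq"),
    spec: HierSpec | None = None,
    outcome: str = "ar_days",
    columns: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Model-D adjusted mean AR per size-for-gestational-age class.

    Marginal prediction per class: covariates at their analysis-sample
    means, except the category-linked covariates (the birth-weight z terms,
    or class indicator columns) which take their within-class means.  SEs
    come from the delta method (x' V x); estimates and pairwise class
    contrasts are pooled over imputations with Rubin's rules.
    """
    if columns is None:
        if spec is None:
            spec = default_hier_spec()
        columns = nested_columns(spec)[MODEL_NAMES[len(spec.levels) - 1]]
    classes = sorted(pd.unique(datasets[0][category_col].dropna()))
    if not classes:
        raise ValueError("no category levels present")
    mean_q = {c: [] for c in classes}
    mean_u = {c: [] for c in classes}
    pairs = [(a, b) for i, a in enumerate(classes) for b in classes[i + 1:]]
    con_q = {p: [] for p in pairs}
    con_u = {p: [] for p in pairs}
    n_used = None
    for df in datasets:
        sub = df[[outcome, category_col] + columns].dropna()
        n_used = len(sub)
        y = sub[outcome].to_numpy(dtype=float)
        X = sm.add_constant(sub[columns].to_numpy(dtype=float), has_constant="add")
        res = sm.OLS(y, X).fit()
        V = np.asarray(res.cov_params())
        overall = sub[columns].mean()
        xrow = {}
        for cls in classes:
            in_cls = sub[category_col] == cls
            if not in_cls.any():
                raise ValueError(f"empty category {cls!r}")
            x = overall.copy()
            for col in category_linked:
                if col in x.index:
                    x[col] = sub.loc[in_cls, col].mean()
            xv = np.concatenate([[1.0], x.to_numpy(dtype=float)])
            xrow[cls] = xv
            mean_q[cls].append(float(xv @ res.params))
            mean_u[cls].append(float(xv @ V @ xv))
        for a, b in pairs:
            d = xrow[a] - xrow[b]
            con_q[(a, b)].append(float(d @ res.params))
            con_u[(a, b)].append(float(d @ V @ d))
    def _pool(qd, ud, labels):
        q = np.column_stack([qd[k] for k in labels])
        u = np.column_stack([ud[k] for k in labels])
        if q.shape[0] == 1:  # single dataset: no between-imputation variance
            return pd.DataFrame(
                {"estimate": q[0], "se": np.sqrt(u[0]),
                 "W": u[0], "B": 0.0, "T": u[0]}
            )
        return rubin_pool(q, u, df_com=(n_used - len(columns) - 1))

    means = _pool(mean_q, mean_u, classes)
    means.insert(0, "category", classes)
    contrasts = _pool(con_q, con_u, pairs)
    contrasts.insert(0, "contrast", [f"{a}-{b}" for a, b in pairs])
    return means, contrasts


def plot_adjusted_means(means: pd.DataFrame, path: str, title: str | None = None):
    """Point-and-error-bar figure of adjusted mean AR by category."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from ._constants import DAYS_PER_YEAR

    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    x = np.arange(len(means))
    y = means["estimate"].to_numpy() / DAYS_PER_YEAR
    err = means["se"].to_numpy() / DAYS_PER_YEAR
    ax.errorbar(x, y, yerr=err, fmt="o", capsize=4)
    ax.set_xticks(x)
    ax.set_xticklabels(means["category"])
    ax.set_ylabel("Adjusted mean age at AR (years)")
    ax.set_xlabel("Birth-weight category")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
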