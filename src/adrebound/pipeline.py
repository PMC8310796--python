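"""End-to-end orchestration: simulate -> filter -> fit -> AR -> score ->
impute -> associate, with cohort descriptives and a run manifest.

Every intermediate artifact is written as plain CSV/JSON so each stage can
be inspected or re-run independently; the manifest records seeds, stage row
counts (input children -> eligible -> AR estimated -> with scores) and any
model warnings, and two runs with the same config are numerically
identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import genetics, growthmodel, hierassoc, mimpute, perinatal, rebound, simcohort

__all__ = ["RunConfig", "describe_cohort", "run_all"]

log = logging.getLogger("adrebound")


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    out_dir: str = "results"
    seed: int = 0
    n_children: int = 1000
    #: optional external inputs; when None the cohort is simulated
    anthro_csv: str | None = None
    covariates_csv: str | None = None
    genotypes_csv: str | None = None
    m_imputations: int = 40
    imputation_iters: int = 10
    use_weighted_score: bool = False
    exclude_preterm: bool = False
    complete_case: bool = False
    min_children_per_sex: int = 30
    sim: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        allowed = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - allowed
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def describe_cohort(
    table: pd.DataFrame,
    group_col: str,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Descriptive comparison across groups, Table-1 style.

    Continuous variables: mean (SD) per group and a two-sample Student t
    test; binary/categorical: % (N) and a chi-square test without
    continuity correction.  Constant variables are skipped with a logged
    reason.  The grouping variable must have >= 2 non-empty groups.
    """
    groups = [g for g, sub in table.groupby(group_col, dropna=True)]
    if len(groups) < 2:
        raise ValueError("grouping variable must define at least two groups")
    if variables is None:
        variables = [
            c for c in table.columns
            if c != group_col and pd.api.types.is_numeric_dtype(table[c])
        ]
    rows = []
    for var in variables:
        sub = table[[group_col, var]].dropna()
        per_group = {g: d[var].to_numpy(dtype=float)
                     for g, d in sub.groupby(group_col)}
        if any(len(v) == 0 for v in per_group.values()):
            raise ValueError(f"group with n = 0 for {var}")
        allvals = sub[var].to_numpy(dtype=float)
        uniq = np.unique(allvals)
        if uniq.size < 2:
            rows.append((var, "skipped", *["" for _ in groups], np.nan,
                         "constant variable"))
            continue
        binary = set(uniq) <= {0.0, 1.0}
        if binary:
            obs = pd.crosstab(sub[group_col], sub[var])
            stat, p, _, _ = stats.chi2_contingency(obs.to_numpy(), correction=False)
            cells = [
                f"{100 * per_group[g].mean():.1f} ({int(per_group[g].sum())})"
                for g in groups
            ]
            rows.append((var, "chi2", *cells, p, ""))
        else:
            a, b = (per_group[g] for g in groups[:2])
            stat, p = stats.ttest_ind(a, b, equal_var=True)
            cells = [
                f"{per_group[g].mean():.2f} ({per_group[g].std(ddof=1):.2f})"
                for g in groups
            ]
            rows.append((var, "t", *cells, p, ""))
    cols = ["variable", "test", *[f"group_{g}" for g in groups], "p", "note"]
    return pd.DataFrame(rows, columns=cols)


def _results_hash(tables: dict[str, pd.DataFrame]) -> str:
    h = hashlib.sha256()
    for name in sorted(tables):
        h.update(name.encode())
        h.update(tables[name].round(10).to_csv(index=False).encode())
    return h.hexdigest()


def _assemble_analysis_table(
    covariates: pd.DataFrame,
    scores: pd.DataFrame,
    ar_table: pd.DataFrame,
    use_weighted: bool,
) -> pd.DataFrame:
    cov = perinatal.derive_covariates(covariates)
    cov["sex_female"] = (cov["sex"] == "female").astype(float)
    score_col = "weighted_score" if use_weighted else "risk_score"
    cov = cov.merge(
        scores[["child_id", score_col]].rename(columns={score_col: "risk_score"}),
        on="child_id", how="left",
    )
    cov = cov.merge(
        ar_table[ar_table.status == "estimated"][
            ["child_id", "ar_age_days", "ar_age_years"]
        ],
        on="child_id", how="inner",
    )
    return cov.rename(columns={"ar_age_days": "ar_days", "ar_age_years": "ar_years"})


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest (also written to
    ``out_dir/manifest.json``)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)
    fh = logging.FileHandler(out / "run.log")
    log.addHandler(fh)
    manifest: dict = {"seed": config.seed, "stages": {}, "warnings": []}
    try:
        # -- stage 1: inputs ------------------------------------------------
        if config.anthro_csv is None:
            sim_cfg = simcohort.SimConfig(
                n_children=config.n_children, seed=config.seed, **config.sim
            )
            anthro, covariates, genotypes, truth = simcohort.generate_cohort(sim_cfg)
            truth.to_csv(out / "truth.csv", index=False)
            manifest["stages"]["simulate"] = {"n_children": config.n_children}
        else:
            anthro = pd.read_csv(config.anthro_csv)
            covariates = pd.read_csv(config.covariates_csv)
            genotypes = pd.read_csv(config.genotypes_csv, sep=None, engine="python")
            truth = None
            manifest["stages"]["load"] = {
                "n_children": int(covariates["child_id"].nunique())
            }
        n_input = int(covariates["child_id"].nunique())

        # -- stage 2: eligibility and growth model --------------------------
        eligible, exclusions = growthmodel.eligibility_filter(anthro)
        manifest["stages"]["eligibility"] = {
            "input_children": int(anthro["child_id"].nunique()),
            "eligible": len(eligible),
            "excluded": int(len(exclusions)),
        }
        exclusions.to_csv(out / "exclusions.csv", index=False)
        records = anthro[anthro["child_id"].isin(eligible)]
        curves_parts, fit_summaries = [], {}
        for sex in ("male", "female"):
            fit = growthmodel.fit_cubic_mixed(
                records, sex=sex, min_children=config.min_children_per_sex
            )
            fit_summaries[sex] = fit.summary_dict()
            curves_parts.append(growthmodel.predict_curves(fit))
            manifest["warnings"].extend(
                f"growthmodel[{sex}]: {w}" for w in fit.warnings_log
            )
        curves = pd.concat(curves_parts, ignore_index=True)
        curves.to_csv(out / "curves.csv", index=False)
        with open(out / "growth_fits.json", "w") as f:
            json.dump(fit_summaries, f, indent=2)

        # -- stage 3: AR ----------------------------------------------------
        ar_table, counts = rebound.ar_for_cohort(curves, exclusions)
        ar_table.to_csv(out / "ar.csv", index=False)
        manifest["stages"]["ar"] = counts

        # -- stage 4: scores ------------------------------------------------
        passing, qc_report = genetics.qc_filter(genotypes)
        qc_report.to_csv(out / "genotype_qc.csv", index=False)
        panel = genetics.default_panel()
        panel = panel[panel.snp_id.isin(passing)].reset_index(drop=True)
        scores = genetics.cohort_scores(genotypes, panel)
        scores.to_csv(out / "scores.csv", index=False)
        manifest["stages"]["scores"] = {
            "snps_passing_qc": len(passing),
            "children_with_scores": int(scores["complete"].sum()),
        }

        # -- stage 5: analysis table + early AR -----------------------------
        analysis = _assemble_analysis_table(
            covariates, scores, ar_table, config.use_weighted_score
        )
        spec = hierassoc.default_hier_spec()
        if config.exclude_preterm:
            n_pre = int((analysis["preterm"] == 1).sum())
            analysis = analysis[analysis["preterm"] != 1]
            manifest["stages"]["exclude_preterm"] = {"dropped": n_pre}
            # preterm is constant in this sensitivity subset; drop the term
            spec = hierassoc.HierSpec(
                levels=tuple(
                    tuple(v for v in lvl if v != "preterm") for lvl in spec.levels
                )
            )
        threshold, early = hierassoc.early_ar_indicator(analysis["ar_years"])
        analysis = analysis.assign(early_ar=early)
        manifest["stages"]["analysis_sample"] = {
            "n": int(len(analysis)),
            "early_ar_threshold_years": threshold,
            "early_ar_fraction": float(early.mean()),
        }
        desc = describe_cohort(
            analysis.assign(early=early), "early",
            variables=["maternal_bmi", "paternal_bmi", "gwg_kg", "smoking",
                       "maternal_edu_years", "risk_score", "bw_z"],
        )
        desc.to_csv(out / "descriptives_by_early_ar.csv", index=False)

        # -- stage 6: imputation --------------------------------------------
        model_cols = [v for lvl in spec.levels for v in lvl]
        keep = (["child_id", "ar_days", "ar_years", "early_ar", "size_class",
                 "mother_score", "father_score"] + model_cols)
        imp_input = analysis[keep].copy()
        if config.complete_case:
            imp_input = imp_input.dropna(subset=model_cols)
            datasets = [imp_input.copy(), imp_input.copy()]
            report = {"mode": "complete_case", "n": int(len(imp_input))}
        else:
            plan = mimpute.ImputationPlan(
                m=config.m_imputations,
                n_iter=config.imputation_iters,
                seed=config.seed,
                # the squared term is recomputed passively from imputed bw_z
                predictors={},
            )
            no_sq = imp_input.drop(columns=["bw_z_sq"])
            datasets, report = mimpute.fcs_impute(no_sq, plan)
            for d in datasets:
                d["bw_z_sq"] = d["bw_z"] ** 2
                d["size_class"] = perinatal.classify_size(d["bw_z"])
        imp_dir = out / "imputations"
        imp_dir.mkdir(exist_ok=True)
        for i, d in enumerate(datasets[: min(3, len(datasets))]):
            d.to_csv(imp_dir / f"imputed_{i}.csv", index=False)
        with open(out / "imputation_report.json", "w") as f:
            json.dump(report, f, indent=2)
        manifest["stages"]["imputation"] = {"m": len(datasets)}

        # -- stage 7: association -------------------------------------------
        linear = hierassoc.fit_hier_linear(datasets, spec=spec)
        logistic = hierassoc.fit_hier_logistic(datasets, spec=spec)
        tidy = []
        for kind, result in (("linear", linear), ("logistic", logistic)):
            for mname, tab in result["models"].items():
                t = tab.assign(model=mname, family=kind)
                tidy.append(t)
            result["headline"].assign(family=kind).to_csv(
                out / f"headline_{kind}.csv", index=False
            )
        pd.concat(tidy, ignore_index=True).to_csv(out / "models_tidy.csv", index=False)

        snp_cols = [c for c in genotypes.columns if c.startswith("rs")]
        cc = analysis.dropna(subset=model_cols)
        snp_table = cc.merge(genotypes, on="child_id", how="left")
        scan = hierassoc.per_snp_scan(snp_table, snp_cols)
        scan.to_csv(out / "per_snp.csv", index=False)

        means, contrasts = hierassoc.adjusted_means_by_category(datasets, spec=spec)
        means.to_csv(out / "adjusted_means.csv", index=False)
        contrasts.to_csv(out / "adjusted_contrasts.csv", index=False)
        hierassoc.plot_adjusted_means(means, str(out / "adjusted_means.png"))

        # -- manifest --------------------------------------------------------
        flow = {
            "input_children": n_input,
            "eligible": manifest["stages"]["eligibility"]["eligible"],
            "excluded_eligibility": manifest["stages"]["eligibility"]["excluded"],
            "ar_estimated": counts["estimated"],
            "no_rebound": counts["no_rebound"],
            "insufficient_data": counts["insufficient_data"],
            "analysis_n": manifest["stages"]["analysis_sample"]["n"],
        }
        manifest["flow"] = flow
        manifest["results_hash"] = _results_hash(
            {
                "ar": ar_table.fillna(-1), "curves": curves,
                "headline_linear": linear["headline"].select_dtypes("number").reset_index(drop=True),
                "means": means.drop(columns=["category"]),
            }
        )
        manifest["headline_linear"] = {
            r["term"]: {"estimate": r["estimate"], "se": r["se"], "p": r["p"]}
            for _, r in linear["headline"].iterrows()
        }
        manifest["config"] = asdict(config)
        with open(out / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=2, default=str)
        return manifest
    except Exception as err:  # surface the failing stage, never continue silently
        stage = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed after stage '{stage}': {err}") from err
    finally:
        log.removeHandler(fh)
        fh.close()
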