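"""Genotype quality control and obesity risk-allele scores.

A risk-allele score sums, over a panel of biallelic SNPs associated with
adult BMI, the number of BMI-increasing alleles carried (0, 1 or 2 per
locus, co-dominant/additive coding).  The weighted variant multiplies each
allele count by the SNP's per-allele effect on adult BMI from the source
GWAS.  QC follows the usual genotyping thresholds: per-SNP call rate
> 0.95 and Hardy-Weinberg equilibrium p > 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SNPDef",
    "default_panel",
    "hwe_test",
    "panel_stats",
    "qc_filter",
    "unweighted_score",
    "weighted_score",
    "cohort_scores",
]


@dataclass(frozen=True)
class SNPDef:
    """One panel SNP: identifier, risk (BMI-increasing) allele, per-allele
    effect weight on adult BMI (kg/m^2), and population risk-allele
    frequency (used for simulation and QC expectations)."""

    snp_id: str
    risk_allele: str
    weight: float
    freq: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.weight):
            raise ValueError(f"{self.snp_id}: non-finite weight")
        if not 0.0 < self.freq < 1.0:
            raise ValueError(f"{self.snp_id}: frequency must be in (0, 1)")


# 27 loci reported in adult-BMI GWAS.  The weights and frequencies below are
# ILLUSTRATIVE (plausible magnitudes, not the published per-SNP estimates) and
# NON-CANONICAL: the exact 27-locus panel membership and effect sizes are
# configurable and should be replaced with the user's own panel definition for
# real analyses.  Frequencies average ~0.40 so the unweighted score is centred
# near 21.6 of a 0-54 range.
_DEFAULT_PANEL_ROWS = [
    ("rs1421085", "C", 0.39, 0.42),    # FTO
    ("rs2867125", "C", 0.31, 0.83),    # TMEM18
    ("rs571312", "A", 0.23, 0.24),     # MC4R
    ("rs10938397", "G", 0.18, 0.43),   # GNPDA2
    ("rs10767664", "A", 0.19, 0.78),   # BDNF
    ("rs2815752", "A", 0.13, 0.61),    # NEGR1
    ("rs7359397", "T", 0.15, 0.40),    # SH2B1
    ("rs9816226", "T", 0.14, 0.82),    # ETV5
    ("rs3817334", "T", 0.06, 0.41),    # MTCH2
    ("rs29941", "G", 0.06, 0.67),      # KCTD15
    ("rs10913469", "C", 0.22, 0.20),   # SEC16B
    ("rs987237", "G", 0.13, 0.18),     # TFAP2B
    ("rs7138803", "A", 0.12, 0.38),    # FAIM2
    ("rs10150332", "C", 0.13, 0.21),   # NRXN3
    ("rs713586", "C", 0.14, 0.47),     # RBJ/POMC
    ("rs12444979", "C", 0.17, 0.87),   # GPRC5B
    ("rs2241423", "G", 0.13, 0.78),    # MAP2K5
    ("rs2287019", "C", 0.15, 0.80),    # QPCTL
    ("rs1514175", "A", 0.07, 0.43),    # TNNI3K
    ("rs13107325", "T", 0.19, 0.07),   # SLC39A8
    ("rs2112347", "T", 0.10, 0.63),    # FLJ35779
    ("rs10968576", "G", 0.11, 0.31),   # LRRN6C
    ("rs3810291", "A", 0.09, 0.67),    # TMEM160
    ("rs887912", "T", 0.10, 0.29),     # FANCL
    ("rs13078807", "G", 0.10, 0.20),   # CADM2
    ("rs1555543", "C", 0.06, 0.59),    # PTBP2
    ("rs4836133", "A", 0.08, 0.48),    # ZNF608
]


def default_panel() -> pd.DataFrame:
    """Return the 27-SNP default panel as a DataFrame.

    Columns: ``snp_id``, ``risk_allele``, ``weight``, ``freq``.  Weights and
    frequencies are illustrative placeholders (see module notes); the panel
    is meant to be replaced via the ``panel`` argument of the scoring
    functions or the CLI ``--panel`` CSV.
    """
    df = pd.DataFrame(
        _DEFAULT_PANEL_ROWS, columns=["snp_id", "risk_allele", "weight", "freq"]
    )
    assert len(df) == 27
    return df


def hwe_test(n_hom_risk: int, n_het: int, n_hom_other: int) -> tuple[float, float]:
    """Chi-square goodness-of-fit test against Hardy-Weinberg proportions.

    Expected genotype counts are ``n * (p^2, 2pq, q^2)`` with ``p`` the
    observed risk-allele frequency.  Returns ``(chi2, p_value)`` on 1 df.
    Monomorphic SNPs (p = 0 or 1) fit HWE exactly: statistic 0, p-value 1.
    """
    counts = np.asarray([n_hom_risk, n_het, n_hom_other], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n < 1:
        raise ValueError("at least one genotyped individual required")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    q = 1.0 - p
    expected = n * np.array([p * p, 2 * p * q, q * q])
    mask = expected > 0
    chi2 = float(np.sum((counts[mask] - expected[mask]) ** 2 / expected[mask]))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def panel_stats(genotypes: pd.DataFrame, snp_cols: list[str] | None = None) -> pd.DataFrame:
    """Per-SNP call rate, genotype counts, and HWE p-value.

    ``genotypes`` holds dosages in {0, 1, 2, NaN}, one row per child, one
    column per SNP (non-SNP columns such as ``child_id`` are ignored when
    ``snp_cols`` is None and they are not numeric dosage columns).
    """
    if snp_cols is None:
        snp_cols = [c for c in genotypes.columns if c.startswith("rs")]
    if not snp_cols:
        raise ValueError("empty genotype panel")
    # call rate is an assay property: children never genotyped (all SNPs
    # missing) are not in the batch and do not count against it
    assayed = genotypes.loc[genotypes[snp_cols].notna().any(axis=1)]
    rows = []
    for snp in snp_cols:
        g = assayed[snp]
        valid = g.dropna()
        bad = ~valid.isin([0, 1, 2])
        if bad.any():
            raise ValueError(f"{snp}: dosages outside {{0,1,2}}")
        call_rate = len(valid) / len(g) if len(g) else 0.0
        counts = [(valid == 2).sum(), (valid == 1).sum(), (valid == 0).sum()]
        if len(valid):
            chi2, p = hwe_test(*counts)
        else:
            chi2, p = np.nan, np.nan
        rows.append((snp, call_rate, *counts, chi2, p))
    return pd.DataFrame(
        rows,
        columns=["snp_id", "call_rate", "n_hom_risk", "n_het", "n_hom_other",
                 "hwe_chi2", "hwe_p"],
    )


def qc_filter(
    genotypes: pd.DataFrame,
    snp_cols: list[str] | None = None,
    call_rate_min: float = 0.95,
    hwe_alpha: float = 0.01,
) -> tuple[list[str], pd.DataFrame]:
    """Apply the genotyping QC thresholds.

    A SNP passes iff call rate > ``call_rate_min`` AND HWE p > ``hwe_alpha``
    (both strict, matching the "> 95%" / "p > 0.01" criteria).  Returns the
    passing SNP list and a report with a failure reason per SNP.
    """
    report = panel_stats(genotypes, snp_cols)
    reasons = []
    for _, row in report.iterrows():
        why = []
        if not row.call_rate > call_rate_min:
            why.append(f"call_rate {row.call_rate:.3f} <= {call_rate_min}")
        if not row.hwe_p > hwe_alpha:
            why.append(f"hwe_p {row.hwe_p:.3g} <= {hwe_alpha}")
        reasons.append("; ".join(why) if why else "pass")
    report = report.assign(status=reasons)
    passing = report.loc[report.status == "pass", "snp_id"].tolist()
    return passing, report


def _check_dosages(dosages: np.ndarray) -> None:
    valid = dosages[~np.isnan(dosages)]
    if valid.size and not np.isin(valid, [0.0, 1.0, 2.0]).all():
        raise ValueError("dosages must be in {0, 1, 2} or missing")


def unweighted_score(dosages) -> float:
    """Sum of risk alleles over the panel; NaN if any SNP is missing.

    Missing scores are not prorated (that would change the score's scale);
    they are recovered later by multiple imputation using parental scores.
    """
    d = np.asarray(dosages, dtype=float)
    _check_dosages(d)
    if np.isnan(d).any():
        return float("nan")
    return float(d.sum())


def weighted_score(dosages, weights) -> float:
    """Dot product of risk-allele dosages with per-SNP GWAS effect weights."""
    d = np.asarray(dosages, dtype=float)
    w = np.asarray(weights, dtype=float)
    if d.shape != w.shape:
        raise ValueError("weights misaligned with dosage vector")
    _check_dosages(d)
    if np.isnan(d).any():
        return float("nan")
    return float(d @ w)


def cohort_scores(
    genotypes: pd.DataFrame,
    panel: pd.DataFrame | None = None,
    id_col: str = "child_id",
) -> pd.DataFrame:
    """Unweighted and weighted risk-allele scores for every child.

    ``genotypes`` columns must include ``id_col`` and one dosage column per
    panel SNP, oriented to the risk allele.  Children missing any SNP get
    NaN scores and ``complete = False``.
    """
    if panel is None:
        panel = default_panel()
    if panel.empty:
        raise ValueError("empty SNP panel")
    snps = panel["snp_id"].tolist()
    missing_cols = [s for s in snps if s not in genotypes.columns]
    if missing_cols:
        raise ValueError(f"genotype table lacks panel SNPs: {missing_cols[:5]}...")
    dos = genotypes[snps].to_numpy(dtype=float)
    _check_dosages(dos)
    complete = ~np.isnan(dos).any(axis=1)
    uw = np.where(complete, np.nansum(dos, axis=1), np.nan)
    ww = np.where(complete, np.nansum(dos * panel["weight"].to_numpy(), axis=1), np.nan)
    return pd.DataFrame(
        {
            id_col: genotypes[id_col].to_numpy(),
            "risk_score": uw,
            "weighted_score": ww,
            "complete": complete,
        }
    )
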