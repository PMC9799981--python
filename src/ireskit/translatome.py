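"""Polysome PCR-array analysis by relative quantification (2^-ΔΔCT).

Input is a long-format Ct table (gene, gene class, RNA fraction, treatment,
biological and technical replicate, Ct).  Technical replicates are averaged
in Ct space; ΔCt normalizes each gene to a reference gene (default Gapdh)
within a sample; ΔΔCt compares treatment to a calibrator treatment (default
the control gapmer); RQ = 2^-ΔΔCt.  Polysome recruitment is either the
polysomal-fraction RQ alone or the ratio RQ_polysomal / RQ_total.  Fold
change follows the signed convention: RQ if RQ ≥ 1, else −1/RQ.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CT_COLUMNS = ["gene", "gene_class", "fraction", "treatment", "bio_rep", "tech_rep", "ct"]

GENE_CLASSES = ("IRES", "ITAF", "other")
FRACTIONS = ("total", "polysomal")

#: recruitment metrics
POLYSOMAL_ONLY = "polysomal_only"
POLYSOMAL_OVER_TOTAL = "polysomal_over_total"


def _validate_ct(ct: pd.DataFrame, reference_gene: str) -> None:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns: {missing}")
    if reference_gene not in set(ct["gene"]):
        raise ValueError(f"reference gene {reference_gene!r} absent from Ct table")


def delta_delta_ct(
    ct: pd.DataFrame,
    reference_gene: str = "Gapdh",
    calibrator_treatment: str = "control",
    fraction: str | None = None,
) -> pd.DataFrame:
    """Per-gene relative quantification RQ = 2^-ΔΔCt.

    Technical replicates are averaged in Ct space; ΔCt = Ct(gene) − Ct(ref)
    per (treatment, biological replicate); ΔΔCt = mean_bio ΔCt(treatment) −
    mean_bio ΔCt(calibrator), so the calibrator's RQ is exactly 1.
    Undetermined Ct (NaN) in all replicates of a cell flags the gene
    not-quantified for that treatment (RQ = NaN, logged).

    Returns a DataFrame with columns gene, gene_class, treatment, rq, ddct,
    n_bio.
    """
    _validate_ct(ct, reference_gene)
    sub = ct if fraction is None else ct[ct["fraction"] == fraction]
    if sub.empty:
        raise ValueError(f"no rows for fraction {fraction!r}")
    # average technical replicates in Ct space
    tech = (
        sub.groupby(["gene", "gene_class", "treatment", "bio_rep"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    ref = tech[tech["gene"] == reference_gene].set_index(["treatment", "bio_rep"])["ct"]
    tech = tech.set_index(["treatment", "bio_rep"])
    tech["dct"] = tech["ct"] - ref
    tech = tech.reset_index()

    dct = tech.groupby(["gene", "gene_class", "treatment"], sort=False)["dct"].agg(
        ["mean", "count"]
    )
    dct = dct.rename(columns={"mean": "dct", "count": "n_bio"}).reset_index()
    cal = dct[dct["treatment"] == calibrator_treatment].set_index("gene")["dct"]
    if cal.empty:
        raise ValueError(f"calibrator treatment {calibrator_treatment!r} absent")
    dct["ddct"] = dct["dct"] - dct["gene"].map(cal).to_numpy()
    # snap rounding jitter so a truly unchanged gene sits at RQ exactly 1
    dct.loc[dct["ddct"].abs() < 1e-9, "ddct"] = 0.0
    dct["rq"] = 2.0 ** (-dct["ddct"])
    n_dropped = int(dct["rq"].isna().sum())
    if n_dropped:
        logger.info("%d gene × treatment cells not quantified (undetermined Ct)", n_dropped)
    return dct[["gene", "gene_class", "treatment", "rq", "ddct", "n_bio"]]


def signed_fold_change(rq):
    """Signed fold-change convention: RQ when RQ ≥ 1, −1/RQ when RQ < 1.

    Accepts scalars or arrays; |result| ≥ 1 and f(RQ) = −f(1/RQ) for RQ ≠ 1.
    """
    rq = np.asarray(rq, dtype=float)
    if (rq[~np.isnan(rq)] <= 0).any():
        raise ValueError("RQ must be positive")
    out = np.where(rq >= 1, rq, -1.0 / rq)
    return float(out) if out.ndim == 0 else out


def recruitment(
    ct: pd.DataFrame,
    metric: str = POLYSOMAL_OVER_TOTAL,
    reference_gene: str = "Gapdh",
    calibrator_treatment: str = "control",
) -> pd.DataFrame:
    """Polysomal-recruitment RQ per gene × treatment.

    ``polysomal_over_total``: RQ computed within each RNA fraction, then
    recruitment RQ = RQ_polysomal / RQ_total.  ``polysomal_only``: the
    polysomal-fraction RQ alone.  The metric used is recorded in the output.

    Returns gene, gene_class, treatment, rq, log2_rq, fold_change (signed),
    metric.
    """
    if metric not in (POLYSOMAL_ONLY, POLYSOMAL_OVER_TOTAL):
        raise ValueError(f"unknown metric {metric!r}")
    fractions = set(ct["fraction"])
    need = {"polysomal"} if metric == POLYSOMAL_ONLY else {"polysomal", "total"}
    if not need <= fractions:
        raise ValueError(f"metric {metric!r} requires fractions {sorted(need)}, have {sorted(fractions)}")

    poly = delta_delta_ct(ct, reference_gene, calibrator_treatment, fraction="polysomal")
    if metric == POLYSOMAL_ONLY:
        out = poly.rename(columns={"rq": "rq"})[["gene", "gene_class", "treatment", "rq"]]
    else:
        total = delta_delta_ct(ct, reference_gene, calibrator_treatment, fraction="total")
        merged = poly.merge(
            total, on=["gene", "gene_class", "treatment"], suffixes=("_poly", "_total")
        )
        merged["rq"] = merged["rq_poly"] / merged["rq_total"]
        merged.loc[(merged["rq"] - 1).abs() < 1e-9, "rq"] = 1.0
        out = merged[["gene", "gene_class", "treatment", "rq"]]
    out = out.copy()
    out["log2_rq"] = np.log2(out["rq"])
    valid = out["rq"].notna()
    out["fold_change"] = np.nan
    out.loc[valid, "fold_change"] = signed_fold_change(out.loc[valid, "rq"])
    out["metric"] = metric
    return out


def summarize_classes(results: pd.DataFrame, dead_band: float = 0.0) -> pd.DataFrame:
    """Per gene-class and treatment: percent of genes with decreased
    (RQ < 1 − dead_band) vs increased (RQ > 1 + dead_band) recruitment.

    The reference gene and non-quantified genes (RQ = NaN) are excluded.
    Percentages are reported rounded to integer percent alongside exact
    fractions; the default dead band is 0 (RQ = 1 counts unchanged).
    """
    unknown = set(results["gene_class"]) - set(GENE_CLASSES)
    if unknown:
        raise ValueError(f"unknown gene_class labels: {sorted(unknown)}")
    res = results[results["rq"].notna()]
    rows = []
    grouped = res.groupby(["gene_class", "treatment"], sort=False)
    for (cls, treatment), grp in grouped:
        rows.append(_summary_row(cls, treatment, grp["rq"], dead_band))
    for treatment, grp in res.groupby("treatment", sort=False):
        rows.append(_summary_row("all", treatment, grp["rq"], dead_band))
    return pd.DataFrame(rows)


def _summary_row(cls: str, treatment: str, rq: pd.Series, dead_band: float) -> dict:
    n = len(rq)
    dec = float((rq < 1 - dead_band).mean()) if n else np.nan
    inc = float((rq > 1 + dead_band).mean()) if n else np.nan
    unch = 1.0 - dec - inc if n else np.nan
    return {
        "gene_class": cls,
        "treatment": treatment,
        "n_genes": n,
        "frac_decreased": dec,
        "frac_increased": inc,
        "frac_unchanged": unch,
        "pct_decreased": int(round(100 * dec)) if n else np.nan,
        "pct_increased": int(round(100 * inc)) if n else np.nan,
    }


def heatmap_matrix(results: pd.DataFrame) -> pd.DataFrame:
    """Gene × treatment matrix of signed fold changes (repression negative,
    induction positive), ready for heatmap display."""
    return results.pivot(index="gene", columns="treatment", values="fold_change")
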