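"""Label-free AP-MS differential-interactome statistics.

Pipeline (order is fixed and enforced):

    aggregate peptides -> median normalization -> 5%-quantile imputation
    -> log2 -> average technical replicates -> pooled-variance t-test
    -> confidence filters

Protein intensity per run is the sum of its unique-peptide intensities.
Each run is rescaled so its median (over observed values) equals the median
of run medians; missing values are replaced per run by the run's 5% quantile
of observed intensities; the test is an unpaired two-tailed Student t-test
with pooled (equal) variance on log2, technically-averaged data.  A protein
is *enriched* when |log2FC| > 1 and p < 0.05, and survives the confidence
filters when additionally its total averaged PSM count exceeds 4 and it was
quantified before imputation in ≥ 2 biological replicates of at least one
compared group.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ["condition", "compartment", "bio_rep", "tech_rep"]

#: pipeline stages in mandatory order
_STAGES = ["raw", "normalized", "imputed", "log2", "averaged"]

#: floor used when a pooled-variance t statistic is infinite (zero variance)
P_FLOOR = 1e-300


@dataclass
class LfqMatrix:
    """Protein × run intensity matrix with explicit missing values (NaN).

    ``intensities``: DataFrame, index = protein ids, columns = run ids.
    ``annotation``: DataFrame indexed by run id with columns
    ``condition, compartment, bio_rep, tech_rep`` (``tech_rep`` absent after
    technical averaging).
    ``psm``: per-protein per-run PSM counts (same shape as intensities).
    ``observed``: boolean pre-imputation observation mask, kept through the
    pipeline so the confidence filters can look behind the imputation.
    """

    intensities: pd.DataFrame
    annotation: pd.DataFrame
    psm: pd.DataFrame | None = None
    observed: pd.DataFrame | None = None
    stage: str = "raw"

    def __post_init__(self) -> None:
        missing_runs = [c for c in self.intensities.columns if c not in self.annotation.index]
        if missing_runs:
            raise ValueError(f"runs without annotation: {missing_runs}")
        if (self.intensities <= 0).any().any() and self.stage in ("raw", "normalized", "imputed"):
            raise ValueError("intensities must be positive where present (missing = NaN, never 0)")
        if self.observed is None:
            self.observed = self.intensities.notna()

    def _expect_stage(self, expected: str, op: str) -> None:
        if self.stage != expected:
            raise ValueError(
                f"{op} expects a {expected!r} matrix but got {self.stage!r}; "
                f"pipeline order is {' -> '.join(_STAGES)}"
            )

    def groups(self) -> pd.Series:
        """(condition, compartment) per run."""
        return self.annotation.apply(lambda r: (r["condition"], r["compartment"]), axis=1)


@dataclass(frozen=True)
class ComparisonSpec:
    """A pairwise comparison between two (condition, compartment) groups."""

    name: str
    group1: tuple[str, str]
    group2: tuple[str, str]

    def __post_init__(self) -> None:
        if self.group1 == self.group2:
            raise ValueError("group1 and group2 must differ")


#: the four canonical pairwise comparisons of the nucleus/cytoplasm ×
#: normoxia/hypoxia AP-MS design
CANONICAL_COMPARISONS = [
    ComparisonSpec("nucleus_hypoxia_vs_normoxia", ("hypoxia", "nucleus"), ("normoxia", "nucleus")),
    ComparisonSpec(
        "cytoplasm_hypoxia_vs_normoxia", ("hypoxia", "cytoplasm"), ("normoxia", "cytoplasm")
    ),
    ComparisonSpec("normoxia_nucleus_vs_cytoplasm", ("normoxia", "nucleus"), ("normoxia", "cytoplasm")),
    ComparisonSpec("hypoxia_nucleus_vs_cytoplasm", ("hypoxia", "nucleus"), ("hypoxia", "cytoplasm")),
]


def aggregate_peptides(
    peptides: pd.DataFrame,
    annotation: pd.DataFrame,
    psm: pd.DataFrame | None = None,
    protein_col: str = "protein",
    peptide_col: str = "peptide",
) -> LfqMatrix:
    """Sum unique-peptide intensities into protein intensities per run.

    ``peptides`` is wide: one row per peptide, a ``protein`` column (multiple
    accessions separated by ``;`` mark a shared peptide) and one intensity
    column per run.  Shared peptides contribute to no protein and are dropped
    with a logged count.
    """
    shared = peptides[protein_col].astype(str).str.contains(";")
    if shared.any():
        logger.info("dropping %d shared peptides (mapped to >1 protein)", int(shared.sum()))
    unique = peptides.loc[~shared]
    runs = [c for c in peptides.columns if c not in (protein_col, peptide_col)]
    # sum skips NaN; all-NaN groups stay missing
    summed = unique.groupby(protein_col)[runs].sum(min_count=1)
    summed.index.name = "protein"
    return LfqMatrix(summed, annotation, psm=psm)


def normalize_median(matrix: LfqMatrix) -> LfqMatrix:
    """Rescale each run so all run medians equal the median of run medians."""
    matrix._expect_stage("raw", "normalize_median")
    medians = matrix.intensities.median(axis=0, skipna=True)
    if medians.isna().any():
        bad = medians.index[medians.isna()].tolist()
        raise ValueError(f"runs with no observed values: {bad}")
    reference = medians.median()
    scaled = matrix.intensities * (reference / medians)
    return replace(matrix, intensities=scaled, stage="normalized")


def impute_quantile(matrix: LfqMatrix, q: float = 0.05) -> LfqMatrix:
    """Replace missing values per run by that run's ``q`` quantile of
    observed intensities (linear interpolation between order statistics)."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if matrix.stage not in ("normalized", "imputed"):  # idempotent on imputed data
        matrix._expect_stage("normalized", "impute_quantile")
    filled = matrix.intensities.copy()
    fills = filled.quantile(q, axis=0, interpolation="linear")
    filled = filled.fillna(fills)
    return replace(matrix, intensities=filled, observed=matrix.observed, stage="imputed")


def log2_transform(matrix: LfqMatrix) -> LfqMatrix:
    matrix._expect_stage("imputed", "log2_transform")
    return replace(matrix, intensities=np.log2(matrix.intensities), stage="log2")


def average_technical(matrix: LfqMatrix) -> LfqMatrix:
    """Average technical replicates per biological sample, in log2 space.

    Sample ids become ``condition|compartment|bio_rep``.  PSM counts are
    averaged the same way (these are the "averaged PSM counts" used by the
    confidence filter) and the pre-imputation observation mask collapses to
    "observed in any technical replicate of the sample".
    """
    matrix._expect_stage("log2", "average_technical")
    ann = matrix.annotation.loc[matrix.intensities.columns]
    sample_of_run = ann["condition"] + "|" + ann["compartment"] + "|" + ann["bio_rep"].astype(str)
    dup = ann.assign(sample=sample_of_run).groupby("sample")[["condition", "compartment", "bio_rep"]].nunique()
    if (dup > 1).any().any():
        raise ValueError("technical replicates with inconsistent annotation")

    averaged = matrix.intensities.T.groupby(sample_of_run).mean().T
    observed = matrix.observed.T.groupby(sample_of_run).any().T
    psm = None
    if matrix.psm is not None:
        psm = matrix.psm.T.groupby(sample_of_run).mean().T
    new_ann = (
        ann.assign(sample=sample_of_run)
        .drop_duplicates("sample")
        .set_index("sample")[["condition", "compartment", "bio_rep"]]
    )
    return LfqMatrix(averaged, new_ann, psm=psm, observed=observed, stage="averaged")


def _group_columns(matrix: LfqMatrix, group: tuple[str, str]) -> list[str]:
    g = matrix.groups()
    cols = g.index[g == group].tolist()
    if not cols:
        raise ValueError(f"group {group} not present in annotation")
    return cols


def test_enrichment(
    matrix: LfqMatrix,
    spec: ComparisonSpec,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-protein differential test for one pairwise comparison.

    log2FC = mean(group1) − mean(group2); unpaired two-tailed Student t-test
    with pooled variance; ``enriched`` ⇔ |log2FC| > ``fc_threshold`` and
    p < ``p_threshold``.  A Benjamini–Hochberg column (``p_bh``) is provided
    for reference but never gates the flags.
    """
    matrix._expect_stage("averaged", "test_enrichment")
    cols1 = _group_columns(matrix, spec.group1)
    cols2 = _group_columns(matrix, spec.group2)
    x1 = matrix.intensities[cols1].to_numpy()
    x2 = matrix.intensities[cols2].to_numpy()

    log2fc = x1.mean(axis=1) - x2.mean(axis=1)
    untestable = min(len(cols1), len(cols2)) < 2
    if untestable:
        t = np.full(len(log2fc), np.nan)
        p = np.full(len(log2fc), np.nan)
    else:
        t, p = stats.ttest_ind(x1, x2, axis=1, equal_var=True)
        zero_var = ~np.isfinite(t)
        identical = zero_var & (log2fc == 0)
        with np.errstate(invalid="ignore"):
            t = np.where(identical, 0.0, t)
            p = np.where(identical, 1.0, p)
            p = np.where(zero_var & ~identical, P_FLOOR, p)
            t = np.where(zero_var & ~identical, np.sign(log2fc) * np.inf, t)

    n1 = matrix.observed[cols1].sum(axis=1) if matrix.observed is not None else np.nan
    n2 = matrix.observed[cols2].sum(axis=1) if matrix.observed is not None else np.nan
    psm_total = (
        matrix.psm[cols1 + cols2].sum(axis=1)
        if matrix.psm is not None
        else pd.Series(np.nan, index=matrix.intensities.index)
    )
    out = pd.DataFrame(
        {
            "comparison": spec.name,
            "log2fc": log2fc,
            "fc": 2.0 ** log2fc,
            "t": t,
            "p": p,
            "n_quant_group1": n1,
            "n_quant_group2": n2,
            "psm_total": psm_total,
            "untestable": untestable,
        },
        index=matrix.intensities.index,
    )
    out["p_bh"] = _benjamini_hochberg(out["p"].to_numpy())
    out["enriched"] = (out["log2fc"].abs() > fc_threshold) & (out["p"] < p_threshold)
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p values (reference column only)."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        from statsmodels.stats.multitest import multipletests

        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def apply_confidence_filters(
    table: pd.DataFrame, psm_min: float = 4.0, min_bio_quantified: int = 2
) -> pd.DataFrame:
    """Flag enriched proteins that also pass the low-intensity false-positive
    filters: total averaged PSM count strictly > ``psm_min`` and quantified
    pre-imputation in ≥ ``min_bio_quantified`` biological replicates of at
    least one compared group."""
    out = table.copy()
    psm_ok = out["psm_total"] > psm_min
    quant_ok = (out["n_quant_group1"] >= min_bio_quantified) | (
        out["n_quant_group2"] >= min_bio_quantified
    )
    out["significant_after_filters"] = out["enriched"] & psm_ok & quant_ok
    n_removed = int((out["enriched"] & ~out["significant_after_filters"]).sum())
    logger.info(
        "confidence filters removed %d of %d enriched proteins",
        n_removed,
        int(out["enriched"].sum()),
    )
    return out


def volcano_data(table: pd.DataFrame, p_cap: float = P_FLOOR) -> pd.DataFrame:
    """Volcano-plot coordinates: log2FC vs −log10 p, with the flags.

    p = 0 is mapped to ``p_cap`` with a warning; the significance guides are
    |log2FC| = 1 and −log10 p = −log10(0.05) ≈ 1.30.
    """
    p = table["p"].copy()
    if (p == 0).any():
        import warnings

        warnings.warn(f"p = 0 capped at {p_cap}", stacklevel=2)
        p = p.replace(0.0, p_cap)
    out = pd.DataFrame(
        {
            "log2fc": table["log2fc"],
            "neg_log10_p": -np.log10(p),
            "enriched": table["enriched"],
        },
        index=table.index,
    )
    if "significant_after_filters" in table:
        out["significant_after_filters"] = table["significant_after_filters"]
    return out


def run_enrichment_pipeline(
    matrix: LfqMatrix,
    comparisons: list[ComparisonSpec] | None = None,
    q: float = 0.05,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.05,
    psm_min: float = 4.0,
) -> dict[str, pd.DataFrame]:
    """Run normalize → impute → log2 → average → test → filter for each
    comparison, starting from a raw protein-level matrix."""
    comparisons = comparisons or CANONICAL_COMPARISONS
    m = normalize_median(matrix)
    m = impute_quantile(m, q=q)
    m = log2_transform(m)
    m = average_technical(m)
    return {
        c.name: apply_confidence_filters(
            test_enrichment(m, c, fc_threshold=fc_threshold, p_threshold=p_threshold),
            psm_min=psm_min,
        )
        for c in comparisons
    }


# ---------------------------------------------------------------------------
# paraspeckle-component annotation
# ---------------------------------------------------------------------------


def load_paraspeckle_table() -> pd.DataFrame:
    """Packaged annotation of 40 reported paraspeckle components: name,
    alternative name, structural class (I/II/III sub-classes, 'n/d' or blank
    where unreported), known ITAF function, and presence in the p54nrb
    AP-MS interactome."""
    ref = importlib.resources.files("ireskit.data") / "paraspeckle_components.csv"
    with importlib.resources.as_file(ref) as path:
        table = pd.read_csv(path, keep_default_na=False)
    return table


def annotate_paraspeckle(
    annotation: pd.DataFrame, identified: set[str] | None = None
) -> dict[str, int | str]:
    """Overlap of an identified-protein set with the paraspeckle annotation.

    With ``identified=None`` ("fixture" mode) presence is read from the
    annotation's ``presence_in_ms`` column; otherwise ("analysis" mode) a
    component is present when its name or alternative name occurs in
    ``identified`` (case-insensitive).

    Returns ``n_total``, ``n_present``, ``n_present_itaf`` and ``mode``.
    """
    names = annotation["name"].str.lower()
    if names.duplicated().any():
        raise ValueError("duplicate names in annotation")
    if identified is None:
        present = annotation["presence_in_ms"].str.lower() == "yes"
        mode = "fixture"
    else:
        idset = {s.lower() for s in identified}
        alt = annotation.get("alternative_name", pd.Series("", index=annotation.index))
        present = names.isin(idset) | alt.str.lower().isin(idset)
        mode = "analysis"
    itaf = annotation["itaf"].str.lower() == "yes" if len(annotation) else pd.Series(dtype=bool)
    return {
        "n_total": int(len(annotation)),
        "n_present": int(present.sum()),
        "n_present_itaf": int((present & itaf).sum()) if len(annotation) else 0,
        "mode": mode,
    }
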