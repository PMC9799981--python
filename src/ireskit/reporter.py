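"""Dual-luciferase bicistronic reporter analysis.

In the bicistronic reporter the upstream renilla cistron (LucR) is translated
cap-dependently and the downstream firefly cistron (LucF) by the IRES placed
between them, so the LucF/LucR ratio measures IRES activity.  The pipeline:
plate background (non-transduced wells) is subtracted per channel; the
technical ratio LucF/LucR is computed per well; biological replicates are the
mean of their technical ratios; activities are normalized to a reference
group mean; groups are compared with the Mann-Whitney U test (exact when
feasible).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

PLATE_COLUMNS = [
    "well",
    "construct",
    "condition",
    "bio_rep",
    "tech_rep",
    "lucR",
    "lucF",
    "is_background",
]


def subtract_background(
    readings: pd.DataFrame, no_background: bool = False, plate_col: str | None = None
) -> pd.DataFrame:
    """Subtract the mean of non-transduced (background) wells per channel.

    When ``plate_col`` names a column, backgrounds are computed per plate.
    Sample wells at or below background are flagged ``valid = False`` and
    excluded downstream.  Without background wells this raises unless
    ``no_background`` is set, in which case readings pass through unchanged.
    """
    out = readings.copy()
    if no_background:
        out["valid"] = ~out["is_background"]
        return out
    groups = out.groupby(plate_col) if plate_col else [(None, out)]
    parts = []
    for _, plate in groups:
        bg = plate[plate["is_background"]]
        if bg.empty:
            raise ValueError("no background wells; pass no_background=True to skip subtraction")
        p = plate.copy()
        p["lucR"] = p["lucR"] - bg["lucR"].mean()
        p["lucF"] = p["lucF"] - bg["lucF"].mean()
        parts.append(p)
    out = pd.concat(parts)
    out["valid"] = ~out["is_background"] & (out["lucR"] > 0) & (out["lucF"] > 0)
    n_bad = int((~out["valid"] & ~out["is_background"]).sum())
    if n_bad:
        logger.info("%d wells invalid after background subtraction", n_bad)
    return out


def ires_activity(readings: pd.DataFrame) -> pd.DataFrame:
    """LucF/LucR per well, averaged over technical replicates.

    Returns one row per (construct, condition, bio_rep) with the biological
    ratio = mean of its technical LucF/LucR ratios.  Requires
    background-subtracted readings with a ``valid`` flag.
    """
    if "valid" not in readings:
        raise ValueError("run subtract_background first (no 'valid' flag)")
    ok = readings[readings["valid"]].copy()
    if (ok["lucR"] <= 0).any():
        raise ValueError("LucR must be positive for valid wells")
    ok["ratio"] = ok["lucF"] / ok["lucR"]
    bio = (
        ok.groupby(["construct", "condition", "bio_rep"], sort=False)["ratio"]
        .agg(ratio="mean", n_tech="count")
        .reset_index()
    )
    unbalanced = bio["n_tech"].nunique() > 1
    if unbalanced:
        logger.info("unbalanced technical replication: %s", bio["n_tech"].value_counts().to_dict())
    return bio


def normalize_to_reference(
    activities: pd.DataFrame, reference: dict[str, str] | str
) -> pd.DataFrame:
    """Divide every ratio by the reference-group mean ratio.

    ``reference`` selects the reference group either as a condition label or
    as a ``{column: value}`` mapping (e.g. ``{"condition": "normoxia"}``).
    The normalized mean of the reference group is exactly 1.
    """
    if isinstance(reference, str):
        reference = {"condition": reference}
    sel = pd.Series(True, index=activities.index)
    for col, val in reference.items():
        sel &= activities[col] == val
    if not sel.any():
        raise ValueError(f"reference group {reference} is empty")
    ref_mean = activities.loc[sel, "ratio"].mean()
    if ref_mean <= 0:
        raise ValueError("reference-group mean must be positive")
    out = activities.copy()
    out["normalized_ratio"] = out["ratio"] / ref_mean
    return out


@dataclass
class GroupComparison:
    """Mann-Whitney comparison of two groups of activities."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    u: float
    p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    method: str


def mann_whitney(
    group_a, group_b, label_a: str = "A", label_b: str = "B"
) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration of the permutation null when n_a + n_b ≤ 20 and
    there are no ties; otherwise the normal approximation with tie
    correction.  Completely tied samples (all values equal) give p = 1.
    The method used is recorded.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        u, p, method = len(a) * len(b) / 2.0, 1.0, "degenerate (all tied)"
    elif not has_ties and len(a) + len(b) <= 20:
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact"
    else:
        u, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        method = "normal approximation, tie-corrected"
    return GroupComparison(
        label_a,
        label_b,
        len(a),
        len(b),
        float(u),
        float(p),
        float(a.mean()),
        float(b.mean()),
        float(a.std(ddof=1)) if len(a) > 1 else 0.0,
        float(b.std(ddof=1)) if len(b) > 1 else 0.0,
        method,
    )


def compare_groups(
    activities: pd.DataFrame,
    group_col: str = "condition",
    value_col: str = "ratio",
) -> pd.DataFrame:
    """All pairwise Mann-Whitney comparisons between levels of ``group_col``."""
    levels = list(pd.unique(activities[group_col]))
    rows = []
    for i, ga in enumerate(levels):
        for gb in levels[i + 1 :]:
            cmp = mann_whitney(
                activities.loc[activities[group_col] == ga, value_col],
                activities.loc[activities[group_col] == gb, value_col],
                str(ga),
                str(gb),
            )
            rows.append(vars(cmp))
    return pd.DataFrame(rows)
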