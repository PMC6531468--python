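"""In vivo binding index (B index) and array-count group comparisons.

The B index of a transcript region is its CLIP tag count divided by its
expression level (mean RNA-seq coverage), so that tag density is compared
across regions independent of transcript abundance. Regions are grouped by
their motif-array count (0, 1, 2/3, >=4) and each non-zero group is compared
against the array-free group with Welch's unequal-variance two-sample t test
(two-sided, Welch-Satterthwaite degrees of freedom, no multiple-testing
correction).

CLIP tags are assigned to a region by their start coordinate (the iCLIP
truncation-position convention; configurable to the tag midpoint). Regions
with zero or missing expression are excluded before analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scanner import GROUP_LABELS, array_count_group

logger = logging.getLogger(__name__)


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float
    skipped: bool = False


def welch_ttest(a, b) -> tuple[float, float, float]:
    """Welch's two-sample t statistic, Welch-Satterthwaite df, two-sided p.

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with sample
    variances (ddof=1). Two identical zero-variance groups give t=0, p=1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    sa, sb = va / na, vb / nb
    denom = math.sqrt(sa + sb)
    diff = a.mean() - b.mean()
    if denom == 0.0:
        if diff == 0.0:
            return 0.0, float(na + nb - 2), 1.0
        return math.copysign(math.inf, diff), float(na + nb - 2), 0.0
    t = diff / denom
    df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p


def count_tags_in_regions(
    regions: pd.DataFrame, tags: pd.DataFrame, position: str = "start"
) -> pd.Series:
    """Number of tag records whose assigned position falls within each region.

    ``regions``: columns chrom, start, end, region_id (half-open intervals).
    ``tags``: columns chrom, start, end. ``position`` is "start" (default,
    truncation convention) or "midpoint".
    """
    if position == "start":
        pos = tags["start"].to_numpy()
    elif position == "midpoint":
        pos = ((tags["start"] + tags["end"]) // 2).to_numpy()
    else:
        raise ValueError("position must be 'start' or 'midpoint'")
    counts = pd.Series(0, index=regions["region_id"], dtype=int)
    tag_chrom = tags["chrom"].to_numpy()
    for chrom, sub in regions.groupby("chrom"):
        p = np.sort(pos[tag_chrom == chrom])
        lo = np.searchsorted(p, sub["start"].to_numpy(), side="left")
        hi = np.searchsorted(p, sub["end"].to_numpy(), side="left")
        counts.loc[sub["region_id"]] = hi - lo
    return counts


def compute_b_index(
    regions: pd.DataFrame,
    tags: pd.DataFrame,
    expression: pd.Series,
    array_counts: pd.Series | None = None,
    tag_position: str = "start",
) -> pd.DataFrame:
    """Per-region B index table, optionally joined with motif-array counts.

    ``expression`` maps region_id to a positive expression level; regions
    with zero or missing expression are excluded (logged). Returns columns
    region_id, length, expression, tag_count, b_index (+ array_count, group
    when array counts are supplied).
    """
    df = regions[["region_id", "chrom", "start", "end"]].copy()
    df["length"] = df["end"] - df["start"]
    df["tag_count"] = count_tags_in_regions(regions, tags, tag_position).to_numpy()
    df["expression"] = df["region_id"].map(expression)
    missing = df["expression"].isna()
    zero = df["expression"] <= 0
    dropped = int((missing | zero).sum())
    if dropped:
        logger.warning("excluding %d regions with zero or missing expression", dropped)
    df = df[~(missing | zero.fillna(False))].copy()
    df["b_index"] = df["tag_count"] / df["expression"]
    if array_counts is not None:
        df["array_count"] = df["region_id"].map(array_counts).astype(int)
        df["group"] = df["array_count"].map(array_count_group)
    return df.drop(columns=["chrom", "start", "end"]).reset_index(drop=True)


def group_and_compare(
    bindings: pd.DataFrame, value: str = "b_index", bins: int = 50
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare each array-count group against the array-free group.

    Returns (comparisons, density) where comparisons has one row per
    non-zero group with the Welch statistic, df, and two-sided p, and
    density is a per-group histogram of the value at ``bins`` bins.
    Any group with fewer than 2 members is skipped with a flag.
    """
    if "group" not in bindings.columns:
        raise ValueError("bindings must carry an array-count group column")
    baseline = bindings.loc[bindings["group"] == "0", value].to_numpy()
    rows = []
    for label in GROUP_LABELS[1:]:
        vals = bindings.loc[bindings["group"] == label, value].to_numpy()
        if len(vals) < 2 or len(baseline) < 2:
            rows.append(
                GroupComparison("0", label, len(baseline), len(vals), float("nan"),
                                float("nan"), float("nan"), float("nan"), float("nan"),
                                skipped=True)
            )
            continue
        t, df_, p = welch_ttest(vals, baseline)
        rows.append(
            GroupComparison("0", label, len(baseline), len(vals),
                            float(baseline.mean()), float(vals.mean()), t, df_, p)
        )
    comparisons = pd.DataFrame([vars(r) for r in rows])
    lo = float(bindings[value].min())
    hi = float(bindings[value].max())
    edges = np.linspace(lo, hi if hi > lo else lo + 1.0, bins + 1)
    dens = {}
    for label in GROUP_LABELS:
        vals = bindings.loc[bindings["group"] == label, value].to_numpy()
        dens[label] = np.histogram(vals, bins=edges)[0]
    density = pd.DataFrame(dens, index=pd.IntervalIndex.from_breaks(edges))
    return comparisons, density


def group_means(bindings: pd.DataFrame, value: str = "b_index") -> pd.Series:
    """Mean value per array-count group, in group order 0, 1, 2/3, >=4."""
    means = bindings.groupby("group")[value].mean()
    return means.reindex(list(GROUP_LABELS))


def read_bed(path) -> pd.DataFrame:
    """Minimal BED reader (chrom, start, end [, name])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end"})
    if df.shape[1] > 3:
        df = df.rename(columns={3: "region_id"})
    return df


def read_expression(path) -> pd.Series:
    """Two-column (region_id, value) tab-separated expression table."""
    df = pd.read_csv(path, sep="\t", header=None, names=["region_id", "value"])
    return df.set_index("region_id")["value"]
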