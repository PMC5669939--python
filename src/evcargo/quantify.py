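"""Percent-of-total quantification, expression thresholding and top-N profiles.

The abundance unit throughout is percent of total counts per sample
(100 * count / column total).  Features are retained when their group-mean
percent reaches a threshold (default 0.05%) in at least one group; top-N
profiles flag features shared between groups versus unique to one.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

__all__ = [
    "percent_of_total",
    "group_mean",
    "threshold_filter",
    "top_n",
    "cumulative_top_share",
    "isomir_fraction",
    "summarize_by_gene_type",
]

DEFAULT_THRESHOLD_PERCENT = 0.05


def percent_of_total(counts: pd.DataFrame) -> pd.DataFrame:
    """Convert a feature x sample count table to percent of column total.

    Every column of the result sums to 100.  A sample with zero total has no
    defined composition and raises.
    """
    totals = counts.sum(axis=0)
    zero = totals[totals == 0]
    if not zero.empty:
        raise ValueError(f"zero-total sample column(s): {list(zero.index)}")
    return 100.0 * counts / totals


def group_mean(percents: pd.DataFrame, sample_sheet: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of replicate columns within each group.

    Column sums (100) are preserved because the mean of columns each summing
    to 100 sums to 100.
    """
    sheet = sample_sheet.set_index("sample_id")
    missing = set(percents.columns) - set(sheet.index)
    if missing:
        raise ValueError(f"samples not in sample sheet: {sorted(missing)}")
    groups: dict[str, list[str]] = {}
    for s in percents.columns:
        groups.setdefault(sheet.loc[s, "group_id"], []).append(s)
    if any(len(cols) == 0 for cols in groups.values()):
        raise ValueError("group with no samples")
    out = pd.DataFrame(
        {g: percents[cols].mean(axis=1) for g, cols in sorted(groups.items())}
    )
    return out


def threshold_filter(
    group_percents: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD_PERCENT
) -> list[str]:
    """Features whose percent reaches ``threshold`` (inclusive) in >= 1 group.

    Input-row order is preserved.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = group_percents.max(axis=1) >= threshold
    return list(group_percents.index[keep])


def top_n(group_percents: pd.DataFrame, n: int) -> pd.DataFrame:
    """Per-group top-n features with a shared/unique flag.

    Ranking is by descending percent with ties broken by ascending feature
    id, so output is independent of input row order.  A feature is shared if
    it appears in the top-n of at least two groups.  Returns a DataFrame
    with columns group, rank, feature, percent, shared.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    per_group: dict[str, pd.Series] = {}
    for g in group_percents.columns:
        s = group_percents[g].sort_index().sort_values(ascending=False, kind="stable")
        per_group[g] = s.iloc[:n]
    membership: dict[str, int] = {}
    for s in per_group.values():
        for f in s.index:
            membership[f] = membership.get(f, 0) + 1
    rows = []
    for g, s in per_group.items():
        for rank, (feature, pct) in enumerate(s.items(), start=1):
            rows.append(
                {
                    "group": g,
                    "rank": rank,
                    "feature": feature,
                    "percent": float(pct),
                    "shared": membership[feature] >= 2,
                }
            )
    return pd.DataFrame(rows)


def cumulative_top_share(group_percents: pd.DataFrame, n: int) -> pd.Series:
    """Sum of the top-n percents per group (the share of cargo held by the
    n most abundant features)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return pd.Series(
        {
            g: float(
                group_percents[g]
                .sort_index()
                .sort_values(ascending=False, kind="stable")
                .iloc[:n]
                .sum()
            )
            for g in group_percents.columns
        }
    )


def isomir_fraction(class_counts: pd.DataFrame) -> pd.Series:
    """Fraction of miRNA-assigned reads that are isomiRs, per sample.

    ``class_counts`` is the long isomiR count table (columns class,
    sample_id, count).  The denominator is canonical + isomiR reads; a sample
    with zero miRNA-assigned reads raises.
    """
    totals = class_counts.groupby("sample_id")["count"].sum()
    if (totals == 0).any():
        raise ValueError("sample with zero miRNA-assigned reads")
    iso = (
        class_counts[class_counts["class"] != "CANONICAL"]
        .groupby("sample_id")["count"]
        .sum()
        .reindex(totals.index, fill_value=0)
    )
    return iso / totals


def summarize_by_gene_type(
    retained: Sequence[str], feature_types: Mapping[str, str]
) -> pd.Series:
    """Count retained features per gene type; the sum equals len(retained)."""
    unmapped = [f for f in retained if f not in feature_types]
    if unmapped:
        raise ValueError(f"features without a gene type: {unmapped}")
    counts: dict[str, int] = {}
    for f in retained:
        t = feature_types[f]
        counts[t] = counts.get(t, 0) + 1
    return pd.Series(counts, dtype=int).sort_index()
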