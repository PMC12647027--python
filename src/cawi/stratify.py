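"""Quintile stratification of institutions by bed capacity and group summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GroupSummary", "assign_quintile_groups", "summarize_groups"]

INDICATORS = ("gr", "cmi", "los", "cawi")


@dataclass(frozen=True)
class GroupSummary:
    """Per-quintile descriptive statistics of the four indicators."""

    group_index: int  # 1 (smallest hospitals) .. 5 (largest)
    bed_min: float
    bed_max: float
    n_institutions: int
    mean: dict[str, float]
    sd: dict[str, float]


def assign_quintile_groups(records: pd.DataFrame) -> pd.Series:
    """Assign each institution to a size quintile (1 = smallest beds, 5 = largest).

    Institutions are sorted ascending by beds with ties broken by
    institution_id, then split into 5 contiguous blocks whose sizes differ by
    at most one; remainder institutions go to the lowest-index groups.
    Returns a Series of group labels indexed by institution_id.
    """
    n = len(records)
    if records["institution_id"].duplicated().any():
        raise ValueError("records must hold one row per institution")
    if n < 5:
        raise ValueError(f"quintile grouping needs >= 5 institutions, got {n}")
    order = records.sort_values(["beds", "institution_id"], kind="mergesort")
    base, extra = divmod(n, 5)
    sizes = [base + (1 if g < extra else 0) for g in range(5)]
    labels = np.repeat(np.arange(1, 6), sizes)
    return pd.Series(labels, index=order["institution_id"], name="group")


def summarize_groups(
    records: pd.DataFrame, grouping: pd.Series
) -> tuple[list[GroupSummary], dict[str, float]]:
    """Group means and sample SDs of each indicator, plus overall GR/CAWI SDs.

    ``grouping`` maps institution_id to a group label (1-5) and must cover
    every record.  SDs use the n-1 denominator.
    """
    missing = set(records["institution_id"]) - set(grouping.index)
    if missing:
        raise ValueError(f"grouping does not cover institutions: {sorted(missing)[:5]}")
    df = records.assign(group=records["institution_id"].map(grouping))
    summaries = []
    for g, sub in df.groupby("group"):
        summaries.append(
            GroupSummary(
                group_index=int(g),
                bed_min=float(sub["beds"].min()),
                bed_max=float(sub["beds"].max()),
                n_institutions=len(sub),
                mean={k: float(sub[k].mean()) for k in INDICATORS},
                sd={k: float(sub[k].std(ddof=1)) for k in INDICATORS},
            )
        )
    summaries.sort(key=lambda s: s.group_index)
    overall = {
        "gr_sd": float(df["gr"].std(ddof=1)),
        "cawi_sd": float(df["cawi"].std(ddof=1)),
    }
    return summaries, overall


def summaries_to_frame(summaries: list[GroupSummary]) -> pd.DataFrame:
    """Flatten group summaries into a table shaped like the benchmark report."""
    rows = []
    for s in summaries:
        row = {
            "group": s.group_index,
            "bed_min": s.bed_min,
            "bed_max": s.bed_max,
            "n": s.n_institutions,
        }
        for k in INDICATORS:
            row[f"{k}_mean"] = s.mean[k]
            row[f"{k}_sd"] = s.sd[k]
        rows.append(row)
    return pd.DataFrame(rows)
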