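"""Waste-benchmarking indicators: CMI, LOS, generation rate, and CAWI.

Four indicators per institution:

* **CMI** (Case-Mix Index): case-weighted mean DRG relative weight,
  ``sum(weight * cases) / sum(cases)`` — clinical complexity.
* **LOS** (Length of Stay): ``total inpatient days / total discharges`` —
  care intensity (shorter stays = more intensive care).
* **GR** (generation rate): ``annual hazardous waste kg / (beds * days in
  year)`` in kg/bed/day — the conventional benchmarking unit.
* **CAWI** (Complexity-Adjusted Waste Index): ``GR * CMI / LOS`` in
  kg/bed/day^2 — the waste rate normalized for both complexity and
  intensity, used as a scale-independent comparative metric.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .simulate import days_in_year

__all__ = [
    "DRGCaseGroup",
    "compute_cmi",
    "compute_los",
    "compute_generation_rate",
    "compute_cawi",
    "compute_index_records",
    "validate_panel",
    "CONTROL_VARIABLES",
]

logger = logging.getLogger(__name__)

#: Control variables carried through to the validation battery.
CONTROL_VARIABLES = ("icu_patients", "inpatients", "mdr_incidence", "educational")

Aggregation = Literal["institution_mean", "pooled"]


@dataclass(frozen=True)
class DRGCaseGroup:
    """One Diagnosis-Related Group: its relative resource weight and case count."""

    relative_weight: float
    case_count: int

    def __post_init__(self) -> None:
        if self.relative_weight <= 0:
            raise ValueError("relative_weight must be > 0")
        if self.case_count < 0:
            raise ValueError("case_count must be >= 0")


def compute_cmi(groups: Iterable[DRGCaseGroup | tuple[float, int]]) -> float:
    """Case-Mix Index: case-weighted mean DRG relative weight.

    Raises ``ValueError`` when the total case count is zero (CMI undefined).
    """
    groups = [g if isinstance(g, DRGCaseGroup) else DRGCaseGroup(*g) for g in groups]
    total = sum(g.case_count for g in groups)
    if total <= 0:
        raise ValueError("CMI undefined: total case count is zero")
    return sum(g.relative_weight * g.case_count for g in groups) / total


def compute_los(inpatient_days: float, discharges: float) -> float:
    """Average length of stay in days: inpatient days per discharge."""
    if discharges <= 0:
        raise ValueError("LOS undefined: discharges must be > 0")
    return inpatient_days / discharges


def compute_generation_rate(
    hhcw_kg: float, beds: float, year: int, leap_aware: bool = True
) -> float:
    """Hazardous-waste generation rate in kg/bed/day.

    ``hhcw_kg / (beds * days)`` with ``days`` the calendar days of ``year``
    (366 in leap years) unless ``leap_aware`` is False, then a fixed 365.
    """
    if beds <= 0:
        raise ValueError("generation rate undefined: beds must be > 0")
    if hhcw_kg < 0:
        raise ValueError("hhcw_kg must be >= 0")
    days = days_in_year(year) if leap_aware else 365
    return hhcw_kg / (beds * days)


def compute_cawi(gr: float, cmi: float, los: float) -> float:
    """Complexity-Adjusted Waste Index: ``GR * CMI / LOS`` (kg/bed/day^2)."""
    if los <= 0:
        raise ValueError("CAWI undefined: LOS must be > 0")
    if cmi <= 0:
        raise ValueError("CAWI undefined: CMI must be > 0")
    if gr < 0:
        raise ValueError("CAWI undefined: GR must be >= 0")
    return gr * cmi / los


_REQUIRED_COLUMNS = (
    "institution_id",
    "year",
    "beds",
    "hhcw_kg",
    "inpatient_days",
    "discharges",
    "cmi",
    "icu_patients",
    "inpatients",
    "mdr_incidence",
    "educational",
)


def validate_panel(panel: pd.DataFrame) -> None:
    """Check the panel schema and row invariants, naming row and field on failure."""
    missing = [c for c in _REQUIRED_COLUMNS if c not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing required columns: {missing}")
    if len(panel) == 0:
        raise ValueError("panel is empty")
    checks = [
        ("beds", panel["beds"] <= 0),
        ("hhcw_kg", panel["hhcw_kg"] < 0),
        ("inpatient_days", panel["inpatient_days"] < 0),
        ("discharges", panel["discharges"] < 0),
        ("mdr_incidence", panel["mdr_incidence"] < 0),
    ]
    for fieldname, bad in checks:
        bad = bad | panel[fieldname].isna()
        if bad.any():
            row = int(panel.index[bad][0])
            raise ValueError(f"panel row {row}: invalid value in field '{fieldname}'")


def _apply_drg_table(panel: pd.DataFrame, drg_table: pd.DataFrame) -> pd.DataFrame:
    """Replace precomputed CMI with a CMI derived from a DRG case table.

    The case table wins over a precomputed ``cmi`` column; discrepancies
    above 1e-6 are logged.
    """
    needed = {"institution_id", "year", "relative_weight", "case_count"}
    missing = needed - set(drg_table.columns)
    if missing:
        raise ValueError(f"DRG table missing columns: {sorted(missing)}")
    panel = panel.copy()
    grouped = drg_table.groupby(["institution_id", "year"])
    for (inst, year), sub in grouped:
        value = compute_cmi(list(zip(sub["relative_weight"], sub["case_count"])))
        mask = (panel["institution_id"] == inst) & (panel["year"] == year)
        old = panel.loc[mask, "cmi"]
        if old.notna().any() and (old - value).abs().max() > 1e-6:
            logger.warning(
                "DRG-derived CMI %.6f overrides precomputed CMI %.6f for %s/%s",
                value,
                float(old.iloc[0]),
                inst,
                year,
            )
        panel.loc[mask, "cmi"] = value
    return panel


def compute_index_records(
    panel: pd.DataFrame,
    aggregation: Aggregation = "institution_mean",
    drg_table: pd.DataFrame | None = None,
    leap_aware: bool = True,
) -> pd.DataFrame:
    """Derive per-institution indicator records from a hospital-year panel.

    Under ``institution_mean`` (default) the yearly GR, CMI and LOS are
    averaged per institution first and CAWI is formed from the averaged
    components; control variables are averaged across years.  Under
    ``pooled`` every institution-year yields its own record.  Rows with
    undefined LOS (zero discharges) or CMI are dropped and logged.

    Returns a DataFrame with columns ``institution_id, beds, gr, cmi, los,
    cawi`` plus the control variables; one row per institution
    (``institution_mean``) or per institution-year (``pooled``, with a
    ``year`` column).
    """
    if aggregation not in ("institution_mean", "pooled"):
        raise ValueError(f"unknown aggregation mode: {aggregation!r}")
    validate_panel(panel)
    if drg_table is not None:
        panel = _apply_drg_table(panel, drg_table)

    df = panel.copy()
    usable = (df["discharges"] > 0) & df["cmi"].notna() & (df["cmi"] > 0)
    dropped = int((~usable).sum())
    if dropped:
        logger.warning(
            "dropping %d record(s) with undefined LOS or CMI (rows %s)",
            dropped,
            list(df.index[~usable][:10]),
        )
        df = df[usable]
    if len(df) == 0:
        raise ValueError("no usable records after dropping undefined LOS/CMI")

    days = df["year"].map(days_in_year) if leap_aware else 365
    df = df.assign(
        gr=df["hhcw_kg"] / (df["beds"] * days),
        los=df["inpatient_days"] / df["discharges"],
    )

    if aggregation == "pooled":
        out = df[["institution_id", "year", "beds", "gr", "cmi", "los"]].copy()
        for c in CONTROL_VARIABLES:
            out[c] = df[c].to_numpy()
    else:
        agg = {c: "mean" for c in ("beds", "gr", "cmi", "los", *CONTROL_VARIABLES)}
        out = df.groupby("institution_id", as_index=False).agg(agg)
    out["cawi"] = out["gr"] * out["cmi"] / out["los"]
    return out.reset_index(drop=True)
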