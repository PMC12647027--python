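"""Synthetic hospital-panel generator.

Emulates a national administrative panel of inpatient institutions: bed
capacity, annual hazardous healthcare waste (HHCW) mass, inpatient days,
discharges, a Case-Mix Index (CMI), ICU-patient and inpatient counts, the
incidence of multidrug-resistant healthcare-associated infections (MDR HAI),
and an educational-activity flag.  The generative structure encodes the
relationships the benchmarking analysis assumes: CMI rises and length of
stay (LOS) falls with hospital size, and the daily waste generation rate
rises with CMI and falls with LOS.

Every generated panel ships with its :class:`GroundTruth` — the effect sizes
and per-institution latent generation rates actually used — so downstream
parameter-recovery tests need no re-derivation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "default_params",
    "generate_panel",
    "days_in_year",
    "write_panel_csv",
    "write_ground_truth_json",
    "PANEL_COLUMNS",
]

#: Column order of the panel CSV contract shared with the indices module.
PANEL_COLUMNS = [
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
]

#: Fixed average bed occupancy linking beds to inpatient days.
DEFAULT_OCCUPANCY = 0.8


def days_in_year(year: int) -> int:
    """Calendar days in ``year`` (366 for leap years)."""
    leap = (year % 4 == 0 and year % 100 != 0) or year % 400 == 0
    return 366 if leap else 365


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic hospital-panel model.

    Bed counts are log-normal (``exp(N(bed_log_mean, bed_log_sd))``) clipped
    to ``[bed_min, bed_max]`` and held fixed across years.  Per institution
    ``i`` with ``L_i = log(beds_i)``:

    * ``CMI_i   = a0 + a1 * L_i + N(0, cmi_noise_sd)``, clipped to > 0.1
    * ``LOS_i   = exp(b0 - b1 * L_i + N(0, los_noise_sd))``
    * ``log GR_i = c0 + c1 * log(CMI_i) - c2 * log(LOS_i) + N(0, gr_noise_sd)``

    where GR is the waste generation rate in kg/bed/day.  Annual waste mass
    is ``GR_i * beds_i * days_in_year``; inpatient days come from beds at a
    fixed occupancy; discharges are inpatient days / LOS.  ICU share is
    linear in ``L_i``, MDR incidence is linear in ICU share, and the
    educational flag is Bernoulli with a logistic probability in ``L_i``.
    """

    n_institutions: int = 94
    years: tuple[int, ...] = (2017, 2018, 2019, 2020, 2021)
    # bed-count distribution
    bed_log_mean: float = 6.0
    bed_log_sd: float = 0.85
    bed_min: int = 30
    bed_max: int = 3513
    # CMI model (linear in log-beds)
    cmi_intercept: float = -0.21
    cmi_slope: float = 0.20
    cmi_noise_sd: float = 0.30
    # log-LOS model (decreasing in log-beds)
    los_intercept: float = 4.56
    los_slope: float = 0.354
    los_noise_sd: float = 0.30
    # log generation-rate model
    gr_intercept: float = 0.30
    gr_cmi_effect: float = 0.80
    gr_los_effect: float = 0.60
    gr_noise_sd: float = 0.40
    # ICU share model (fraction of inpatients)
    icu_share_base: float = 0.015
    icu_share_slope: float = 0.012
    # MDR HAI incidence model (cases per 100,000 inpatient days)
    mdr_base: float = 10.0
    mdr_icu_effect: float = 500.0
    mdr_noise_sd: float = 5.0
    # educational-activity flag (logistic in log-beds)
    edu_logit_intercept: float = -9.0
    edu_logit_slope: float = 1.5
    occupancy: float = DEFAULT_OCCUPANCY
    seed: int = 0

    def validate(self) -> None:
        """Raise ``ValueError`` naming the violated invariant, if any."""
        if self.n_institutions < 5:
            raise ValueError("n_institutions must be >= 5 (quintiles degenerate)")
        if len(self.years) < 1:
            raise ValueError("years must be non-empty")
        if not (0 < self.bed_min <= self.bed_max):
            raise ValueError("bed clip bounds must satisfy 0 < bed_min <= bed_max")
        for name in ("cmi_noise_sd", "los_noise_sd", "gr_noise_sd", "mdr_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.bed_log_sd < 0:
            raise ValueError("bed_log_sd must be >= 0")
        if not (0 < self.occupancy <= 1):
            raise ValueError("occupancy must be in (0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """Realized generative quantities stored alongside every panel."""

    gr_cmi_effect: float
    gr_los_effect: float
    latent_gr: pd.Series = field(repr=False)  # kg/bed/day per institution
    cmi: pd.Series = field(repr=False)
    los: pd.Series = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "gr_cmi_effect": self.gr_cmi_effect,
            "gr_los_effect": self.gr_los_effect,
            "latent_gr": self.latent_gr.to_dict(),
            "cmi": self.cmi.to_dict(),
            "los": self.los.to_dict(),
        }


def default_params(seed: int = 0) -> GeneratorParams:
    """Default parameters: 94 institutions over 2017-2021, beds in [30, 3513]."""
    return GeneratorParams(seed=seed)


def generate_panel(params: GeneratorParams | None = None) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a hospital-year panel and its ground truth.

    Returns ``(panel, truth)`` where ``panel`` has one row per
    institution-year with columns :data:`PANEL_COLUMNS`.  All latent noise is
    drawn once per institution, so annual rows of one institution differ only
    through calendar-day counts; equal seeds give bit-identical panels.
    """
    if params is None:
        params = default_params()
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = params.n_institutions

    beds = np.exp(rng.normal(params.bed_log_mean, params.bed_log_sd, size=n))
    beds = np.clip(np.round(beds), params.bed_min, params.bed_max).astype(int)
    log_beds = np.log(beds)

    cmi = params.cmi_intercept + params.cmi_slope * log_beds
    cmi = cmi + rng.normal(0.0, params.cmi_noise_sd, size=n)
    cmi = np.maximum(cmi, 0.1)

    log_los = params.los_intercept - params.los_slope * log_beds
    log_los = log_los + rng.normal(0.0, params.los_noise_sd, size=n)
    los = np.exp(log_los)

    log_gr = (
        params.gr_intercept
        + params.gr_cmi_effect * np.log(cmi)
        - params.gr_los_effect * np.log(los)
        + rng.normal(0.0, params.gr_noise_sd, size=n)
    )
    gr = np.exp(log_gr)

    icu_share = np.clip(
        params.icu_share_base + params.icu_share_slope * (log_beds - np.log(params.bed_min)),
        0.0,
        0.5,
    )
    mdr = params.mdr_base + params.mdr_icu_effect * icu_share
    mdr = np.maximum(mdr + rng.normal(0.0, params.mdr_noise_sd, size=n), 0.0)

    edu_logit = params.edu_logit_intercept + params.edu_logit_slope * log_beds
    edu_p = 1.0 / (1.0 + np.exp(-edu_logit))
    educational = (rng.random(n) < edu_p).astype(int)

    ids = [f"H{i + 1:03d}" for i in range(n)]
    rows = []
    for year in params.years:
        days = days_in_year(year)
        inpatient_days = beds * days * params.occupancy
        discharges = np.maximum(np.round(inpatient_days / los), 1).astype(int)
        inpatients = discharges  # one counted inpatient per stay
        icu_patients = np.maximum(np.round(icu_share * inpatients), 0).astype(int)
        rows.append(
            pd.DataFrame(
                {
                    "institution_id": ids,
                    "year": year,
                    "beds": beds,
                    "hhcw_kg": gr * beds * days,
                    "inpatient_days": inpatient_days,
                    "discharges": discharges,
                    "cmi": cmi,
                    "icu_patients": icu_patients,
                    "inpatients": inpatients,
                    "mdr_incidence": mdr,
                    "educational": educational,
                }
            )
        )
    panel = pd.concat(rows, ignore_index=True)[PANEL_COLUMNS]
    panel = panel.sort_values(["institution_id", "year"], ignore_index=True)

    idx = pd.Index(ids, name="institution_id")
    truth = GroundTruth(
        gr_cmi_effect=params.gr_cmi_effect,
        gr_los_effect=params.gr_los_effect,
        latent_gr=pd.Series(gr, index=idx, name="latent_gr"),
        cmi=pd.Series(cmi, index=idx, name="cmi"),
        los=pd.Series(los, index=idx, name="los"),
    )
    return panel, truth


def write_panel_csv(panel: pd.DataFrame, path: str | Path) -> None:
    panel.to_csv(path, index=False)


def write_ground_truth_json(truth: GroundTruth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True))


def params_to_dict(params: GeneratorParams) -> dict:
    d = dataclasses.asdict(params)
    d["years"] = list(params.years)
    return d
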