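# cawi — Complexity-Adjusted Waste Index benchmarking

Hospitals are routinely compared on their hazardous healthcare waste (HHCW)
output with the raw generation rate, GR = kg of waste per bed per day. That
metric ignores *who* the hospital treats: tertiary centres with complex,
short-stay, high-intensity caseloads will always look "wasteful" next to
small long-stay institutions. `cawi` implements and validates a
complexity-adjusted alternative,

```
GR   = annual HHCW kg / (beds × days in year)        [kg/bed/day]
CMI  = Σ(DRG relative weight × cases) / Σ(cases)     [dimensionless]
LOS  = total inpatient days / total discharges        [days]
CAWI = GR × CMI / LOS                                 [kg/bed/day²]
```

where the Case-Mix Index (CMI) up-weights clinically complex caseloads and
the average Length of Stay (LOS) discounts long-stay, low-intensity care.
The package is aimed at health-system analysts and waste-management
researchers who want to benchmark institutions on an equal footing — and to
check, on their own data, whether the adjusted index really behaves better
than the raw rate.

## What it does

* **Indicator derivation** (`cawi.indices`) from hospital-year panels
  (CSV or DataFrame), optionally recomputing CMI from a DRG case table,
  with pooled or per-institution-mean aggregation.
* **Quintile stratification** (`cawi.stratify`) of institutions by bed
  capacity with per-group means/SDs of all four indicators.
* **A comparative statistical battery** (`cawi.stats`): Shapiro–Wilk
  gatekeeping, a two-sided variance-ratio F-test of GR vs CAWI, Spearman
  correlations, Fisher-z and Steiger-z comparison of dependent correlation
  coefficients, and Huber IRLS robust regression with residual diagnostics.
* **A synthetic panel generator** (`cawi.simulate`) that emulates a
  national 94-institution, 5-year administrative dataset with known
  ground-truth effect sizes, so the whole pipeline is testable offline.
* **A Model/Results interface** (`cawi.model.CAWIValidation`) plus a CLI
  (`cawi simulate | compute-indices | validate | report`).

## Worked example

```python
from cawi.model import CAWIValidation

results = CAWIValidation.from_synthetic(seed=1).fit()
print(results.summary())
results.save("out/")            # report.json + CSV table analogues
```

On the default synthetic panel (94 institutions × 2017–2021) this prints,
among other tables:

```
overall SD: GR 0.1769  CAWI 0.0493
variance F-test GR vs CAWI: F = 12.893, p = 2.13e-28

Spearman with GR: CMI rho = 0.653 (p = 9.54e-13)  LOS rho = -0.578 (p = 1.09e-09)

Correlation comparison (CAWI vs GR) per control variable:
      control  n  rho_gr  p_gr  rho_cawi  p_cawi  fisher_z  fisher_p
 icu_patients 94  0.5741   0.0    0.7029     0.0    1.4796    0.1390
mdr_incidence 94  0.5320   0.0    0.6135     0.0    0.8205    0.4119
   inpatients 94  0.5837   0.0    0.7142     0.0    1.5346    0.1249
```

Reading: waste output rises with case complexity (positive CMI–GR
correlation) and falls with length of stay; the adjusted index is far less
dispersed across institutions than the raw rate (significant F-test) and
tracks the clinical-intensity controls (ICU patients, MDR infection
incidence, inpatient volume) more closely. The robust-regression table
additionally shows uniformly smaller standard errors for the CAWI models —
the pattern that motivates using CAWI for cross-institution benchmarking.

The same battery runs on real data:

```python
results = CAWIValidation.from_csv("panel.csv").fit()
```

where `panel.csv` has one row per institution-year with columns
`institution_id, year, beds, hhcw_kg, inpatient_days, discharges, cmi,
icu_patients, inpatients, mdr_incidence, educational`.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full pipeline from scratch — generates the default synthetic
panel at the given seed, derives all four indicators, stratifies the
institutions, and runs the complete statistical battery — and writes its
results JSON to `--out`.

## Layout

```
src/cawi/simulate.py    synthetic panel generator + ground truth
src/cawi/indices.py     CMI / LOS / GR / CAWI arithmetic and aggregation
src/cawi/stratify.py    bed-capacity quintiles and group summaries
src/cawi/stats.py       the statistical battery
src/cawi/model.py       CAWIValidation / CAWIValidationResults
src/cawi/io.py, cli.py  CSV I/O and the command line
docs/methods.md         model assumptions, defaults, numerical choices
```
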