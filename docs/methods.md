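# Methods

## The indicators

For an institution-year with `beds` operating beds, annual hazardous
healthcare waste mass `W` (kg), total inpatient days `D`, discharges `S`,
and a Diagnosis-Related-Group (DRG) case table with relative weights `w_g`
and case counts `n_g`:

* generation rate `GR = W / (beds × d_y)` with `d_y` the calendar days of
  the year (366 in leap years; a fixed-365 mode is available, since real
  reporting conventions vary and the leap-day correction is ~0.3%);
* Case-Mix Index `CMI = Σ w_g n_g / Σ n_g` (a case-weighted mean, hence
  bounded by the smallest and largest active weight);
* length of stay `LOS = D / S` (undefined for `S = 0`; such rows are
  dropped and logged);
* `CAWI = GR × CMI / LOS`, nominal unit kg/bed/day², used purely as a
  comparative scale-independent quantity.

**Aggregation.** The default `institution_mean` mode averages the yearly
GR, CMI and LOS per institution over the study window and forms CAWI from
the averaged components (mean-of-components, then ratio). Group-level CAWI
in the quintile table is the *mean of institution-level CAWIs*, not the
CAWI of group-mean components — the two differ whenever the indicators
covary across institutions, and the mean-of-ratios convention is the one a
benchmark table reports. A `pooled` mode (one record per institution-year)
is retained for sensitivity analysis.

## Stratification

Institutions are ranked by bed capacity (ties broken by identifier, so the
split is deterministic) and cut into five contiguous rank blocks whose
sizes differ by at most one; remainders go to the smallest-bed groups, so
94 institutions split 19/19/19/19/18. Rank blocks rather than bed-value
cut points are used because the design goal is ~20% of institutions per
group; the printed bed ranges are then observed extremes. All dispersion
statistics use the sample (n−1) denominator.

## The statistical battery

Run in a fixed order by `CAWIValidation.fit()`:

1. **Shapiro–Wilk** on each indicator (delegated to `scipy.stats.shapiro`;
   its role is gatekeeping the choice of non-parametric methods, and the
   result is recorded in the report).
2. **Variance F-test** of GR against CAWI: `F = s²_GR / s²_CAWI`,
   two-sided `p = 2·min(P(F≤f), P(F≥f))` capped at 1. The raw-scale
   comparison is intentional: the claim under test is that the adjusted
   index disperses less across institutions on its own scale.
3. **Spearman correlations** of CMI and LOS with GR, and of both
   indicators with each continuous control variable (ICU patients, MDR
   HAI incidence, inpatient count). Average ranks for ties; p-values from
   the t approximation with n−2 df.
4. **Correlation comparison.** The default is the independent-samples
   Fisher z statistic, `Z = (atanh r₁ − atanh r₂)/√(1/(n₁−3)+1/(n₂−3))`.
   Because both indicators are measured on the *same* institutions this
   form is strictly misspecified (it ignores the GR–CAWI dependence and is
   conservative); it is kept as the default because it is the conventional
   report, and Steiger's z for dependent overlapping correlations (with
   the Dunn–Clark pooled-correlation refinement) is provided alongside
   (`comparison="steiger"` or `"both"`). The binary educational flag is
   excluded from the correlation comparison and enters only the
   regressions.
5. **Robust regression.** One univariate Huber regression of each
   indicator on each control variable (separate models, matching the
   one-coefficient-per-control reporting shape; a multivariable mode is
   available). Estimation is IRLS with Huber weights, `c = 1.345` (95%
   Gaussian efficiency), scale re-estimated each iteration by the
   normalized MAD of residuals, convergence when the maximum coefficient
   change drops below 1e-8 (max 50 iterations; non-convergence sets a
   flag and warns, never silently). Standard errors are the asymptotic
   sandwich covariance of the M-estimator. Implementation delegates to
   `statsmodels` RLM with exactly these settings; an optional Tukey
   biweight (`c = 4.685`) is behind a flag. This emulates, and does not
   bit-reproduce, the unnamed robust estimator of commercial packages.
6. **Residual diagnostics** per fit: residual SD and the OLS slope of
   |residual| on fitted values as a heteroscedasticity cue.

A perfect-fit design collapses the MAD scale to zero, where Huber weights
are undefined; the fit then returns the exact least-squares solution with
zero standard errors.

## The synthetic generator

The generator emulates a national administrative panel: 94 institutions
over 2017–2021, bed counts log-normal (log-mean 6.0, log-SD 0.85) clipped
to [30, 3513] and fixed across years. Per institution `i` with
`L = log beds`:

| latent | model | default |
|---|---|---|
| CMI | `−0.21 + 0.20·L + N(0, 0.30)`, clipped > 0.1 | rises with size, ~0.75 small → ~1.3 large |
| LOS | `exp(4.56 − 0.354·L + N(0, 0.30))` | falls with size, ~17 d small → ~7 d large |
| log GR | `0.30 + 0.8·log CMI − 0.6·log LOS + N(0, 0.40)` | GR ~0.2–0.5 kg/bed/day |
| ICU share | `0.015 + 0.012·(L − log 30)` | ~2–7% of inpatients |
| MDR incidence | `10 + 500·share + N(0, 5)`, floored at 0 | tens per 100k inpatient days |
| educational | Bernoulli(σ(−9 + 1.5·L)) | largest institutions usually academic |

The CMI/LOS intercepts and slopes were set once so that the smallest and
largest size quintiles land near the published group-level magnitudes
(CMI ≈ 0.76 vs 1.29, LOS ≈ 17.2 vs 6.9 days); the GR elasticities
(c₁ = 0.8, c₂ = 0.6) and noise SDs are the package's own choice of a
realistic stated world — strong enough to reproduce the qualitative
correlation structure, noisy enough that nothing is deterministic.
Annual quantities are derived deterministically from the institution-level
latents: waste `= GR·beds·d_y`, inpatient days `= beds·d_y·0.8` (fixed
occupancy — bed occupancy is not modelled, only the beds→days link),
discharges `= inpatient days / LOS` rounded to ≥ 1, inpatients set equal
to discharges. All randomness sits at the institution level, so a panel is
bit-identical under one seed and each institution's years differ only
through calendar length.

**What a green test does not establish.** The generator has no year
shocks, no reporting error, no missing data, no coding drift in CMI, and
its confounding runs only through hospital size; real panels have richer
error structure, so passing the validation battery here shows the
*machinery* is correct and the qualitative contrasts follow from the
assumed structure — not that any particular real system satisfies them.

Parameter-recovery checks regress log GR on **both** log CMI and log LOS:
the two regressors share the size driver, so separate univariate slopes
are confounded by construction, while the joint robust fit recovers the
generative elasticities to within a few percent.

## Determinism and serialization

Given one seed and configuration, the whole pipeline is deterministic and
its JSON report serializes byte-identically (sorted keys, no timestamps).
The run manifest embeds the configuration, seed, and package version.

## Limitations

* Group bed ranges and headline statistics of any specific national
  dataset are reproducible only from that dataset (ingestable as a
  pre-mapped CSV); the package asserts structure and qualitative
  behaviour, not published point values.
* The Fisher-z default is knowingly misspecified for dependent
  correlations (see above); Steiger's z is the statistically correct
  alternative and is reported on request.
* Robust-regression results emulate "a" Huber IRLS; other software's
  defaults (weight function, scale estimator, SE formula) differ in the
  third decimal and beyond.
* No multiple-testing correction is applied anywhere, mirroring the
  reporting convention the battery reproduces.
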