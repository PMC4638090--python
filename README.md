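# glycotrial

Glycemic-control and infection analysis for three-arm ICU enteral-nutrition
trials, plus a synthetic trial generator so the whole pipeline runs with no
external data.

In mechanically ventilated, hyperglycemic ICU patients, the enteral formula
itself is a glycemic intervention: diabetes-specific formulas (slow
carbohydrates, MUFA, fiber) can lower insulin needs, capillary glucose and —
critically — glycemic *variability*, which is associated with ICU-acquired
infection and mortality. `glycotrial` packages the analysis such a trial
needs, for trialists and biostatisticians working with bedside glucose logs:

- **Glycemic variability metrics** on irregularly sampled capillary glucose:
  daily mean Glu_M and SD Glu_SD (n−1 denominator), coefficient of variation
  Glu_CV = Glu_SD·100/Glu_M, peak and day-1 glycemia, band occupancy
  (target 110–150 mg/dL, moderate hypoglycemia 50–80, severe <50), and the
  extraction-corrected **glycemic lability index**

      GLI [(mmol/L)²·h⁻¹·day⁻¹] = Σₙ (gₙ − gₙ₊₁)² / ((N−1)·(hₙ₊₁ − hₙ))

  summed over a day's consecutive reading pairs (g in mmol/L, h in hours,
  N readings that day). Dividing by both the inter-reading gap and N−1 makes
  the index comparable across patients monitored at different frequencies.
- **A sliding-scale insulin engine**: a table-driven reconstruction of the
  consensus continuous-infusion protocol (start at ≥150 mg/dL, stepwise
  escalation, stop and de-arm below 50 mg/dL), zero-order hold between
  capillary checks, exact step-function integration to IU/day totals, and
  suspension during the 8-h blood-test interruptions on days 3/7/14/21/28.
- **Nutrition accounting**: formula compositions per 100 kcal, volume ratio
  VR (%) = administered/prescribed × 100, 25 kcal/kg/day prescriptions,
  non-nutritional calories, and GI-complication rules (GRV ≥500 mL,
  diarrhea ≥5 stools or ≥2000 mL/day).
- **Epidemiology**: ICU-acquired infection filtering (onset ≥48 h),
  incidence rates per 1000 ventilator-days / per 100 treatment-days, 2×2
  odds ratios with Woolf CIs, Poisson score tests on rates, normality-
  screened group comparisons (ANOVA/Tukey or Kruskal–Wallis/Mann–Whitney,
  chi-squared or exact conditional tests), and the group-level Pearson
  correlation between arm variability and arm infection rates (n = 3 arms,
  flagged as such).
- **A trial simulator**: center-stratified blocked randomization (blocks of
  six, 2:2:2), mean-reverting (Ornstein–Uhlenbeck) latent glucose with
  closed-loop insulin feedback, Poisson infection processes over exposure
  time, and coherent CSV output that round-trips through the validators.

## Worked example

```python
from glycotrial import (GlucoseSeries, glycemic_lability_index, window_summary,
                        incidence_rate, odds_ratio, gv_infection_correlation)

s = GlucoseSeries("icu-07", [0.0, 4.0, 8.0, 11.0, 14.5],
                  [180.0, 126.0, 180.0, 150.0, 132.0])
glycemic_lability_index(s, day=1)        # 1.425 (mmol/L)^2 h^-1 day^-1
summ = window_summary(s, (1, 1))
(summ.glu_m, summ.glu_sd, summ.glu_cv)   # (153.6, 25.7, 16.7 %)

incidence_rate(10, 392, 1000).rate       # 25.5 per 1000 ventilator-days
o = odds_ratio(23, 30, 18, 34, orientation="B/A")
(o.oddsratio, o.ci_low, o.ci_high)       # (1.45, 0.66, 3.19)
gv_infection_correlation([28.3, 42.6, 28.4], [15.2, 25.5, 16.5])
                                         # (r=0.994, p=0.07), group-level n=3
```

The five readings swing 180→126→180 mg/dL and back toward target: each
large excursion contributes its squared mmol/L change divided by the gap,
giving a day-1 GLI of 1.425. The 2×2 odds ratio compares infected counts
23/53 vs 18/52 between two arms; the correlation call relates the three
arms' week-1 CV to their tracheobronchitis rates per 1000 ventilator-days.

## Command line

```
glycotrial simulate --seed 42 --out-dir data/        # synthetic 157-patient trial
glycotrial metrics  --glucose data/glucose.csv --windows 1-7,1-28 --out gv.csv
glycotrial protocol --glucose data/glucose.csv --out trace.csv
glycotrial intake   --volumes data/volumes.csv --out intake.csv
glycotrial analyze  --data-dir data/ --out report/   # per-arm report tables
```

CSV schemas: `glucose.csv` (patient_id, time_h, value_mgdl, source),
`patients.csv` (arm, center_id, exposures, outcomes), `infections.csv`
(patient_id, kind, onset_h), `volumes.csv` (daily prescribed/administered mL,
formula, extra kcal). See `src/glycotrial/io.py` for the full schemas and
`docs/methods.md` for the model and its assumptions.

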