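# Methods

This note documents the statistical procedures `glycotrial` implements, the
modelling choices behind the synthetic generator, and the numerical
conventions that matter when reproducing or extending the analyses.

## Time and data model

Time is real-valued hours since ICU admission; "ICU day k" is the half-open
interval [24·(k−1), 24·k). Glucose is stored in mg/dL everywhere and
converted to mmol/L (dividing by 18.0182, the molar mass of glucose over
ten; configurable) only inside the lability index, whose published units are
(mmol/L)²·h⁻¹·day⁻¹. Duplicate timestamps within one patient's series are
rejected rather than averaged, because the lability index divides by
inter-reading gaps and a zero gap is undefined. By default readers keep only
capillary readings — the bedside stream all variability metrics are defined
on — so that same-time capillary/plasma pairs cannot create ties.

Validation is total: every malformed input (missing column, non-numeric
glucose, unknown arm, infection row referencing an absent patient) raises a
structured error with line context; there is never a partial silent result.
A patient with more ventilator-days than ICU-days triggers a warning, not an
error, because discharge bookkeeping differs between centers.

## Glycemic variability

Daily statistics use the sample (n−1) SD; days with fewer than two readings
contribute neither SD nor GLI (flagged absent, not zero-filled). A window
summary over days a..b reports:

- `glu_m`: mean of all readings in the window;
- `glu_sd`: unweighted mean of the defined daily SDs;
- `glu_cv` = `glu_sd`·100/`glu_m` (%), unitless, hence identical whether
  computed in mg/dL or mmol/L;
- `gli`: unweighted mean of the defined daily GLIs;
- day-1 mean glycemia and peak glucose, always over the full stay.

The GLI sums, over a day's consecutive reading pairs, the squared mmol/L
difference divided by (N−1)·gap. The printed form of the equation sums
n = 1..N with a term involving reading N+1; we implement the sum over the
N−1 consecutive pairs (n = 1..N−1), which is what the (N−1) extraction
correction and the original Ryan construction imply — the printed upper
bound is read as an off-by-one typographical artifact. Per-day GLIs are
aggregated to a window by an unweighted mean of defined days; the source
trial fixes the per-day scope ("N is the total number of readings performed
that day") but not the aggregation, and mean-of-days is the least-surprising
reduction.

Pairs spanning a gap longer than `max_pair_gap_h` (default 12 h — longer
than any 8-h feeding interruption plus one sampling interval) are excluded,
and N is reduced to the readings still participating in at least one kept
pair; with fewer than two eligible readings the day's GLI is absent. The
cutoff bounds the influence of pathological gaps even though the per-gap
division already damps them.

Band occupancy uses a literal reading of the printed ranges: severe
hypoglycemia strictly <50 mg/dL, moderate [50, 80], the reported control
band (80, 150], hyperglycemia >150, and the titration target [110, 150]
inclusive (overlapping the control band; counted separately). All edges are
configurable. Percentages are reported over the series' own measurement
count; published episode percentages whose denominators cannot be
reconstructed from the printed measurement counts are not reproduced — the
module reports counts alongside percentages precisely so both are traceable.

## Insulin protocol engine

The engine is a pure rule table over glucose bands ([low, high) intervals
partitioning [0, ∞)) with five action kinds: stop, hold, set (absolute
IU/h), delta (IU/h change) and scale (multiplicative). Two pieces of state
ride along: the current rate and an "armed" flag. Infusion only starts once
a reading reaches the start threshold (150 mg/dL); any reading below the
severe threshold (50 mg/dL) stops the pump *and de-arms it*, so the rate
stays zero until glucose again reaches the restart threshold. Rates are
clamped to [0, max_rate].

The bundled band table is a documented reconstruction around the published
anchor points (start ≥150; +0.5/+1/+2 IU/h escalations per 50-mg/dL band;
halve below 110; stop below 80 pending recheck; stop-and-de-arm below 50;
ceiling 4 IU/h), because the actual multicenter consensus table was only
circulated as supplementary material. Every boundary, action and threshold
is overridable from a YAML band file. Insulin dilution (1:1 saline, 50-mL
syringe) is documentation only and does not affect IU accounting.

Between capillary checks the rate is held constant (zero-order hold), since
the infusion is continuous and adjusted only at measurements. Daily IU
totals are exact integrals of the resulting step function, with the
integrand forced to zero inside the configured interruption windows. The
trial protocol states feeding and insulin were interrupted for 8 h on days
3, 7, 14, 21 and 28 "from 12 p.m. to 8 a.m."; noon-to-8-a.m. is twenty
hours, so this is read as midnight-to-8-a.m. and implemented as the first
8 h of each listed day (offset and length configurable).

## Nutrition accounting

Per-100-kcal composition is canonical; per-100-mL values are derived through
the caloric density. For the three bundled formulas the two routes agree
with the printed per-100-mL values within 2 %. A day's enteral energy is
volume × density; nutrient grams are (kcal/100) × per-100-kcal amount;
non-nutritional calories (propofol 2 %, IV glucose 5 %) are added to energy
only. GI complications use numeric thresholds only where the definitions
give one (GRV ≥500 mL; diarrhea ≥5 liquid stools/24 h or ≥2000 mL/day);
distension, vomiting and regurgitation are boolean observations. A
complication withholding the diet >48 h closes the case early while keeping
the patient in the intention-to-treat set. Classification returns a tuple
because several complications can co-occur in one day's observation.

## Epidemiology and group comparisons

Acquired infections are those with onset ≥48 h after admission; the boundary
is inclusive ("starting 48 h after" read inclusively; configurable).
Respiratory infections (ventilator-associated tracheobronchitis and
pneumonia) are expressed per 1000 ventilator-days; other infections per 100
treatment (enteral-nutrition) days. Rates are compared with a Poisson score
chi-squared test on counts with exposure offsets (1 df); the degenerate
zero-event case returns p = 1. The implementation is cross-checked in the
tests against statsmodels' two-sample Poisson score test and an exact
conditional binomial oracle.

Odds ratios use the (a·d)/(b·c) form with the Woolf (log-normal) 95 % CI;
zero cells get the Haldane–Anscombe 0.5 correction with an explicit flag,
and a fully zero margin is reported as undefined. Published CIs may not
match exactly because the original analysis does not name its CI method.
Because the published OR's direction is ambiguous, reports always carry both
orientations with explicit labels (the printed 1.4 corresponds to
odds(standard arm)/odds(study arm)).

Continuous variables are screened for normality per arm with the
Lilliefors-corrected Kolmogorov–Smirnov test (α = 0.05; arms with fewer
than four observations are not screened): if all arms pass, one-way ANOVA
with Tukey HSD post-hoc; otherwise Kruskal–Wallis with Bonferroni-corrected
pairwise Mann–Whitney U. Categorical arm × level tables use the chi-squared
test, switching to an exact conditional (Fisher) test when any expected cell
is below 5; for tables larger than 2×2 the exact test enumerates all tables
with the observed margins under the multivariate hypergeometric null
(feasible precisely in the small-count regime that triggers it; verified
against R's `fisher.test` and scipy's 2×2 implementation). Under null
simulation with three identical arms the dispatcher's type-I error is close
to the nominal 5 % (checked over 1000 replicates in the test suite).

The variability–infection relationship is a Pearson correlation between
per-arm GV summaries and per-arm infection rates. With three arms this is an
n = 3 correlation with a single degree of freedom for the t transform; it is
a procedure check, not an inferential workhorse, and every report row
carries the "group-level, n=3" flag. "Adjusted for time" is interpreted as
correlating time-normalized rates (already per-1000-ventilator-days); no
further adjustment is applied. A repeated-measures GLM over time points is
deliberately out of scope; per-window summaries plus the tests above replace
it.

Report tables round half-up at the configured precision (default 2
decimals), via decimal arithmetic rather than banker's rounding.

## Synthetic trial generator

The generator emulates the monitoring and exposure structure the analysis
assumes; it makes no mechanistic claim about how formula composition alters
glycemia — arm differences are encoded directly as variability/set-point
parameters.

**Randomization.** Center-stratified blocks of six (2:2:2). Patients are
spread across centers as evenly as possible; each center receives complete
shuffled AABBCC blocks, and the incomplete tails draw from a shuffled global
remainder pool constructed so per-arm totals equal the configured sizes
(52/53/52 by default). Within every complete block the 2:2:2 balance is
exact.

**Glucose.** Each patient's latent glucose is a discretized
Ornstein–Uhlenbeck process — the simplest process with independently tunable
mean, stationary variance and autocorrelation, the three properties the
lability index responds to. The patient's set-point is drawn around the arm
set-point (between-patient SD); the process reverts toward set-point minus
`insulin_sensitivity` × current infusion rate (a linear steady-state
depression: a minimal closed loop that exercises the protocol engine, not a
PK/PD model). Readings occur at uniform random 1–4-h intervals, add
glucometer noise, are floored at 20 mg/dL, and are never emitted inside
interruption windows. The insulin trace is produced by running the same
protocol engine the analysis uses, so simulated feedback and accounted
insulin are identical by construction.

**Default calibration** (`data/trial_arms.yaml`) targets the published
operating characteristics of the three-arm trial this pipeline is built
for: arm set-points 155/162/157 mg/dL with within-patient SDs 40/60/40 and
a 2 IU/h protocol ceiling give observed arm means near 146/155/150 mg/dL
and daily insulin near 26 IU/day; respiratory hazards 15.2–25.5 per 1000
ventilator-days and exposure lognormals reproduce the published
ventilator/ICU/EN-day medians; mortality is Bernoulli at the published
28-day and 6-month proportions (6-month death is forced consistent with
28-day death). These are calibration targets, not ground truth. Between-
and within-patient spread, reversion 0.25 h⁻¹ and 5 mg/dL meter noise are
the package's own choices of realistic magnitudes where the source reports
none.

**Infections.** Counts are Poisson with mean hazard × exposure/scale —
ventilator-days for respiratory kinds, ICU-days for catheter/primary
bloodstream and urinary infections — with onsets uniform over the exposure
beyond the 48-h acquired cutoff; a patient whose exposure ends before 48 h
cannot acquire an event.

**Determinism.** All randomness flows from one integer seed; each patient
uses a sub-stream keyed by enrolment index, so datasets are byte-identical
under a repeated seed and stable under patient re-ordering.

**What the simulator does not capture** — and hence what passing tests do
not show about real data: meal/feed-cycle periodicity, nurse-driven
measurement timing (more checks when unstable, which correlates sampling
with lability), diabetic subpopulation dynamics, center effects beyond
stratified allocation, and any mechanistic link from formula composition to
glycemia. Simulated per-day GLI magnitudes are accordingly higher than the
published medians (an OU process with a 4-h decorrelation time is rougher
between checks than smoothed physiological glycemia); the GLI's correctness
is therefore established by algebraic invariants and an independent
pairwise-loop oracle, not by reproducing published group GLI values, which
depend on unavailable patient-level data.

## Problem sizes and numerical checks

The test suite validates the vectorized GLI against the naive oracle on
1000 random irregular series (agreement within 1e-10) and its shift-
invariance, quadratic scaling about the mean, and gap-halving/doubling
identities at relative tolerance 1e-9. Parameter recovery runs at 500
patients/arm on a dedicated recovery design whose set-points sit below the
insulin trigger with zero feedback gain — with feedback on, the operating
mean is depressed below the set-point by construction, so "recover the
set-point" is only well-posed without it. Recovery asserts arm means within
2 SE and tracheobronchitis counts within exact Poisson 95 % intervals of
the configured hazards. Null calibration of the comparison dispatcher uses
1000 three-identical-arm replicates at n = 20/arm. The acceptance script
simulates the full default design (157 patients, 28-day horizon) in a few
seconds.
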