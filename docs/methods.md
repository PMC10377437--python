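# Methods

`pvrisk` re-creates, on synthetic cohorts, an analysis pipeline for
thromboembolic-event (TE) risk in polycythemia vera (PV) patients starting
hydroxyurea (HU): period-aligned annualized incidence with propensity
matching, a random survival forest (RSF) with log-rank splitting and
drop-column importance, pairwise synergy screening, a two-variable threshold
"risk landscape" search, and fixed-threshold external validation. This note
records the models, conventions, parameter choices and known limitations.

## Data model and conventions

A patient record carries demographics, a TE-history flag, anticoagulant/
antiplatelet use, pre-summarized laboratory and observation medians from the
3–6-month post-index feature window, treatment-course dates and TE event
times. Conventions:

* Dates are integer day offsets from an arbitrary per-cohort epoch; months
  convert at 30.4375 days. The feature window "3–6 months post-index" is the
  half-open day interval [91, 183); the prediction window "6–18 months" is
  [183, 548). Month boundaries are a declared convention — inclusive vs
  exclusive month edges are not externally fixed.
* Missing lab/observation medians are represented as absent (`None`/`NaN`),
  never zero; absence propagates through every stage.
* All analysis periods are half-open `[start, end)`, including the
  ruxolitinib switch period; person-time arithmetic is unaffected and event
  counting at the exact closing day is measure-zero under the continuous-time
  generator.

## Synthetic cohort generator

The generator emulates an abstracted HU-treated PV cohort so that every
downstream stage is testable without restricted EHR data.

* **Continuous variables** (7 labs, 8 observations) are log-normal with
  parameters solved from target median and IQR: mu = ln(median),
  sigma = ln(q3/q1)/1.349. Neutrophil (NEP) and lymphocyte (LYP)
  percentages share a Gaussian copula with rho = −0.8 — they are
  complementary parts of the differential count. Percentage-scale variables
  are capped at 100. Age is truncated normal on [30, 97].
  Discovery-cohort lab targets (e.g. NEP 70 (62–78), LYP 19.5 (13.0–26.3),
  RDW 17.0 (14.5–19.3), age 73 (64–80), TE-history prevalence 0.161) follow
  the published characteristics of a large US EHR model-development cohort;
  the validation defaults (NEP 68, LYP 22, RDW 16.0, age 65, TE-history
  0.32, n = 100) follow the published characteristics of an independent
  community registry. No published median/IQR exists for the observation
  medians (BMI, blood pressures, weight, height, heart rate, respiration,
  pulse); their defaults are realistic values for an elderly US cohort,
  chosen once and recorded in the truth sidecar.
* **Events** follow a homogeneous Poisson process per period. Pre-index rate:
  `baseline_hazard * exp(b_hist * te_history)`; post-index rate:
  `baseline_hazard * exp(lp)` with
  `lp = 0.9*te_history + 0.2*anticoag + 0.1*(age-73)/10 + 0.8*Q1 + 0.8*Q2`,
  where Q1 = (NEP >= 72.05 and RDW < 14.3) and Q2 = (LYP < 19.3 and
  RDW < 14.05) are the planted threshold interactions. Quadrant indicators
  use true (pre-missingness) values: missingness is an observation mask, not
  biology. The default baseline hazard is 0.087 events per patient-year
  (≈ 8.7 per 100 patient-years pre-index). The TE-history *flag* is drawn at
  the target prevalence as a patient trait (chart-recorded history predating
  the record); pre-index event counts correlate with it through the hazard.
* **Censoring** is administrative at record_end = index + min(administrative
  follow-up, exponential dropout), follow-up lognormal (median 4 years,
  sigma 0.4; 6 years for the validation registry), dropout 0.05/year.
* Poisson counts are drawn through the quantile function applied to
  per-patient uniforms, so raising an effect size under a fixed seed re-uses
  common random numbers and can only increase per-patient event counts
  (used by the monotonicity property test).

What the generator does **not** emulate: longitudinal visit structure,
informative missingness (in the real data, *having* labs in the feature
window was itself a risk marker), treatment adherence, calendar effects and
competing risks. Passing tests therefore demonstrate correctness of the
*methods* on data with known structure, not clinical performance on real
cohorts.

## Survival primitives

Kaplan–Meier and the k-group log-rank test are implemented directly on
numpy arrays (the RSF split search needs a batched two-group statistic far
faster than per-call library functions; the batched path accumulates in
float32, agreeing with the float64 reference to ~1e-5 relative). The
log-rank uses the standard hypergeometric mean and tie-corrected variance at
each distinct event time, chi-square reference with (groups − 1) df; subjects
censored at an event time remain in that time's risk set. Results are
cross-checked in the test suite against lifelines and against a brute-force
accumulation oracle on small instances.

## Random survival forest

* Trees are grown on 63.2% subsamples drawn **without** replacement;
  at each node `ceil(sqrt(k))` random features are tried over up to 24
  quantile-based candidate cutpoints each, maximizing the two-group log-rank
  chi-square; splits must leave at least 3 events in each child; depth is
  unlimited. These are conventional RSF settings at cohort sizes of
  1,000–2,000; no external hyperparameters are prescribed.
* Missing values route down the child that received more training samples
  ("majority direction") — deterministic and surrogate-free.
* A terminal node's value is its training samples' Nelson–Aalen cumulative
  hazard over the prediction horizon; a patient's risk score is the tree
  average, and out-of-bag (OOB) scores average only trees not containing the
  patient.
* The outcome is time from the feature-window end (day 183 post-index) to
  the first TE within a 12-month horizon. The published threshold analysis
  targets "TEs within 12 months" while the model window is 6–18 months
  post-index; this package reads the two as the same interval measured from
  the feature-window end and exposes `horizon_days` as a parameter.
* Evaluation is the Mann–Whitney ROC-AUC of OOB scores against the binary
  label "at least one TE in the window", restricted to patients whose
  follow-up covers the horizon (or who had an event). A single reported AUC
  for a fixed window, rather than a time-dependent AUC, matches how the
  performance figure this package echoes was defined.
* Variable importance is **drop-column**: refit without each variable (same
  seed) and score the OOB-AUC degradation; ties break alphabetically. A
  permutation-importance mode is provided for comparison. The default
  feature list has 15 entries (TE history, anticoagulant use, age, 7 labs,
  BMI, DBP, SBP, weight, heart rate); height and the rarely-assessed
  respiration/pulse observations are excluded as redundant.

## Synergy screening

For a variable pair within a TE-history stratum: p1 and p2 are two-group
log-rank p-values at each variable's stratum median (binary flags split by
value); the expected significance is p1·p2; the observed significance is the
k-group log-rank over the four median quadrants; the synergy score is
expected/observed. Quadrants under 10 patients are dropped from the observed
test with a warning; fewer than two usable groups invalidates the record.
Raw p-values are reported (with a Bonferroni column for reference only),
matching the screening design this package reproduces.

Calibration note: under the null the score's median is ≈ 0.4 (the product of
two p-values is anti-conservative as a combined reference), and even with a
planted quadrant effect at non-median thresholds the median-split score
rarely exceeds ~5 — the four-quadrant grouping detects the interaction
(observed p ≪ 0.01) but the *ratio* stays moderate because the median split
dilutes an off-median quadrant and the marginal p-values absorb much of the
signal. Large scores of order 100 require interactions that are nearly
invisible marginally yet sharp at the medians, a structure the generator's
planted quadrants do not produce.

## Risk landscape and decision trees

Candidate thresholds default to each variable's 5th–95th percentiles in
steps of 2.5 within the analysis stratum. For each threshold pair the
default `risk_vs_rest` mode tests the designated risk quadrant against the
pooled remainder (two-group log-rank), matching a comparison of the named
risk group against "the other threshold groups" pooled; `four_group` mode
keeps all quadrants separate. Cells with a group under 10 patients are
absent. The matrix minimum gives the optimal threshold pair; ties break by
larger risk group, then lower thresholds. Risk directions are fixed to the
clinically established ones (NEP high, LYP low, RDW low) when supplied;
otherwise the quadrant with the worst KM survival at the horizon is
designated per cell. The selected minimum p is accompanied by an
event-label-permutation adjusted p (an addition beyond the original scan,
labelled as such in outputs) because the minimum over ~1,400 correlated
cells is optimistically biased. Decision trees are two-level threshold
rules: high risk iff both risk conditions hold; a patient missing either
value defaults to low risk. Fixed-threshold validation applies a tree
unchanged to an independent cohort and compares thrombosis-free survival
between leaves by log-rank over full follow-up.

## Incidence and matching

Periods per patient: pre-index [index−365, index); switchers: post-index
[index, first ruxolitinib), switch period over the ruxolitinib course;
non-switchers: post-index of length equal to the switcher cohort's median HU
course, then a no-switch period of the median ruxolitinib course length. All
periods truncate at record_end; records too short for the full pre-index
window are flagged out of that denominator. Incidence is annualized per 100
patient-years of period person-time with **all** events counted (the
standard person-time annualization; the original denominator definition is
not public). A first-event-only mode is provided behind a flag. Propensity
matching is a logistic model on total treatment time, sex, race, age and
region, then 1:1 greedy nearest-neighbour on the logit without replacement,
caliper 0.2 SD of the logit, ties and processing order by patient id — the
default behaviour of the common matching tools this emulates.

## Problem sizes and experiment design

Recovery and calibration experiments in the test suite use: threshold
recovery n = 2,000 × 20 seeds; drop-column importance n = 700, 60 trees ×
20 seeds (16 refits per seed); forest evaluation n = 2,000 with 200 trees;
type-I error 1,000 replicates at n = 100; estimator bias at n = 5,000;
external validation n = 300 × 20 seeds. These sizes make the planted
structure statistically identifiable while keeping the full suite fast on a
single CPU.

## Known limitations

* The generator's planted effect sizes give a Bayes-optimal windowed AUC of
  about Phi(sd(lp)/sqrt(2)) ≈ 0.65–0.70 (sd(lp) ≈ 0.56); no model can reach
  0.8 on these cohorts, so the forest's measured OOB AUC (~0.65) should be
  read against that ceiling, not against figures reported for real EHR
  cohorts with richer structure.
* Drop-column importance divides credit among correlated variables: with
  the NEP–LYP copula at rho = −0.8 the two percentages shade each other, and
  RDW — present in both planted interactions — outranks the TE-history main
  effect in roughly half of replicates. Rank-based recovery claims should be
  interpreted accordingly.
* The landscape argmin over ~1,400 correlated cells has substantial sampling
  variability at n = 2,000 and planted log-HR 0.8: recovered thresholds
  scatter over a few grid steps (and are pulled toward the second, overlapping
  planted quadrant), which the permutation-adjusted p is designed to expose.
* Confidence intervals for incidence rates are not computed (bootstrap is
  left to the caller); competing-risks and weighted log-rank variants are out
  of scope.
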