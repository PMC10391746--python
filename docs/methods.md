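# Methods

This note documents the models, conventions and design choices behind the
package, in the order the pipeline applies them.

## Day and unit conventions

CAR-T infusion is day 0; all windows are closed integer intervals of study
days ([0, 30], [31, 100], [0, 60], [0, 90]). The start of lymphodepletion
is recorded per patient as its own (negative) day, and baseline labs carry
sample days relative to that start. Canonical units are ANC and platelets
in G/l (10⁹/l), hemoglobin in g/dl, CRP in mg/dl and ferritin in ng/ml;
per-µl counts are accepted only with an explicit unit column and divided by
1000 — magnitudes are never guessed. Missing values are empty cells, never
0, because 0 is a legal ANC. Same-day duplicate draws keep the minimum
value (the conservative choice for cytopenia endpoints) and are flagged in
the validation report.

## Score

The rubric is additive over five components; platelet bands are
implemented as ≤ 75 / (75, 175] / > 175 G/l and ferritin bands as
< 650 / [650, 2000) / ≥ 2000 ng/ml, which reproduce the printed integer
bands exactly while leaving no undefined gap for non-integer values. The
leniency window is *before or at* the start of lymphodepletion
(days −3…0 relative to the start); values after the start of chemotherapy
are never scored under the default window, since the score is defined on
pre-lymphodepletion labs. A symmetric ±3-day window is available as an
option. For each analyte the draw closest to the start wins, ties broken
toward the later draw. The default missingness policy is strict (error);
a zero-points policy exists for exploratory use and always flags the
imputed analytes in its output.

## Trajectory metrics

Lab series are expanded onto an integer daily grid by last observation
carried forward (LOCF), with no backfill before the first draw; unknown
days never count toward any threshold. LOCF is the standard conservative
rule for inpatient labs; because the counting rule between draws is a
modelling choice, a measured-days-only mode is provided for sensitivity
analysis. Consecutive-day requirements (≥ 7, ≥ 14 days) are maximal runs
on this grid. The phenotype decision order is: aplastic (any run of ≥ 14
consecutive days with ANC < 0.5 G/l), else intermittent (a day with
ANC > 1.5 followed by a later day ≥ 22 with ANC < 1.0), else quick — so
the classes partition every classifiable trajectory and aplasia, the
clinically dominant pattern, takes precedence. "After day 21" is read
strictly (day ≥ 22) for the intermittent dip, while "measured ≥ 21 days
after CAR-T" gives day ≥ 21 for the prolonged flag, mirroring each phrase
literally. Recovery for the intermittent rule must precede the dip but is
not required to precede day 21. Trajectories whose last draw falls before
day 21 are classified with a low-confidence flag rather than rejected.

## Infections

Events carry onset day (day of the diagnostic test), category, source and
a 5-grade severity; grade ≥ 3 is severe. Neutropenic fever alone is not an
infection event and is dropped (and flagged) on read. Per-patient flags
derive only from events with onset in days 0–90; all events stay in the
descriptive tallies. Cumulative incidence is one minus the Kaplan–Meier
estimator of time to first qualifying event, censoring at death or the
horizon; death is treated as censoring rather than a competing event so
that the curves match the log-rank comparison applied to them. The
Aalen–Johansen machinery in `stats` can be used instead when a
competing-risks treatment is wanted; with meaningful pre-90-day mortality
the censoring variant overstates incidence.

## Survival and discrimination statistics

* **Kaplan–Meier**: product-limit estimator via lifelines with
  Greenwood-type (log–log) confidence intervals. The median is the
  smallest time with S(t) ≤ 0.5; when the curve sits exactly at 0.5 over a
  flat stretch, the midpoint between reaching 0.5 and dropping below it is
  reported, so a 4-death curve at times 1–4 has median 2.5.
* **Log-rank**: hypergeometric expected counts at each distinct event
  time; an exact mode enumerates all group relabelings (practical to a
  pooled n of about 12) and reports the fraction of relabelings with a
  statistic at least as large.
* **Non-relapse mortality** (death without prior progression) uses the
  Aalen–Johansen estimator with progression-related death as the competing
  cause; at every time the event-free probability and the cause-specific
  incidences sum to 1. Group comparison defaults to a cause-specific
  log-rank; the 1 − KM variant is available through `km_fit` directly.
* **Cox**: lifelines partial likelihood with Efron tie handling and Wald
  intervals; constant or collinear covariates and non-convergence raise
  errors rather than returning unstable estimates. The multivariable
  specification uses five binary indicators: eGFR < 60 ml/min, LDH above
  the upper limit of normal, ECOG ≥ 2, bone-marrow plasma-cell
  infiltration > 50%, and HT-high.
* **Logistic regression** (aplastic phenotype, severe infection):
  statsmodels maximum likelihood with Wald intervals; perfect separation
  raises an error.
* **ROC**: AUC is the tie-corrected normalized Mann–Whitney U (ties count
  half), with the operating point chosen by Youden's J and a p-value from
  the normal approximation to U. Higher scores must indicate the positive
  class; direction is enforced, not auto-detected.
* **Group tests**: Mann–Whitney with a tie-corrected normal approximation,
  switching to exact enumeration of all group assignments for combined
  n ≤ 12 (the permutation convention handles ties without a correction
  formula); Fisher's exact test is two-sided by summing hypergeometric
  probabilities no larger than the observed table's. No multiple-testing
  adjustment is applied anywhere; p-values are reported raw.

## Synthetic cohorts

The generator's defaults are **calibrated, not estimated**: published group
summaries pin the targets, and the remaining free parameters are set once
to values that reproduce them.

* **Strata and labs.** A latent stratum (low with probability 0.558 =
  63/113) drives the baseline-lab draws: log-normal for ANC, platelets,
  CRP and ferritin, normal for hemoglobin, located at the published group
  medians (low: ANC 2.95 G/l, Hb 11.6 g/dl, platelets 181 G/l, CRP
  0.45 mg/dl, ferritin 86 ng/ml; high: 1.77 / 8.5 / 63 / 1.02 / 811).
  The log-scales are free calibration parameters chosen so that about 95%
  of latent-high patients score ≥ 2 and the overall low fraction stays
  near 55.8%; the realized latent-vs-computed crossover rate (typically
  3–4%) is reported by `calibration_report`.
* **Conditioning on the computed class.** Everything downstream — the
  trajectory, infections, survival, covariates — is conditioned on the
  risk class recomputed from the generated labs (or on the score itself),
  not on the latent stratum, because the study's strata are defined by the
  computed score. This is the package's own design choice; it makes the
  stratum-level targets exact by construction up to sampling noise.
* **Neutropenia duration.** Severe-neutropenia days follow a negative
  binomial with mean 2.0 + 2.48 × score (slope from the published
  duration-vs-score regression; intercept and dispersion r = 6 calibrated
  so the class medians land at 9 and 3 days) realized as one contiguous
  severe run starting near the nadir day, so a duration ≥ 14 days *is* the
  aplastic phenotype and generated trajectories reclassify consistently.
  Draws are daily through day 30 and around the severe run and any late
  dip, every 2–3 days otherwise, so the LOCF grid recovers the intended
  run exactly. Second dips (0.55–0.95 G/l, after day 25) occur with
  class-specific probability and create the intermittent phenotype.
* **Infections.** A patient acquires any infection with probability 0.58
  (high) / 0.23 (low) and, given that, a severe first event with the
  conditional probability that makes the marginal severe rates 40% and 5%.
  Onset days are drawn from a daily weight over days 0–90 that is 5-fold
  elevated while ANC < 0.5 G/l — a discrete hazard tied to concurrent
  neutropenia that leaves the marginal rates exact. A second, mild event
  occurs with probability 0.16 (matching 51 events in 44 patients).
* **Survival.** Time to non-relapse death is exponential with the rate
  implied by the 1-year NRM targets (12.7% / 2.1%); time to progression is
  exponential with the residual rate so that PFS medians are 5.4 / 14.9
  months; post-progression survival is exponential with median
  os_median − pfs_median. The low-group OS median "not reached" is
  emulated with a 60-month median, and everyone is administratively
  censored at 12 months, matching the 1-year estimates. At that follow-up
  the low-group PFS/OS KM medians are legitimately not reached, and the
  high-group OS median sits at the censoring boundary — medians beyond
  ~12 months are not identifiable in the default configuration.
* **Covariates, responses, support events** are drawn from class-specific
  categorical/Bernoulli distributions matching the published frequencies
  (ECOG ≥ 2 only in the high class, BM > 50% in 42% vs 11.1%, ≥ VGPR in
  44% vs 70%, transfusion and growth-factor rates from the toxicity
  tables). CRS/ICANS grades are recorded covariates, not modelled
  pathophysiology.

### What the generator does and does not emulate

It reproduces the stratified marginal structure the analysis consumes:
group-wise lab distributions, duration-score coupling, infection rates tied
to neutropenia, and group-specific survival with competing causes. It does
not emulate center effects, time-varying hazards beyond the piecewise
construction, correlated multi-lineage cytopenia dynamics, infection-death
coupling (fatal grade-5 events are drawn independently of the survival
process), or calendar-time accrual. Passing end-to-end tests therefore
demonstrates that the pipeline recovers the quantities it is pointed at
under the stated generative assumptions — not that the score generalizes
to any real cohort.

## Problem sizes

The end-to-end checks use ten cohorts of 1000 patients (class medians and
rates stabilize well below Monte-Carlo tolerances at that size), and the
regression-recovery checks use 200 replicates of n = 5000 with a 5%
log-scale bias bound; both sizes are the package's own choice of a
desk-scale experiment.

## Known limitations

* LOCF day-counting is a convention, not ground truth; between sparse
  draws the true severe duration is interval-censored. The measured-days
  mode brackets the answer from below.
* The cumulative-incidence default (censor at death) overstates infection
  incidence when pre-90-day mortality is non-negligible.
* Cox/logistic inference is Wald-based; profile-likelihood intervals are
  out of scope.
* The generator's lab log-scales are identified only up to the published
  medians and rubric-crossing behaviour; they are calibration defaults,
  not estimates of any real distribution.
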