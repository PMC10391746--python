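# hematotox

Risk stratification of hematological toxicity and infections after
BCMA-directed CAR T-cell therapy (ide-cel, cilta-cel) in relapsed/refractory
multiple myeloma, built around the **CAR-HEMATOTOX (HT) score**.

The package is aimed at biostatisticians and CAR-T researchers who want a
tested, reusable implementation of the full analysis path: score
computation from pre-lymphodepletion labs, neutrophil-trajectory endpoints,
day 0–90 infection endpoints, survival and discrimination statistics, and a
calibrated synthetic-cohort generator so every stage runs end to end with
no patient data.

## The score

Five labs are drawn before the start of lymphodepleting chemotherapy (with
a leniency window of up to three days before the start):

| component | 1 point | 2 points |
|---|---|---|
| ANC | ≤ 1.2 G/l (1200/µl) | — |
| hemoglobin | ≤ 9.0 g/dl | — |
| platelets | 76–175 G/l | ≤ 75 G/l |
| CRP | ≥ 3.0 mg/dl | — |
| ferritin | 650–2000 ng/ml | ≥ 2000 ng/ml |

The total ranges 0–7; a score ≥ 2 defines the high-risk stratum
(HT-high), 0–1 low risk (HT-low). Downstream endpoints follow the study
definitions: cumulative days with ANC < 500/µl in days 0–60; recovery
phenotypes *quick* (sustained recovery), *intermittent* (recovery above
1500/µl followed by a second dip below 1000/µl after day 21) and *aplastic*
(continuous ANC < 500/µl for ≥ 14 days); grade ≥ 3 infections in days 0–90;
Kaplan–Meier PFS/OS with log-rank and Cox models; and non-relapse mortality
as an Aalen–Johansen competing-risks estimate.

## Worked example

Scoring one patient (`examples/01_score_a_patient.py`):

```
component points: ANC=1 Hb=1 platelets=2 CRP=0 ferritin=1
total = 5  ->  risk class: high
```

ANC 1.1 G/l, hemoglobin 8.7 g/dl and platelets 68 G/l each score, the
ferritin of 900 ng/ml adds one more point, and the patient lands well above
the high-risk cut of 2.

Comparing strata on a simulated cohort of 600 patients
(`examples/04_outcome_statistics.py`):

```
HT-low: n=322, PFS events=142, median PFS not reached
HT-high: n=278, PFS events=221, median PFS 5.7 months
log-rank PFS: chi2=84.7, p=3.4e-20
univariate Cox HR (high vs low): 2.62 [95% CI 2.12-3.24]
1-year NRM, HT-low: 1.9%
1-year NRM, HT-high: 8.3%
90-day severe-infection incidence, HT-low: 5.9%
90-day severe-infection incidence, HT-high: 44.9%
```

The high stratum shows shorter progression-free survival, elevated
non-relapse mortality and a much steeper severe-infection curve — the
orderings the score is designed to capture. The other example scripts
cover trajectory classification (`02`) and generator calibration (`03`).

A command-line entry point wraps the same library calls:

```bash
hematotox simulate --n 500 --seed 42 --out cohort/
hematotox score --cohort cohort/ --out scores.csv
hematotox run-all --cohort cohort/ --out results/
```

## Layout

- `src/hematotox/cohort.py` — data model and the four-file CSV cohort format
- `src/hematotox/score.py` — rubric, leniency selection, cohort scoring
- `src/hematotox/trajectories.py` — daily LOCF grid, neutropenia metrics, phenotypes
- `src/hematotox/infections.py` — infection flags, tallies, cumulative incidence
- `src/hematotox/stats.py` — ROC, KM/log-rank, Aalen–Johansen, Cox, logistic, group tests
- `src/hematotox/simulate.py` — calibrated synthetic-cohort generator
- `src/hematotox/report.py`, `cli.py` — pipeline orchestration and CLI
- `docs/methods.md` — modelling assumptions, conventions and limitations
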