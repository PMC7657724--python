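# Methods

## Symptom catalog and severity grading

The questionnaire tracks 18 symptoms chosen for their relevance to
immune-related adverse events of anti-PD-(L)1 therapy. Each symptom block in
`src/eprowatch/data/symptom_catalog.yaml` declares its question items
(boolean, ordered category, or bounded count) and an ordered,
first-match-wins rule table mapping a complete answer vector to an NCI-CTCAE
v4.03 grade. The catalog is data, not code: clinical review can amend
prompts, domains, and rule tables without touching the grading engine, and
the engine enforces the structural contracts at load time (a `present`
item exists, no rule exceeds the symptom's `max_grade`, the last rule is a
catch-all so grading is exhaustive and deterministic).

Grading conventions:

- "Not present" always maps to grade 0, and follow-up items are then not
  required — mirroring a real form where follow-up questions are skipped.
- Severity is ordered within every answer domain (booleans: true is worse;
  counts: larger is worse; categories: later levels are worse), which makes
  monotonicity — worsening any single indicator never lowers the grade — a
  testable property; the suite sweeps every symptom's full finite domain.
- Criteria a patient cannot self-report (laboratory values, transfusion or
  tube-feeding indications) are excluded, so most symptoms cap at grade 3;
  shortness of breath keeps grade 4 ("so severe that urgent help was
  needed" is self-reportable). The test suite carries an independently
  hand-coded statement of the CTCAE criteria and checks the rule tables
  against it point by point.

The instrument this models was described as having 17 questions while
tracking 18 symptoms (likely a combined blood-in-stool/blood-in-urine
question); the catalog implements all 18 blocks, since every downstream
output table is per-symptom over these 18.

## Urgency algorithm

A graded questionnaire alerts when any symptom satisfies
`grade >= 3` (absolute rule) or `previous == 0 and grade >= 2` (jump rule),
where `previous` is the same patient's most recent prior questionnaire.
Two open choices were resolved conservatively and are configurable via
`AlertConfig`:

- the jump reference is the *most recent prior* questionnaire, not the
  baseline, because the rule describes an increase in severity;
- with no prior questionnaire the implicit reference grade is 0, so a first
  report at grade 2 alerts — the patient-safe default.

One decision is issued per questionnaire and lists every triggering symptom,
so by-symptom trigger counts can exceed the number of alerting
questionnaires. Etiology is a manual annotation (cancer / treatment /
unclear), never inferred.

## Scheduling and compliance

Follow-up runs in 7-day cycles from treatment-phase entry until
discontinuation or 6 months. Each cycle opens with a prompt; if the
questionnaire is not answered on the prompt day, one reminder follows per
day (at most 6), stopping at the first answer. Week *w* covers days
[7(w−1), 7w) after the patient's start date; the baseline questionnaire is
week 0 and is excluded from weekly series. Compliance in week *w* is the
number of answered week-*w* questionnaires divided by the number of
patients whose follow-up window overlaps week *w* — the "active" definition
keeps early terminations from deflating the mean, and since several
questionnaires per week are possible the mean can exceed 1. Calendar
arithmetic is whole days; no time zones.

## Generative cohort model

The simulator is intentionally the simplest longitudinal model able to
reproduce the marginal structure the analysis consumes:

- **Symptom course.** Per patient and symptom, a two-state weekly Markov
  chain with onset probability *o* (absent → present) and persistence *q*
  (present → present); when present, the grade is a categorical draw over
  grades 1–4. Default *q* = 0.6 for all symptoms; *o* is back-solved from a
  target stationary prevalence *p\** = *o*/(1 + *o* − *q*), with per-symptom
  *p\** and severity mixes taken from the observed grade-distribution table
  (e.g., fatigue *p\** = 0.40 with severity mix 0.70/0.275/0.025/0;
  blood in stool and hematuria have *o* = 0).
- **Benefit effects.** Patients are labeled CR/PR/SD ("clinical benefit")
  with probability 22/34, else PD. Benefit multiplies the itching onset
  *odds* by 3.0 (default). PD adds an independent Bernoulli(min(1, δ·w))
  increment to the chest-pain grade in week w with drift δ = 0.03/week, so
  the mean PD chest-pain grade rises linearly — approximately 0 → 0.36 over
  12 weeks, the magnitude of the published trajectory table.
- **Adherence.** The weekly questionnaire is answered on the prompt day
  with probability 0.6, otherwise on each reminder day with hazard 0.2,
  giving an overall weekly answer probability of ≈ 0.895 — the order of the
  observed weekly means. The baseline questionnaire is always answered.
- Default cohort size 37 and follow-up 24 weeks match the study arm; the
  tumor mix is 15:9:9:4 (lung:melanoma:genitourinary:head-and-neck).

All draws flow from a single `numpy` `default_rng(seed)`, so identical
parameters and seed reproduce the cohort bit for bit.

What the simulator does **not** model: treatment mechanism or pharmacology,
survival, symptom–symptom cross-correlation beyond what shared benefit
labels induce, informative missingness (adherence is independent of symptom
state), and within-week repeat questionnaires. Tests passing on simulated
data therefore demonstrate correctness of the pipeline's accounting and its
ability to recover *injected* structure — not clinical validity on real
patients.

## The deterministic study fixture

`build_study_fixture()` constructs one concrete 37-patient cohort whose
pipeline outputs equal the published counts: 889 answered questionnaires
(37 baselines), 391 in weeks 1–12, exactly 67 of which alert under the
urgency rule with the published by-symptom trigger multiset (sum 184) and
etiology mix 38/21/8; per-symptom grade totals whose bucket percentages
round to the published distribution; itching reported by 14/22 benefit vs
4/12 PD patients and chest pain by 7/12 PD vs 4/22 benefit; weekly
compliance extremes 47/37 = 1.27 (week 1) and 21/36 = 0.583 (week 23); and
the 31-respondent experience survey table.

The published weekly compliance means, the 889 total, and the 391
first-12-week count are not jointly realizable by any integer assignment
(the weekly means for weeks 13–24 admit at most ≈ 340 questionnaires for
≤ 37 patients, far below the ≈ 460 the totals require; the week-13 mean
0.991 has no representation n/a with a ≤ 37 at the printed precision). The
fixture therefore prioritizes the exactly quoted quantities — totals, alert
arithmetic, compliance extremes — and realizes the remaining weekly counts
as close to the printed means as integers allow, with the surplus placed in
weeks 25–26 of the six-month window at one questionnaire per patient-week.
Similarly, grade-0 percentages are reported as 100 minus the nonzero
buckets wherever the published row sums to 99 or 101, and the nausea row
follows the internally consistent text fractions rather than the
(inconsistent) printed table row.

Within weeks 1–12 the fixture concentrates all nonzero grades on the 67
alerting questionnaires (jump triggers are grade-2 reports whose
predecessor is symptom-free; absolute triggers are grade 3); the remaining
grade stock lives in weeks 13–26. This is one of many assignments
consistent with the published marginals; the construction is deterministic,
involves no randomness, and validates its own invariants while building.

## Analysis conventions

- **Observation units.** Symptom–symptom correlations use one observation
  per answered questionnaire (18 grade columns). Benefit correlations use
  one observation per evaluable patient — benefit indicator (1 = CR/PR/SD,
  0 = PD) against the patient's mean symptom grade over the window — so the
  published negative chest-pain/benefit correlation keeps its sign. Both
  windows (weeks 1–12 and full follow-up) are supported.
- **Pearson matrices** are computed with pandas (`DataFrame.corr`), with
  per-cell complete-case counts; zero-variance columns and pairs with fewer
  than two complete cases yield NaN markers, never a silent 0. The test
  suite checks the implementation against a direct sum-formula oracle to
  1e-12.
- **Effect sizes** classify |r| with boundaries inclusive to the stronger
  class: ≥ 0.5 large, ≥ 0.3 medium, ≥ 0.1 small, else negligible.
- **Tables** round to whole percentages (the machine outputs keep full
  precision); grade buckets are {0, 1, 2, 3–4}; trajectory bins default to
  2 weeks; heat maps use a diverging red–blue palette (red negative, blue
  positive).
- The exact published correlation magnitudes (0.23/0.25 itching,
  −0.41/−0.47 chest pain) depend on the unavailable raw data and on an
  unstated observation unit; the package checks their *signs* and
  effect-size *classes* on calibrated simulations instead. The published
  "all 12 weeks" row of the trajectory table is likewise not recomputable
  from the printed information and is not a target.

## Problem sizes and numerics

Stochastic checks run at n = 1000–2000 patients with fixed seeds (a
cluster-level 3-standard-error criterion for parameter recovery, sign-level
checks for the injected benefit effects); exhaustive oracles cover every
point of each symptom's finite answer domain and all 25 (previous, current)
grade pairs of the alert rule. The full suite and the acceptance script
each complete in well under a minute on a single CPU. Dataclasses with
explicit validation are used for the domain types; file formats are
UTF-8 CSV (ISO dates, 1-based week indices), YAML for catalogs and
simulation parameters, JSON for reports.

## Known limitations

- The CTCAE rule tables are a faithful but necessarily interpretive
  patient-reportable restriction of the clinical criteria; the original
  instrument's wording is proprietary and was not published.
- The fixture reproduces published *marginals*, not the (unavailable) raw
  trajectories; correlation magnitudes computed on it are not meaningful.
- The simulator's independence assumptions (across symptoms, and between
  adherence and symptom state) are simplifications; both are isolated
  behind `SimulationParams` so richer models can be swapped in.
- No inferential statistics (p-values, multiplicity control) are provided,
  and no survival analysis — neither is part of the monitoring design.
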