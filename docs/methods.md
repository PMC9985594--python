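# Methods

## Problem and scope

UK primary-care databases record oral corticosteroid (OCS) prescriptions
for asthma without stating whether a script is an acute burst or part of
maintenance therapy. The package implements (i) a rule-based classifier
that labels each OCS script *intermittent* or *long-term* from the most
definitive information available, (ii) a whole-follow-up sequencing of
intermittent courses into gap-category patterns, (iii) cohort construction
with explicit attrition accounting, (iv) stratified summaries with
chi-square association tests, and (v) a synthetic-data generator used for
validation. Real source databases are access-restricted, so all empirical
checks run on synthetic cohorts or on arithmetic over bundled published
table counts.

## Cohort construction

The index date is the patient's first OCS prescription (patients with no
OCS ever form a separate non-OCS arm whose reference date defaults to
registration start + 365 days; this arm is carried as a labeled output
only). Eligibility rules are applied in a fixed, logged order so the
attrition report is deterministic:

1. age at index ≥ 4 completed years;
2. an asthma event — diagnosis, consultation, or an asthma-therapy
   prescription (SABA, ICS, ICS-LABA, LTRA, LAMA, biologic) — within the
   concurrency window of the index date;
3. registration start at least 365 days before index (baseline);
4. chronic-condition exclusions: adults (≥ 18 at index) with any of the ten
   listed OCS-treated conditions (ankylosing spondylitis … respiratory
   cancer) ever recorded are excluded; minors only when such a diagnosis is
   concurrent with an OCS script.

All windows are whole days. "Within 3 months" is implemented as ≤ 91 days
and "12 months" as 365 days (configurable); month length is otherwise
undefined. For adults the condition-ever rule is the default because the
condition list is already restricted to OCS-treated diseases; a stricter
concurrency mode is available (`strict_adult_concurrency`).

Counts are conserved by construction: eligible + Σ(removed per rule) =
input patients, and the attrition log reports both.

## The stepwise classifier

Steps run in order instruction → dose → concurrent event → annual count;
the first decisive step fixes the label and is recorded as
`decision_step`. Later steps are never consulted after a decision, so
earlier steps shadow later ones — lowering a dose threshold can never
change an instruction-decided label.

* **Instruction.** An ordered rulebook (plain CSV: priority, regex,
  verdict) is matched case-insensitively; the first hit wins and free text
  never raises. The bundled defaults encode taper/duration phrases as
  intermittent and maintenance phrases as long-term.
* **Dose.** Daily dose is taken from the instruction (strength ×
  units/day) or, failing that, quantity spread over a parsed course
  duration; it is converted to prednisolone equivalents by the ratio of
  WHO ATC/DDD defined daily doses (prednisolone DDD = 10 mg is the
  anchor; the bundled table covers the common oral H02AB substances and is
  extensible). Defaults: ≥ 20 mg/day prednisolone-equivalent ⇒
  intermittent, ≤ 10 mg/day ⇒ long-term, strictly between ⇒ undecided.
  These cut-offs follow the NICE convention that adult acute courses are
  40–50 mg/day and typical maintenance ≤ 10 mg/day; they are package
  defaults, exposed in configuration and echoed in all outputs. Scripts
  with unknown substance or unparseable dose fall through to the next step
  rather than failing.
* **Concurrent event.** An LRTI or exacerbation within ± 14 days
  (symmetric window, configurable) implies an acute course.
* **Annual count.** Each remaining script is labeled by the number of
  still-undecided scripts in the trailing 365-day window ending at it
  (inclusive): ≤ 2 ⇒ intermittent, otherwise long-term. A rolling window
  is used instead of calendar years to avoid year-boundary artifacts.

The undecided-by-default design maximizes specificity for intermittent
use: anything plausibly maintenance ends up long-term. A patient is
`intermittent_only` iff every script is intermittent; only these patients
enter the pattern analysis. Classifying a patient with zero OCS scripts is
an error, not an empty answer.

## Pattern sequencing

Courses are distinct script dates (same-day scripts merge; no course
duration is imputed — gaps are measured between consecutive course start
dates because only start dates are reliably present). Gap categories:
frequent < 90 days, moderately frequent 90–181, infrequent 182–364,
sporadic ≥ 365; these partition the positive integers, verified
exhaustively. The detailed label is the set of categories present, named
longest-cycle-first ("Sporadic, infrequent and frequent"); single-category
patients are "<Category> only" (conventionally just "Sporadic" for the
sporadic-only row) and single-script patients "Once-only" — 16 labels in
all. Simplified: once-only (one script ever), frequent (any < 90-day gap
anywhere in follow-up), otherwise less frequent. Individual-script gaps,
not gaps between script clusters, drive the frequent rule.

## Stratifiers and summaries

All stratifiers are assessed in the 365 days strictly before the index
date (index day excluded). SABA fills band to 0 / 1–2 / ≥ 3; age bands are
half-open (child ≥ 4–< 12, adolescent ≥ 12–< 18, adult ≥ 18). The GINA
2020 step is derived from baseline therapy through a bundled, editable
rule table (biologic or high-dose ICS-LABA ⇒ 5; medium-dose ICS-LABA or
high-dose ICS ⇒ 4; low-dose ICS-LABA, medium-dose ICS or ICS + LTRA ⇒ 3;
low-dose ICS or LTRA ⇒ 2; SABA only ⇒ 1; nothing ⇒ no asthma medication).
ICS dose bands use beclometasone-equivalent µg/day (low ≤ 400, medium
401–800, high > 800) via a small product-equivalence table; scripts whose
units/day cannot be parsed get an "unknown" band and match only
band-agnostic rules. No published code mapping exists for this
derivation, so the rule table is data, not code.

Summary tables report n, percent of total, mean (SD) and median (IQR) of
per-patient prescription counts per detailed label, with "Any <category>"
super-rows defined by the most severe (shortest-gap) category present.
Percentages are rounded half away from zero to one decimal (implemented in
exact rational arithmetic; note that one published percentage cell, 31.5%
for 150,326/476,167, is not reproducible under this or nearest-even
rounding — the count identities are, and are what the acceptance script
checks). Quartiles use linear interpolation between order statistics
(numpy default). Association tests are Pearson chi-square without
continuity correction (scipy), df = (r−1)(c−1), with zero-margin rows or
columns dropped with a warning.

## Synthetic-data generator

Each simulated patient is assigned a role: eligible intermittent-only
(with a target gap pattern), a planted violation of exactly one
eligibility rule, a long-term OCS user, or a non-OCS-arm patient. Defaults
echo the published distributions: pattern mixture once-only 0.42, sporadic
0.14, infrequent 0.07, moderately frequent 0.06, frequent 0.19, mixed
sporadic+frequent 0.12; age bands 16/8/76% child/adolescent/adult; GINA
step mixture 13.8/25.1/32.0/18.4/8.7/2.0% for none/1–5; SABA bands
23.8/44.9/31.3%; 2% of patients per planted ineligibility reason, 5%
long-term users, 5% non-OCS arm. In strict mode (default) every gap is
sampled at least one day inside its category interval and every script
carries one feature decisive at a known step (a taper instruction, a
40 mg/day-equivalent dose, or a concurrent LRTI/exacerbation, mixed
40/40/20%), so ground-truth recovery is exact by construction; a
non-strict mode samples boundary gaps to exercise tie handling. Therapy
bundles per GINA step target map deterministically through the bundled
rule table (e.g. beclometasone 200 µg, two puffs twice daily ⇒ 800 µg/day
⇒ medium ⇒ step 4). A single seeded numpy generator drives everything;
identical configuration gives byte-identical CSVs.

What the generator does **not** emulate: dose variability and
non-canonical instruction text, adherence/stockpiling, clustered
exacerbation bursts, registration churn, co-medication beyond the therapy
bundles, and the real cohort's demographic or count distributions.
Passing recovery tests therefore demonstrate the pipeline's internal
correctness on decisive records, not classifier accuracy on real free
text.

A separate hand-written boundary fixture covers gaps 89/90/181/182/364/
365 days, same-day duplicates, ages 3/4/11/12/17/18 at index, an asthma
event exactly at the window edge, each exclusion condition once, and a
minor with a non-concurrent exclusion diagnosis.

## Validation problem sizes

The end-to-end recovery check runs at n = 2,000 patients (single fixed
seed; ~8,600 prescriptions) and the invariance suite across 100 seeded
cohorts of n = 25; both finish in well under a minute each on one core.
The acceptance script reuses the n = 2,000 setting with the caller's seed.

## Known limitations

* The instruction rulebook and dosing-text parser cover canonical UK
  phrasings; real free text is messier and the classifier's undecided
  fall-through will route unparsed scripts to the annual-count step.
* Dose thresholds, window lengths and the GINA rule table are informed
  defaults, not validated constants; all are configuration.
* The non-OCS arm is constructed and labeled but not analyzed further.
* Patterns are one whole-follow-up profile per patient; no time-varying
  trajectories, no linkage of patterns to exacerbation risk or adverse
  events.
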