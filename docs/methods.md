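# Methods

This note documents the rules each engine implements, the parameters that
matter, what the synthetic generator does and does not emulate, and the
design choices made where the problem was genuinely open.

## Common data model

The CDM is nine typed tables (patients, care trajectories, diagnoses,
prescriptions, laboratory results, admissions, imaging reports, stem-cell
transplants, registry extract) serialized as UTF-8 CSV (canonical) or
JSON-lines, with ISO-8601 dates. All dates are pure calendar dates except
laboratory and report timestamps; nothing is timezone-aware. Identifiers
are opaque strings and birth is recorded as a year only — enough for adult
age-band composition while keeping the synthetic data free of anything
resembling direct identifiers. A missing prescription end date means a
single administration on the start date. Loading is strict about
row-level impossibilities (an end date before a start date is a parse
error naming the row); everything else surfaces as validation *issues*
(severity, table, row, message) so that a dirty extract can still be
inspected.

## Inclusion engine

A candidate case is one (patient, tumor group) pair whose earliest care
trajectory start — taken as the initial contact — is at least **28 days**
(four weeks, boundary included) before the decision date, so that the
diagnostic work-up has had time to complete. Classification applies the
registry criteria (new oncological diagnosis + Dutch residency) with a
fixed reason precedence:

1. `NON_RESIDENT` — `resident_nl` is false;
2. `RELAPSE_TRAJECTORY` — a confirmed diagnosis of the same tumor group
   predates the trajectory start (lookback unlimited within the dataset);
3. `PRELIMINARY_DIAGNOSIS` — no confirmed diagnosis exists by the decision
   date (only preliminary rows, or none);
4. otherwise include.

The precedence is a design choice: the three reasons are reported as a
flat frequency table in practice, but a single-valued reason is required
for exact scoring. A candidate with *no* diagnosis row is treated as
unconfirmed (reason 3), since inclusion requires a diagnosis.

Retrospective matching categorizes each registry record as
`matched_same_year` (a trajectory of the same patient and tumor group
starts in the registry's diagnosis year), `year_mismatch`, or
`diagnosis_mismatch`; a patient wholly absent from the CDM is a fourth,
flagged `absent` category — the generator never produces it, but a real
extract could.

## Regimen engine

* **Normalization.** ATC code → drug class via an editable mapping table.
  Dexamethasone, prednisone and prednisolone collapse into one shared
  `corticosteroid` class; this is forced by the observed
  lenalidomide–prednisone → Rd misread, which is only possible if the
  matcher cannot tell the steroids apart.
* **Episodes.** "Combined when given within the same week" is implemented
  as a greedy 7-day **half-open rolling window** anchored at the earliest
  unassigned oncology-class prescription, not as an ISO calendar week. A
  rolling window reproduces the documented D-Rd merge when two regimens
  co-start a few days apart across a calendar-week boundary; a calendar
  week would not. Prescriptions outside the mapping never enter episodes.
* **Matching.** The catalog entry whose drug-class set is the largest
  subset of the episode's class set wins; ties break toward the larger
  entry, then catalog file order. An episode whose only anti-myeloma class
  is lenalidomide is read as **lenalidomide maintenance iff the dose is
  ≤ 10 mg/day and no corticosteroid co-occurs, else Rd** — the threshold is
  set so that a 15 mg/day maintenance dose is (mis)read as Rd, the
  documented behavior; it is a configurable parameter
  (`maintenance_max_dose`). Whether the original split used dose, steroid
  co-prescription or both is underdetermined; this rule uses both.
* **Sequences.** Consecutive same-name episodes with a gap of ≤ 60 days
  (next start minus previous end) merge into one assignment, so that
  28-day cycles form a single regimen with start/end taken from the
  member prescriptions. The 60-day gap is a convention (config key), large
  enough to bridge cycle breaks and small enough to keep distinct lines of
  therapy separate. Transplants are event-based assignments
  (Auto-SCT/Allo-SCT, start = end = transplant date) taken from the SCT
  table, never from prescriptions.

The shipped MM catalog transcribes the standard anti-myeloma regimen
families (anti-CD38 quadruplets/triplets, PI+IMID, PI, IMID, bispecifics,
CAR-T, other, HSCT). "Trial medication" is carried as a `Trial` entry in
the bispecific block and "bridging therapy" as a cyclophosphamide-based
`Bridging` entry, since neither has a published composition. The AML
catalog is a starter file (7+3 variants, HMA-based, targeted, palliative,
HSCT) and is user-replaceable. ATC codes in the mapping follow the WHO
index where assigned; agents without a published code (iberdomide, trial
medication) carry clearly synthetic placeholder codes in the same format.

## Toxicity engine

One **attribution window** per patient: earliest treatment day to latest
treatment day + 30, truncated to the day before the first stem-cell
transplantation when that comes first (possibly emptying the window).
Overlapping courses merge into one window.

Four channels, each independently signaling a category:

* **lab** — absolute thresholds at CTCAE grade boundaries (bilirubin
  > 51 µmol/L ≈ 3× ULN, ALT > 200 U/L ≈ 5× ULN) or baseline-relative
  ratios (creatinine > 1.5× baseline ≈ grade-2 acute kidney injury);
  the baseline is the most recent value within 90 days before the window,
  and a relative rule without a baseline is skipped. A unit mismatch
  between rule and row is an error, not a silent skip. Each rule signals
  at its first in-window firing.
* **drug** — ATC trigger sets; a multi-drug set fires when all members
  co-start within 3 days, at the first in-window anchor. Trigger drugs
  are prescribed for many non-toxicity indications, so this channel has a
  designed false-positive path (exercised by generator noise).
* **keyword** — case-insensitive whole-word matching over imaging-report
  text, deliberately **negation-blind**: "no evidence of aspergillosis"
  signals. This preserves the known weakness of keyword scanning;
  NLP-based negation handling is out of scope.
* **admission** — listed ICD-10 codes as main or secondary diagnosis on
  any admission overlapping the window (signal date clamped into the
  window); the ICU category fires on the ICU flag.

Signals collapse into one finding per (patient, category) with the
earliest date and the union of channels; combination is idempotent and
order-invariant. The per-category thresholds, trigger sets, keyword lists
and ICD-10 lists shipped in `data/ctcae_rules.yaml` are labelled
reconstructions — plausible clinical defaults in an editable file, not a
published rule set. Channels are kept definitionally independent.

## Lab cross-validation

Items pair **exactly** on (patient, analyte, timestamp); value comparison
is exact numeric equality after a unit check, so single-digit typos and
decimal shifts are always caught. A timestamp typo surfaces as two
unpaired rows rather than a mismatch — documented behavior of the exact
key. The mismatch percentage is emitted three ways: exact, half-up at two
decimals, and a conservative ceiling-at-two-decimals display figure
(7/1,689 → 0.4144 % / 0.41 % / 0.42 %). The ceiling display exists because
half-up and printed figures can disagree at the second decimal; emitting
all three avoids silent disagreement.

## Scoring

All printed accuracies are positive predictive values: correct
predictions over all predictions, rounded half-up to a whole percent; a
stratum with zero predictions prints a blank, never 0 %. A regimen
prediction is correct iff it matches a still-unmatched truth regimen on
patient, name, and both dates within ± 3 days (a convention — registrars
check "correct dates" without a stated tolerance; configurable). Because
the denominator of a printed regimen accuracy can be read as either
predictions or truth regimens, the harness computes **both** tables
(`by_predicted`, PPV; `by_truth`, recall) and labels them; the headline
figure uses the predicted denominator, under which all per-category
accuracies of the validated system are reproduced simultaneously. Every
emitted table is self-checked: each percentage must be recomputable from
its own printed counts.

## Synthetic generator

The generator's defaults are the study conditions: 349 AML + 938 lung
prospective candidates with exactly 11 non-resident, 27
relapsed/refractory and 30 preliminary-only exclusions; 117 MM patients
whose prescriptions realize 198 derivable regimens (191 clean + the six
narrated misreads, composed so the per-category counts are 55/22/16/37/
17/5/10/36); 254 treated AML patients; planted CTCAE events per category
and channel; a 384-record registry extract with 342/14/28 match
categories; 16 breast-cancer trial patients with 1,689 lab items over 27
analytes, into whose *manual copy* exactly 7 typos are injected (the
manual side is the one that errs). Everything is driven by one
`numpy.random.default_rng(seed)`; identical config + seed gives
byte-identical files. Background noise (benign prescriptions, routine
labs, stray indicator-drug orders) is on by default and exercises the
false-positive paths without touching recovery of planted truth.

What the generator does **not** emulate: realistic clinical narrative
text, dose tapering and cycle-level structure, coding errors in the
*extract* itself, inter-hospital schema variation, survival/outcome data,
and patients absent from the CDM. Passing tests therefore demonstrate
that the engines implement their rules exactly and recover planted
structure under realistic composition and noise — not that the rules
would achieve the same accuracy on real hospital data, where the failure
modes are richer than the six planted here.

Problem sizes in the test suite are miniatures of the same plan (a few
patients per arm); the acceptance script uses the full study-scale
defaults, which generate and score in seconds.

## Known limitations

* The CTCAE rule file and the AML catalog are reconstructions; accuracy
  statements about them concern the planted truth, not clinical validity.
* Retrospective matching keys on (patient, tumor group, trajectory-start
  year) only; it does not attempt probabilistic record linkage.
* The keyword channel is intentionally naive (no negation, no sections).
* `classify_inclusion` derives "initial contact" from the trajectory
  start date by construction; deriving it from raw EHR events (first
  visit, first order) is out of scope.
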