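# Methods

This note documents the models and conventions `epispell` implements,
the choices made where register practice is ambiguous, and what the
synthetic generator does and does not emulate.

## Input model and quality controls

One `RegisterEntry` is one administrative row: person identifier,
admission and discharge dates (ISO-8601, inclusive at both ends — a
stay Jan 1 → Jan 1 occupies one calendar day), raw service-type code(s),
specialty, provider, and an ordered list of diagnosis codes (one main,
any number of additional) tagged with their coding system (ICD-8,
ICD-9, ICD-10 or ICPC-2).

Quality filters exclude rows with a missing person identifier, missing
admission or discharge date, discharge before admission, or dates
outside the configured dataset range (boundaries inclusive; "out of
range" means either date outside the range, since register practice
does not define it more precisely).  A row failing several checks is
counted once, under the first matching reason in the order above, so
the exclusion report partitions the input exactly:
retained + Σ excluded-by-reason = total.

### Era-dependent classification

All era/code lists live in a versioned YAML configuration, never in
code; the repository ships a synthetic-register dialect
(`data/era_rules.yaml`) and real extracts supply their own.

* **Service type.** Before 1998 every row is inpatient care.  From 1998
  a raw code maps to {inpatient, outpatient, emergency, day hospital,
  primary care, other contact}; day-hospital care counts as outpatient.
  The 2019 coding reform left rows carrying the old dialect, the new
  one, or a mixture, so two code columns are consulted against both
  maps.  An outpatient/emergency/primary-care contact may end the day
  after it starts (events around midnight), but any non-inpatient row
  touching more than two calendar days (discharge − admission ≥ 2) is
  reclassified as inpatient care.
* **Psychiatric care.** A row is psychiatric if its specialty code is
  in the era's psychiatric list, or — before uniform specialty coding
  (1987) — if its provider is a mental hospital.  Unknown specialties
  classify as non-psychiatric.

### Year-end census rows

From 1996, patients still in inpatient care on Dec 31 generate a row
whose discharge should be blank, though it is not consistently so.
Open inpatient rows are reconciled in a fixed order: (1) a row whose
implied interval [admission, Dec 31] is wholly contained in another
inpatient row of the same person is dropped as a duplicate; (2) a row
continued by an admission on/before Jan 1 of the next year is closed at
that admission date, making the two contiguous under every model;
(3) anything left is closed at Dec 31 and flagged.  Containment is
checked before chaining so duplicated full stays never survive as
phantom rows.  This reconciliation runs before the missing-discharge
quality filter (pipeline order contract).

## Episode identification

Four models cross two binary choices:

| model | merge gap (days) | overnight required |
|-------|------------------|--------------------|
| 1     | 0                | no                 |
| 2     | 0                | yes                |
| 3     | 1                | no                 |
| 4     | 1                | yes                |

Per person, inpatient entries are sorted by (admission, discharge,
entry id) — the id as final key makes membership reproducible under
ties — and swept: an entry joins the current episode iff its admission
is at most `gap` days after the running maximum discharge, with
transitive closure, so chains of transfers and fully contained stays
collapse into one episode.  Gap 0 merges same-day re-admissions; gap 1
additionally merges next-day admissions, i.e. a new episode requires a
full calendar day spent outside the hospital (admission ≥ discharge
+ 2).  With the overnight rule, episodes starting and ending on the
same day are removed and re-emitted as outpatient events.

The psychiatric sub-episode spans the first psychiatric admission to
the last psychiatric discharge among member entries only (never
attached ambulatory contacts).  The overnight rule applies at the
episode level, not the sub-episode level: a one-day psychiatric
sub-interval inside a longer stay survives under models 2/4.

Ambulatory contacts (outpatient, emergency, primary care, other) whose
**start** date falls inside an episode's inclusive interval become
attached, non-independent events of that episode; keying on the start
date alone lets a contact legitimately ending the day after discharge
stay attached (midnight allowance).  Episodes of one person are
separated by more than the merge gap, so a start date can fall in at
most one episode — asserted, not handled.  Reclassified same-day stays
re-enter the ambulatory pool *before* attachment, so a same-day stay
inside another episode is counted as part of it, not as an independent
contact.

## Discharge-diagnosis resolution

Register rows carry their diagnoses at the discharge date of the row
(the register documents the state at the end of the contact); attached
ambulatory events carry theirs at the event start.  For a psychiatric
episode with psychiatric discharge `psy_end` and overall discharge `d`:

* **Final**: (a) diagnoses of psychiatric member entries dated
  `psy_end`; (b) if `psy_end < d`, member diagnoses dated `d` (the
  final day of the overall episode); (c) psychiatric ambulatory
  diagnoses dated in [`psy_end`, `d`].
* **Preliminary**: in-scope diagnoses dated before `psy_end`.
* Mental-disorder codes (ICD-10 chapter F after mapping) issued by
  non-psychiatric specialties are excluded from both sets, but kept in
  the episode's full record (`all_during_episode`).
* The number of discharge diagnoses is not limited.  A code recorded
  both early and at discharge is deduplicated to final status.
* Non-psychiatric episodes run through the same machinery with
  `psy_end` replaced by the overall discharge, and are excluded from
  psychiatric metrics.

Codes from ICD-8, ICD-9 and ICPC-2 are harmonized to ICD-10 sub-chapter
categories by longest-prefix lookup in a user-suppliable mapping table;
the shipped `data/demo_mapping.csv` is a small demonstration mapping
for the synthetic dialect, not an authoritative national table.  ICPC-2
concepts without an ICD-10 counterpart stay unmapped and are grouped
separately, outside the ICD-10 categories.

Each reporting category carries an earliest plausible onset age
(default 5 years; 35 for dementias F00–F03; 1 for F7/F8/F90–98).  A
record is dropped when the person's age in completed years at the
record date is below the floor of the most specific (longest-prefix)
matching category; the boundary is inclusive.  Floors are applied at
metrics time, not at resolution time, so resolved sets stay reusable.

## Metrics conventions

* Episodes are assigned to the calendar year of their (psychiatric)
  discharge; configurable to admission year.
* LOS defaults to nights (discharge − admission); "days" (one more) is
  available because register practice never defines the arithmetic.
  Episode LOS uses the psychiatric sub-interval.
* Median of an even-sized sample is the mean of the two central order
  statistics, reported unrounded in machine output.
* Reduction % = 100 × (raw − processed)/raw; treated-individual change
  % is signed (negative = fewer than raw).  Post-discharge outpatient
  diagnoses included in finals can push a category's processed count
  above its raw count.
* Outpatient-event counts include independent events only; attached
  events are part of an inpatient episode.  LOS histograms use
  configurable bin edges (default 1, 4, 8, 15, 31, 91, 366 nights).

## Synthetic generator

The generator emulates, with planted ground truth emitted as sidecar
structures (never as columns of the entry table): stays fragmented into
2–3 entries by transfers with same-day or overlapping boundaries;
emergency contacts at admission and outpatient contacts during stays;
preliminary diagnoses on non-final days drifting toward the eventual
discharge diagnosis (acute/unspecified psychosis F23/F29 resolving to
F20 and related categories); same-day stays; year-end census rows
(blank or wrongly filled discharge) and stays split at the year
boundary; the 2019 dual service-coding mixture; independent outpatient
and primary-care contacts (partly ICPC-2 coded); and disjoint planted
defects (missing identifier, missing admission, inverted dates, out of
range).

Design choices worth knowing:

* Intra-episode fragment boundaries are same-day or overlapping by
  default.  A "next day" boundary style exists for stress testing but
  defaults to weight 0: a next-day boundary inside a planted stay would
  make the planted truth model-relative (models 1–2 would split it).
  One-day separations are instead planted through the readmission-gap
  distribution, whose support includes gaps of 0, 1 and 2 days so all
  four models are exercised; truth helpers chain planted stays per
  model when computing expected outcomes.
* Year-boundary splits are only planted when the open row starts at
  least two days before Dec 31; closer to the boundary, an adjacent
  gap-0 readmission or overlapping transfer can cover the row's census
  interval, and the resolver would (correctly, per its reconciliation
  order) drop it as a contained duplicate — an ambiguity real data can
  contain but planted truth must not.
* Preliminary diagnoses are planted only on fragments discharged
  strictly before the stay's end, matching the resolver's date
  semantics; planted categories respect the age floors.
* Missing-discharge defects are not planted: an inpatient row with a
  blank discharge is indistinguishable from a census row by design, so
  it cannot be a *disjoint* defect.  The filter still implements the
  missing-discharge reason for non-inpatient rows.
* Admission dates are spread over the whole study window by drawing the
  stay structure first and distributing the remaining slack over the
  long gaps (Dirichlet weights), so annual metrics are stationary.

The "finland-like" default preset (2,000 persons in tests and the
acceptance script; 2011–2020; 0.35 admissions/person-year; ~8 % of
stays fragmented; lognormal LOS with median ≈ 9 nights; 2 % same-day
stays; 0.1 % planted defect rate per kind) was calibrated once so the
raw-vs-processed episode reduction lands in the high-single-digit to
low-double-digit percent range and the pooled median LOS rises by about
one night after merging — a qualitative echo of the magnitudes seen on
real nationwide registers, documented as calibration, not as a claim of
equivalence.  What passing tests show is therefore that the *method* is
exact (oracle agreement, planted-truth recovery, accounting identities)
and directionally realistic; they do not show that the generator
reproduces real Finnish register microstructure (no demographics,
provider networks, seasonality, coding drift across decades, or
survival/censoring structure).

## Numerical and degenerate-input choices

* All date arithmetic is integer calendar-day arithmetic; no floating
  point enters episode construction.
* Deterministic ordering everywhere: persons processed in sorted order,
  entries sorted by (admission, discharge, id), diagnosis records by
  (date, code, category, source, role); identical inputs give
  byte-identical outputs (hashed in the run manifest).
* Empty inputs yield empty outputs (no errors); annual medians over
  empty year cells are NaN.
* Unmapped service-type codes and malformed mapping/config rows raise
  configuration errors naming the offending item; unknown config keys
  are rejected by name before any stage runs.
* The generator validates its parameters (probabilities in [0, 1],
  distributions summing to 1, date range longer than the maximum
  plantable stay) and is byte-reproducible under a fixed seed.

## Known limitations

* The shipped era rules and code mapping are a synthetic dialect;
  reproducing a real register requires the authority's own service-type
  code lists and conversion tables.
* Specialty-specific LOS decomposition within an episode is out of
  scope; the models ignore provider identity, so inter- vs.
  intra-provider transfers are not distinguished.
* Whether a diagnosis can be simultaneously final and preliminary is
  unspecified in register practice; the resolver deduplicates by
  (code, category) keeping final status.
* The overnight requirement is not applied to psychiatric sub-episodes,
  only to overall episodes (see above).
* No statistical inference is provided — the metrics are descriptive
  counts, medians and percentages, as register comparisons of this kind
  report.
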