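# epispell

Construction of inpatient episodes, independent outpatient events and
discharge diagnoses from partly overlapping healthcare-register entries.

## The problem

Continuously collected discharge registers (the Nordic hospital
registers are the canonical case) record one hospitalization as several
rows: ward and specialty transfers generate new, sometimes overlapping
entries; emergency-department and outpatient contacts during a stay are
filed as if they were independent events; patients still in care on
Dec 31 generate year-end census rows with (ideally) blank discharge
dates; and diagnoses recorded early in a stay are often preliminary,
superseded by the discharge diagnosis.  Counting rows as admissions, or
early codes as diagnoses, biases episode counts, length-of-stay (LOS)
statistics and disease incidence derived from the registers.

`epispell` is for register-based epidemiologists who need reproducible,
explicit preprocessing.  It implements four episode-identification
models that bracket the choices used across published register studies:

| Model | Transfer rule (merge gap) | Overnight required |
|-------|---------------------------|--------------------|
| 1 | discharge and re-admission on the same day merge (gap 0) | no |
| 2 | gap 0 | yes — same-day stays become outpatient events |
| 3 | re-admission without a full calendar day outside merges (gap 1) | no |
| 4 | gap 1 | yes |

Model 1 is the most liberal, model 4 the most conservative.  Writing an
entry's interval as [admission *a*, discharge *d*] (inclusive calendar
days), two consecutive stays of one person merge iff
*a*₂ − *d*₁ ≤ gap.  The overall episode spans min *a* to max *d* over
its member entries; the psychiatric sub-episode runs from the first
psychiatric admission to the last psychiatric discharge.  Discharge
diagnoses are the codes dated at the psychiatric discharge (plus
psychiatric ambulatory codes up to the final overall discharge); codes
dated earlier are preliminary and excluded; mental-disorder codes from
non-psychiatric specialties are excluded throughout.

Because the real registers are restricted, the package ships a
synthetic register generator that plants transfers, preliminary
diagnoses, census rows and quality defects with known ground truth, so
every stage is testable end to end.

## Worked example

```python
from epispell import (GeneratorParams, generate_cohort, prepare_entries,
                      identify_episodes, MODELS, EraRules)
from epispell.io import entries_from_frame
from epispell.metrics import count_annual_episodes, annual_median_los

params = GeneratorParams(n_persons=500, seed=7)
cohort = generate_cohort(params)
entries = entries_from_frame(cohort.entries)
validated, report = prepare_entries(entries, EraRules.default(), params.date_range)
print(f"entries: {report.n_input}, retained: {report.n_retained}, "
      f"excluded: {report.n_excluded}")

sets = {m: identify_episodes(validated, MODELS[m]) for m in (1, 2, 3, 4)}
years = list(range(2011, 2021))
counts = count_annual_episodes(sets, validated, years)
total_raw = counts.raw_n.sum()
for m in (1, 2, 3, 4):
    red = 100 * (total_raw - counts[f"n_m{m}"].sum()) / total_raw
    print(f"model {m}: {counts[f'n_m{m}'].sum()} psychiatric inpatient episodes "
          f"({red:.2f}% below the {total_raw} raw entries)")

los = annual_median_los(sets, validated, years)
print(los[["year", "raw_median", "median_m1", "median_m4"]].tail(3).to_string(index=False))
```

prints

```
entries: 12144, retained: 12093, excluded: 51
model 1: 1570 psychiatric inpatient episodes (8.19% below the 1710 raw entries)
model 2: 1547 psychiatric inpatient episodes (9.53% below the 1710 raw entries)
model 3: 1548 psychiatric inpatient episodes (9.47% below the 1710 raw entries)
model 4: 1525 psychiatric inpatient episodes (10.82% below the 1710 raw entries)
 year  raw_median  median_m1  median_m4
 2018         8.5        9.0        9.0
 2019         8.0       10.0       10.0
 2020         8.0        9.0        9.0
```

Reading this: ~0.4 % of rows fail the quality filters (missing person
identifier, missing or inverted dates, out of range).  Merging
transfers removes 8–11 % of apparent "admissions" depending on the
model — exactly the kind of gap that makes unprocessed register counts
incomparable across studies — and the annual median length of stay of
psychiatric episodes comes out 1–2 nights longer than the per-row
medians, because transfer fragments masquerade as short stays.

A command-line interface wraps the same pipeline:

```bash
epispell simulate --params params.yaml --seed 3 --out sim/
epispell process --model all --in sim/entries.csv --out processed/
epispell run --config run.yaml          # simulate + process + metrics
epispell validate --config run.yaml     # config check only
```

Every run writes a `manifest.json` with the config hash, seed, row
counts per stage and output digests; identical config + seed reruns are
byte-identical.

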