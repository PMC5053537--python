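# bdzscreen

Rule-based screening of inpatient benzodiazepine and Z-drug (BDZ)
administrations for potential medication errors, with deterministic triage
and prevalence reporting.

Benzodiazepines are among the most frequently administered hospital drugs,
and a share of their adverse events — falls, CNS and respiratory
depression — trace back to preventable prescribing errors: co-medication
with strong CYP inhibitors that multiply BDZ exposure, lorazepam given in
severe renal impairment, non-reduced zolpidem doses in the elderly.
`bdzscreen` is for pharmacovigilance and clinical-pharmacology teams who
want to screen day-granular administration data (from a hospital
information system export) for these patterns, rank the hits for expert
review, and quantify prevalence. Because real hospital databases cannot be
shared, the package includes a seeded synthetic-data generator with
planted ground-truth violations, so the whole pipeline is demonstrable and
testable end to end.

## What it computes

For every **patient-day** (one calendar day of one hospitalization — both
bounds inclusive), four mechanisms are evaluated:

| mechanism | rule |
|---|---|
| `cyp_ddi` | CYP-metabolized screened BDZ on day *d* with a strong inhibitor of a relevant pathway on *d*, *d−1* or *d−2* of the same stay (prazepam also fires on strong/moderate CYP2C19) |
| `lorazepam_renal` | lorazepam with current eGFR < 30 mL/min (CKD-EPI 2009, most recent creatinine within 72 h before the day) and either lorazepam on an adjacent day or another BDZ the same day |
| `flumazenil_surrogate` | any administration of the BDZ antidote flumazenil |
| `elderly_zolpidem_dose` | zolpidem ≥ 10 mg/day at age ≥ 65 (reported separately as a prescribing-quality stream) |

Flagged hospitalizations are then triaged — exclusions (palliative
situation, known BDZ abuse, all flagged BDZ at ≤ ½ standard dose) force
`NO_ME`; aggravators (another BDZ on a flagged day, severe respiratory
insufficiency, severe liver disease, non-reduced initial dose at age ≥ 65)
yield `VALIDATED_ME`; everything else is `NEEDS_REVIEW` for manual
evaluation. Prevalences are reported over patient-days, patients and
hospitalizations with half-up rounding. See `docs/methods.md` for the
full model and `docs/data_dictionary.md` for the input format.

## Worked example

Run the whole pipeline — simulate, screen, triage, report — on a seeded
synthetic population:

```sh
bdzscreen -v all --seed 5 --out demo_run
# pipeline complete: 10 flags, 8 triaged hospitalizations
```

`demo_run/` then contains the four dataset files, `truth.json` (the
planted violations), `flags.csv`, `elderly_flags.csv`, `annotations.csv`,
`decisions.csv`, `report.json`/`report.md` and a `provenance.json`. With
seed 5 the default configuration produces 160 patients, 234
hospitalizations and 2,243 patient-days, of which 534 (23.8%) carry a BDZ
— the generator targets the 23.2% patient-day prevalence of the emulated
population. The screen finds exactly the 12 planted violations: 3
CYP-interaction days, 5 lorazepam-in-renal-impairment days, 2 flumazenil
days (10 potential-ME flags on 8 hospitalizations) plus 2 elderly-dose
days in the separate stream. Triage splits the 8 flagged hospitalizations
into 2 `VALIDATED_ME`, 2 `NO_ME` and 4 `NEEDS_REVIEW`, matching the
intended classification recorded for each spike-in.

The same stages are available as a library:

```python
from bdzscreen import (SimConfig, generate, load_catalog, screen_all,
                       triage_batch, egfr_ckdepi)

catalog = load_catalog()                 # screened BDZ + inhibitor lists
dataset, truth = generate(SimConfig(seed=5), catalog)
result = screen_all(dataset, catalog)
decisions, summary = triage_batch(result, dataset, catalog)

egfr_ckdepi(2.0, 70, "female")           # 24.7 mL/min/1.73 m2
```

Real data are read with `read_dataset(...)` from the four CSV files
described in `docs/data_dictionary.md`; invalid rows land in a rejection
report, never silently dropped. The inhibitor list, standard doses and
triage policy are data, overridable via YAML (`examples/`).

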