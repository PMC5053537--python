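# Input data dictionary

Four delimited text files (UTF-8; comma or tab, auto-detected from the
header row). Column names are fixed. Dates are ISO-8601 calendar dates
(`YYYY-MM-DD`); timestamps are ISO-8601 to at least the hour; booleans
accept `true/false`, `yes/no`, `1/0`.

## patients.csv

| column | type | notes |
|---|---|---|
| `patient_id` | string | unique, opaque |
| `birth_date` | date | used to derive age at any reference day |
| `sex` | `male` \| `female` | enters the CKD-EPI equation |
| `research_consent` | boolean | `false` excludes the patient from triage |

## hospitalizations.csv

| column | type | notes |
|---|---|---|
| `hosp_id` | string | unique, opaque |
| `patient_id` | string | must reference patients.csv |
| `admit_date` | date | `admit_date <= discharge_date` |
| `discharge_date` | date | both bounds count as patient-days |
| `palliative` | boolean | triage exclusion |
| `known_bdz_abuse` | boolean | triage exclusion |
| `respiratory_insufficiency` | boolean | triage aggravator (severe) |
| `severe_liver_disease` | boolean | triage aggravator |

## administrations.csv

One row per drug actually administered to one patient on one calendar day.
Several rows for the same drug on the same day are summed into a daily dose
for rule evaluation; the individual rows are retained.

| column | type | notes |
|---|---|---|
| `patient_id` | string | must match the hospitalization's patient |
| `hosp_id` | string | must reference hospitalizations.csv |
| `day` | date | must lie within `[admit_date, discharge_date]` |
| `atc_code` | ATC string | 7-char WHO ATC code or legal truncation |
| `drug_name` | string | free text, informational |
| `dose_mg` | number >= 0 | milligrams |
| `route` | `oral` \| `intravenous` \| `other` | recorded, not weighted |

## labs.csv

| column | type | notes |
|---|---|---|
| `patient_id` | string | must reference patients.csv |
| `timestamp` | datetime | drives the 72-hour recency window |
| `analyte` | `creatinine` | only creatinine is used |
| `value` | number > 0 | serum creatinine |
| `units` | `umol_per_L` \| `mg_per_dL` | declared per row, never guessed |

Rows violating any constraint are collected into `rejections.csv`
(`table`, `row`, `reason`) and excluded from analysis; they are never
silently dropped.
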