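# Methods

`bdzscreen` screens day-granular inpatient drug-administration data for
potential medication errors (ME) involving benzodiazepines and "Z-drug"
GABA-receptor modulators (collectively BDZ), triages the flagged
hospitalizations with a deterministic rule skeleton, and reports
prevalences over three denominators. This note records the model, its
assumptions, the parameters that matter, and the design choices made where
the design was genuinely open.

## Screening model

The analysis unit is the **patient-day**: one calendar day of one
hospitalization, both the admission and discharge day included (a same-day
admission and discharge contributes one patient-day). Administrations are
day-granular because every rule below operates on days; only laboratory
values keep timestamps. All rules are evaluated within a single
hospitalization — no rule looks across stays.

Four detection mechanisms:

**CYP drug–drug interaction (`cyp_ddi`).** Eleven screened BDZ (zolpidem,
midazolam, diazepam, alprazolam, triazolam, zopiclone, flunitrazepam,
clorazepate, nitrazepam, prazepam, lorazepam) each carry a metabolic
profile. A patient-day is flagged when a CYP-metabolized screened BDZ was
administered and a strong inhibitor of a relevant pathway was administered
the same day or up to `carryover_days` earlier. Strong CYP3A4 inhibitors
carry `carryover_days = 2`, reflecting mechanism-based inactivation
(e.g. clarithromycin) or long-lived inhibitory metabolites
(e.g. itraconazole); other entries act same-day only. Moderate inhibitors
are annotation-only, with one data-driven exception: prazepam is also
flagged on strong *or* moderate CYP2C19 inhibition (its profile declares an
`extra_trigger`). Glucuronidation-only drugs — lorazepam here, and any BDZ
without a CYP pathway — can never fire this rule. Deduplication: one flag
per (day, BDZ), listing every triggering inhibitor with its day offset.

**Lorazepam in severe renal impairment (`lorazepam_renal`).** Severe renal
impairment is a formal contraindication for lorazepam in the Swiss label.
A lorazepam day is flagged when the *current eGFR* is strictly below
30 mL/min **and** either lorazepam was also given on the adjacent previous
or next day, or at least one other BDZ was given the same day. Each
qualifying day receives its own flag. Days without a current eGFR never
flag — absence of a recent creatinine is a value, not an error.

**Flumazenil surrogate (`flumazenil_surrogate`).** Any administration of
the specific BDZ antagonist flumazenil (ATC V03AB25) flags its day; the
evidence records all BDZ given on that day and the day before. Flumazenil
use is a surrogate signal of BDZ overdose rather than proof of an error,
hence it enters triage like the other mechanisms.

**Elderly zolpidem dosing (`elderly_zolpidem_dose`).** Zolpidem's
recommended dose halves to 5 mg/day at age >= 65. Days with a summed
zolpidem daily dose >= 10 mg in a patient aged >= 65 are flagged — but
reported as a separate prescribing-quality stream, outside the
potential-ME denominator, because they measure guideline compliance rather
than an individual contraindication.

Risk factors (several distinct BDZ on one day, opioid co-medication,
muscle relaxants, additional CYP2C19/CYP1A2 inhibitors) are annotated per
patient-day and are never an ME by themselves; they feed the triage stage.

## Renal function

eGFR uses the 2009 creatinine-based CKD-EPI equation:

    eGFR = 141 · min(Scr/κ, 1)^α · max(Scr/κ, 1)^−1.209 · 0.993^age · 1.018[female]

with κ = 0.7/0.9 and α = −0.329/−0.411 for women/men, Scr in mg/dL
(µmol/L inputs divided by 88.4; the unit is declared per lab row, never
guessed). No race term is used: the data model carries no race field. The
equation is adult-only; under-18 patient-days simply have no eGFR.

The *current eGFR* of an administration day is taken from the most recent
creatinine within 72 hours **before the start of that day**: window
(day 00:00 − 72 h, day 00:00]. Administrations carry no time of day, so
anchoring at the day start is the deterministic, conservative reading of
"within 72 hours before the administration"; this choice is configurable
(`recency_window_hours`) and is the one place where a timestamped quantity
meets the day-granular model.

## Triage

Clinical validation of a potential ME is expert judgment on free-text
records. The triage stage encodes only its deterministic skeleton and
emits `NEEDS_REVIEW` for anything the rules cannot decide — it is a triage
assistant, not a replacement adjudicator. Per flagged hospitalization,
exclusions are checked first:

* palliative situation — benefit outweighs risk, `NO_ME`;
* known BDZ abuse — tolerance of high doses, `NO_ME`;
* careful dosing — every flagged BDZ at <= 1/2 of its standard daily dose
  on every flagged day, `NO_ME`.

Without an exclusion, at least `aggravator_threshold` (default 1) of the
following yields `VALIDATED_ME`:

* >= 1 other BDZ on a flagged day;
* severe respiratory insufficiency;
* severe liver disease;
* age >= 65 with the first administered daily dose of the flagged BDZ not
  below its standard dose ("initial dose not reduced").

The "other BDZ" rule has no numeric qualifier in the source procedure
("depending on number & dose"); the default — any other BDZ at any dose —
is a deliberate, policy-overridable choice. Patients who withheld research
consent are excluded from triage entirely. WHO/CIOMS causality
(`unlikely`/`possible`/`probable`) is carried as a reviewer-supplied
annotation; it is never computed.

Standard daily doses ship in the catalog. Zolpidem's 10 mg (5 mg elderly)
is anchored in the source material; the remaining ten are usual adult
daily doses from the SPCs (midazolam 7.5, diazepam 10, alprazolam 1,
triazolam 0.25, zopiclone 7.5, flunitrazepam 1, clorazepate 20,
nitrazepam 5, prazepam 20, lorazepam 2 mg) and are config-overridable —
the half-dose exclusion and the elderly rule read them as data.

The inhibitor list is likewise data: a curated default (strong 3A4:
clarithromycin, telithromycin, itraconazole, ketoconazole, voriconazole,
posaconazole, ritonavir; moderate 3A4: fluconazole, erythromycin,
diltiazem, verapamil; 2C19: fluvoxamine, ticlopidine strong, fluconazole
moderate; 1A2: fluvoxamine, ciprofloxacin) that any deployment should
review and override via a user YAML — the algorithm, not this list, is the
contract.

## Reporting conventions

Every frequency is reported against patient-days, patients and
hospitalizations. Percentages round **half-up** at one decimal
(12/192 = 6.25% prints as 6.3), switching to two decimals when the
one-decimal value would fall below 0.3% so rare events stay visible
(205/82,074 prints as 0.25%). Every percentage is emitted beside its
numerator and denominator so it can be recomputed exactly. The mean number
of potential ME per calendar day divides flagged patient-days by the
inclusive length of the configured study window (2011-01-01 to 2012-12-31
spans 731 days; 2012 is a leap year).

## Synthetic data

The generator emulates a two-year tertiary-care population: lognormal stay
lengths with mean 10 and median 5 days (µ = ln 5, σ² = 2 ln 2, truncated to
1–397 — only mean, median and range of the real population are known);
BDZ on 23.2% of patient-days; the drug mix over BDZ days (lorazepam 36.1%,
zolpidem 30.3%, midazolam 17.7%, oxazepam 9.9%, ...); a second distinct
BDZ on 7.1% of patient-days; opioids on 27.2% of BDZ days; sporadic strong
inhibitors (1% of patient-days) and severe renal impairment (2% of adult
patients, baseline eGFR drawn in 10–29 via numeric inversion of CKD-EPI);
creatinine drawn every 3 days at 08:00 with 5% lognormal noise; age bands
and a balanced sex ratio matching the published population; doses drawn
from {1/4, 1/2, 1, 2} × standard so the low-dose triage rule is exercised.

Two deliberate unrealisms make it a test oracle. First, the background is
violation-free **by construction**: strong inhibitors are only placed on
days with no CYP-metabolized BDZ in the following two days, severely
renally impaired patients receive no background lorazepam, background
zolpidem in the elderly is always dose-reduced (the real-world compliance
rate is far worse), and flumazenil never occurs in the background. Second,
every violation is an explicit spike-in on a dedicated hospitalization,
with mechanism, day and intended triage classification recorded in
`truth.json`. After generation the production screener is run and any
mismatch with the planted truth raises, so an emitted dataset is
guaranteed internally consistent. Consequently, passing spike-in recovery
shows the pipeline finds exactly what the rules define on clean data; it
says nothing about coding variability, missing administrations or other
messiness of real hospital records.

A separate deterministic hand-built fixture (~20 hospitalizations)
reproduces documented case vignettes — a lorazepam course at eGFR
18 mL/min, an intentional 510 mg/day zolpidem course under known BDZ
addiction, a day combining 2 BDZ + 2 strong inhibitors + 2 opioids + a
muscle relaxant, a flumazenil rescue, carryover boundary pairs — with the
expected flags and triage decisions written down in the test suite.

## Numerical choices and degenerate inputs

* eGFR is computed in double precision and reported to one decimal; the
  renal threshold comparison (`< 30`) uses the reported value.
* Round-half-up is implemented with decimal arithmetic, not binary
  floating-point rounding.
* A zero denominator in a prevalence is an error, never NaN; a missing
  eGFR is an absence, never zero.
* Ties in the creatinine recency rule cannot occur at equal timestamps in
  the data model's hour resolution; if two rows share a timestamp the
  scan keeps the later-sorted one deterministically.
* Row order never affects any output; flags are sorted by
  (hospitalization, day, mechanism, drug).
* Malformed ATC codes raise; classification never silently returns false.

## Problem sizes

Default test and demonstration runs use 25–700 synthetic patients
(roughly 400–10,000 patient-days). Oracle-equivalence checks run at 200
patients; generator parameter-recovery checks at >= 10,000 patient-days
within three binomial standard errors. These sizes were chosen to make the
statistical checks informative while keeping a full run fast on one core.

## Known limitations

* The screen reproduces a fixed rule set; it does not model interaction
  magnitude, CYP induction, dose-response, or pharmacokinetics.
* Intravenous midazolam interacts with CYP3A4 inhibitors far less than
  oral (first-pass effect); the route is recorded and reported but not
  weighted at screening — weighting is left to triage policy.
* The shipped inhibitor list is a conservative consensus default, not a
  site-validated formulary list.
* Triage approximates an expert process; its `VALIDATED_ME` output is a
  prioritization signal, not a clinical verdict.
* Clobazam and barbiturate co-medication are outside the screened set.
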