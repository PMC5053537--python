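# Annotated synthetic-population config (SimConfig overrides).
# Any omitted key keeps its default; the seed always comes from --seed.

n_patients: 150          # background patients (before spike-in patients)
study_start: 2011-01-01
study_end: 2012-12-31

# stay lengths: lognormal, truncated to 1..397 days
stay_mean_days: 10.0
stay_median_days: 5.0

p_bdz_day: 0.232         # fraction of patient-days with any BDZ
p_multi_bdz_day: 0.071   # fraction of patient-days with >= 2 distinct BDZ
p_opioid_on_bdz_day: 0.272
p_muscle_relaxant_on_bdz_day: 0.016

# per-drug share of BDZ patient-days (must sum to <= 1)
drug_mix:
  lorazepam: 0.361
  zolpidem: 0.303
  midazolam: 0.177
  oxazepam: 0.099
  diazepam: 0.015
  alprazolam: 0.014
  triazolam: 0.005

p_strong_inhibitor_day: 0.01   # placed only where no violation results
p_severe_renal_patient: 0.02   # baseline eGFR drawn in 10-29 mL/min

# hospitalization-level validation covariates
p_palliative: 0.05
p_abuse: 0.02
p_respiratory: 0.08
p_liver: 0.03
p_no_consent: 0.02

lab_cadence_days: 3      # creatinine draw interval

# planted ground-truth violations (see truth.json in the output)
n_spike_cyp: 3
n_spike_renal: 3
n_spike_flumazenil: 2
n_spike_elderly: 2
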