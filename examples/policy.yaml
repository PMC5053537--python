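# Annotated triage policy (TriagePolicy overrides).
# true enables a rule; aggravator_threshold is how many aggravating rules
# must fire (with no exclusion) to classify a hospitalization VALIDATED_ME.

palliative: true               # exclusion: benefit outweighs risk
known_abuse: true              # exclusion: high doses tolerated
low_dose: true                 # exclusion: all flagged BDZ <= low_dose_fraction of standard
low_dose_fraction: 0.5

multi_bdz: true                # aggravator: >= 1 other BDZ on a flagged day
respiratory_insufficiency: true
severe_liver_disease: true
elderly_unreduced_dose: true   # age >= 65, initial dose not reduced

aggravator_threshold: 1
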