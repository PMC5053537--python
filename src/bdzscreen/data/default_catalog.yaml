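# Default reference catalog: screened benzodiazepines / Z-drugs, CYP
# inhibitor lists and ATC drug-class prefixes.
#
# The inhibitor list is a curated stand-in assembled from consensus
# interaction references (FDA/Flockhart classifications and SPC texts);
# it is deliberately config-overridable so that the screening algorithm,
# not this particular list, is the contract. Strong CYP3A4 inhibitors
# carry a 2-day carryover window (mechanism-based inactivation or
# long-lived inhibitory metabolites); all other entries act same-day only.
#
# Standard daily doses: zolpidem 10 mg (5 mg if >= 65 y) per SPC; the
# remaining doses are usual adult daily doses from the SPCs.

bdz:
  - drug_name: zolpidem
    atc_code: N05CF02
    pathways: [CYP3A4, CYP1A2]
    standard_daily_dose_mg: 10
    elderly_daily_dose_mg: 5
  - drug_name: midazolam
    atc_code: N05CD08
    pathways: [CYP3A4]
    standard_daily_dose_mg: 7.5
  - drug_name: diazepam
    atc_code: N05BA01
    pathways: [CYP3A4, CYP2C19]
    standard_daily_dose_mg: 10
  - drug_name: alprazolam
    atc_code: N05BA12
    pathways: [CYP3A4]
    standard_daily_dose_mg: 1
  - drug_name: triazolam
    atc_code: N05CD05
    pathways: [CYP3A4]
    standard_daily_dose_mg: 0.25
  - drug_name: zopiclone
    atc_code: N05CF01
    pathways: [CYP3A4]
    standard_daily_dose_mg: 7.5
  - drug_name: flunitrazepam
    atc_code: N05CD03
    pathways: [CYP3A4, CYP2C19]
    standard_daily_dose_mg: 1
  - drug_name: clorazepate
    atc_code: N05BA05
    pathways: [CYP3A4, CYP2C19]
    standard_daily_dose_mg: 20
  - drug_name: nitrazepam
    atc_code: N05CD02
    pathways: [CYP3A4]
    standard_daily_dose_mg: 5
  - drug_name: prazepam
    atc_code: N05BA11
    pathways: [CYP3A4, CYP2C19]
    standard_daily_dose_mg: 20
    extra_trigger:            # strong OR moderate CYP2C19 also flags
      pathway: CYP2C19
      strengths: [strong, moderate]
  - drug_name: lorazepam
    atc_code: N05BA06
    pathways: [glucuronidation_only]
    standard_daily_dose_mg: 2
    renal_contraindicated_below_egfr: 30

inhibitors:
  - {drug_name: clarithromycin, atc_code: J01FA09, pathway: CYP3A4, strength: strong, carryover_days: 2}
  - {drug_name: telithromycin,  atc_code: J01FA15, pathway: CYP3A4, strength: strong, carryover_days: 2}
  - {drug_name: itraconazole,   atc_code: J02AC02, pathway: CYP3A4, strength: strong, carryover_days: 2}
  - {drug_name: ketoconazole,   atc_code: J02AB02, pathway: CYP3A4, strength: strong, carryover_days: 2}
  - {drug_name: voriconazole,   atc_code: J02AC03, pathway: CYP3A4, strength: strong, carryover_days: 2}
  - {drug_name: posaconazole,   atc_code: J02AC04, pathway: CYP3A4, strength: strong, carryover_days: 2}
  - {drug_name: ritonavir,      atc_code: J05AE03, pathway: CYP3A4, strength: strong, carryover_days: 2}
  - {drug_name: fluconazole,    atc_code: J02AC01, pathway: CYP3A4, strength: moderate, carryover_days: 0}
  - {drug_name: erythromycin,   atc_code: J01FA01, pathway: CYP3A4, strength: moderate, carryover_days: 0}
  - {drug_name: diltiazem,      atc_code: C08DB01, pathway: CYP3A4, strength: moderate, carryover_days: 0}
  - {drug_name: verapamil,      atc_code: C08DA01, pathway: CYP3A4, strength: moderate, carryover_days: 0}
  - {drug_name: fluvoxamine,    atc_code: N06AB08, pathway: CYP2C19, strength: strong, carryover_days: 0}
  - {drug_name: ticlopidine,    atc_code: B01AC05, pathway: CYP2C19, strength: strong, carryover_days: 0}
  - {drug_name: fluconazole,    atc_code: J02AC01, pathway: CYP2C19, strength: moderate, carryover_days: 0}
  - {drug_name: fluvoxamine,    atc_code: N06AB08, pathway: CYP1A2, strength: strong, carryover_days: 0}
  - {drug_name: ciprofloxacin,  atc_code: J01MA02, pathway: CYP1A2, strength: strong, carryover_days: 0}

drug_classes:
  opioid_atc_prefixes: [N02A]
  muscle_relaxant_atc_prefixes: [M03]
  flumazenil_atc: V03AB25
  bdz_atc_prefixes: [N05BA, N05CD, N05CF]
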