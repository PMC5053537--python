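"""Independent oracles, coded without reference to the production path.

``egfr_reference`` is a straight-line transcription of the 2009 CKD-EPI
creatinine equation. ``brute_force_scan`` is a deliberately naive screening
scanner — plain nested loops over hospitalizations, days and administration
rows, no indexing or grouping — that re-derives every flag mechanism from
first principles. Both exist solely to cross-check the production
implementations; neither imports from the screening or renal modules.
"""

from __future__ import annotations

from datetime import datetime, timedelta


def egfr_reference(scr_mg_dl: float, age: float, sex: str) -> float:
    kappa = 0.7 if sex == "female" else 0.9
    alpha = -0.329 if sex == "female" else -0.411
    ratio = scr_mg_dl / kappa
    value = (
        141.0
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** -1.209
        * 0.993 ** age
    )
    if sex == "female":
        value *= 1.018
    return value


def _age_on(birth, day):
    years = day.year - birth.year
    if (day.month, day.day) < (birth.month, birth.day):
        years -= 1
    return years


def _egfr_on_day(labs_rows, patient_id, day, age, sex):
    """Most recent creatinine in (day 00:00 - 72 h, day 00:00], else None."""
    if age < 18:
        return None
    end = datetime(day.year, day.month, day.day)
    start = end - timedelta(hours=72)
    best = None
    for lab in labs_rows:
        if lab["patient_id"] != patient_id or lab["analyte"] != "creatinine":
            continue
        if not (start < lab["timestamp"] <= end):
            continue
        if best is None or lab["timestamp"] > best["timestamp"]:
            best = lab
    if best is None:
        return None
    scr = best["value"]
    if best["units"] == "umol_per_L":
        scr = scr / 88.4
    return round(egfr_reference(scr, age, sex), 1)


def _is_bdz(atc, catalog):
    return any(
        atc.startswith(p) for p in catalog.drug_classes.bdz_atc_prefixes
    )


def brute_force_scan(dataset, catalog) -> set[tuple]:
    """Every flag as (hosp_id, day iso, mechanism, bdz_atc), by plain loops.

    Covers all four mechanisms; the elderly-dose stream is included with
    its own mechanism name so callers can split it off.
    """
    patients = {p["patient_id"]: p for p in dataset.patients.to_dict("records")}
    hosps = dataset.hospitalizations.to_dict("records")
    admins = dataset.administrations.to_dict("records")
    labs = dataset.labs.to_dict("records")
    lor_profile = catalog.bdz_profile_by_name("lorazepam")
    zol_profile = catalog.bdz_profile_by_name("zolpidem")
    flum_atc = catalog.drug_classes.flumazenil_atc
    flags: set[tuple] = set()

    for hosp in hosps:
        hid = hosp["hosp_id"]
        patient = patients[hosp["patient_id"]]
        admins_h = [a for a in admins if a["hosp_id"] == hid]
        labs_p = [l for l in labs if l["patient_id"] == patient["patient_id"]]
        day = hosp["admit_date"]
        while day <= hosp["discharge_date"]:
            age = _age_on(patient["birth_date"], day)
            todays = [a for a in admins_h if a["day"] == day]

            # cyp_ddi: BDZ today, qualifying inhibitor today or up to its
            # carryover window back
            for a in todays:
                profile = catalog.bdz_profile(a["atc_code"])
                if profile is None:
                    continue
                rules = []
                if "CYP3A4" in profile.pathways:
                    rules.append(("CYP3A4", ("strong",)))
                if profile.extra_trigger is not None:
                    rules.append(
                        (profile.extra_trigger.pathway,
                         tuple(profile.extra_trigger.strengths))
                    )
                hit = False
                for other in admins_h:
                    back = (day - other["day"]).days
                    if back < 0 or back > 2:
                        continue
                    for entry in catalog.inhibitor_entries(other["atc_code"]):
                        for pathway, strengths in rules:
                            if (entry.pathway == pathway
                                    and entry.strength in strengths
                                    and back <= entry.carryover_days):
                                hit = True
                if hit:
                    flags.add((hid, day.isoformat(), "cyp_ddi", a["atc_code"]))

            # lorazepam in severe renal impairment
            lor_today = [a for a in todays
                         if a["atc_code"] == lor_profile.atc_code]
            if lor_today:
                egfr = _egfr_on_day(labs_p, patient["patient_id"], day, age,
                                    patient["sex"])
                if egfr is not None and \
                        egfr < lor_profile.renal_contraindicated_below_egfr:
                    adjacent = any(
                        a["atc_code"] == lor_profile.atc_code
                        and abs((a["day"] - day).days) == 1
                        for a in admins_h
                    )
                    other_bdz = any(
                        a["atc_code"] != lor_profile.atc_code
                        and _is_bdz(a["atc_code"], catalog)
                        for a in todays
                    )
                    if adjacent or other_bdz:
                        flags.add((hid, day.isoformat(), "lorazepam_renal",
                                   lor_profile.atc_code))

            # flumazenil surrogate
            if any(a["atc_code"] == flum_atc for a in todays):
                flags.add((hid, day.isoformat(), "flumazenil_surrogate",
                           flum_atc))

            # elderly zolpidem dose (separate stream, own mechanism name)
            zol_dose = sum(
                a["dose_mg"] for a in todays
                if a["atc_code"] == zol_profile.atc_code
            )
            if age >= 65 and zol_dose >= zol_profile.standard_daily_dose_mg:
                flags.add((hid, day.isoformat(), "elderly_zolpidem_dose",
                           zol_profile.atc_code))

            day = day + timedelta(days=1)
    return flags


def production_flag_keys(result) -> set[tuple]:
    """ScreeningResult flags in the oracle's key shape, both streams."""
    return {
        (f.hosp_id, f.day.isoformat(), f.mechanism, f.bdz_atc)
        for f in list(result.flags) + list(result.elderly_flags)
    }
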