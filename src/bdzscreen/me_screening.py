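"""Per-BDZ detection algorithms emitting potential-medication-error flags.

Four mechanisms, each evaluated at patient-day granularity:

* ``cyp_ddi`` — a CYP-metabolized screened BDZ administered while a strong
  inhibitor of a relevant pathway was given the same day or up to two days
  earlier in the same stay (the carryover window is data on the inhibitor
  entry). Prazepam additionally fires on strong or moderate CYP2C19
  inhibitors; glucuronidation-only drugs (lorazepam) never fire this rule.
* ``lorazepam_renal`` — lorazepam on a day with current eGFR below the
  severe-impairment threshold (30 mL/min), qualified by either lorazepam on
  an adjacent day or at least one other BDZ the same day. Days without a
  current eGFR never flag.
* ``flumazenil_surrogate`` — any administration of the BDZ antidote
  flumazenil; the evidence lists BDZ given that day and the day before.
* ``elderly_zolpidem_dose`` — zolpidem at a non-reduced daily dose
  (>= 10 mg) at age >= 65. These are prescribing-quality findings and are
  kept in a separate stream, outside the potential-ME denominator.

Risk annotations (multiple BDZ, opioids, muscle relaxants, additional
CYP2C19/1A2 inhibitors) are computed per patient-day but are never a
medication error by themselves.

The carryover lookback never crosses a hospitalization boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Optional, Sequence

import pandas as pd

from .atc import atc_matches
from .ehr_model import Dataset, daily_doses, expand_patient_days
from .reference_catalog import Catalog
from .renal_function import (
    DEFAULT_RENAL_PARAMS,
    RenalParameters,
    attach_current_egfr,
)

MECHANISMS = (
    "cyp_ddi",
    "lorazepam_renal",
    "flumazenil_surrogate",
    "elderly_zolpidem_dose",
)
#: mechanisms that count as potential ME (elderly dosing is reported apart)
ME_MECHANISMS = ("cyp_ddi", "lorazepam_renal", "flumazenil_surrogate")

ELDERLY_AGE = 65


@dataclass(frozen=True)
class PotentialMEFlag:
    """One algorithm hit on one patient-day."""

    patient_id: str
    hosp_id: str
    day: date
    mechanism: str
    bdz_atc: str
    trigger_drugs: tuple[tuple[str, int], ...]  # (ATC, day offset 0..-2)
    egfr: Optional[float]
    evidence: str


@dataclass
class ScreeningResult:
    """All flags and annotations, with the three denominators exposed."""

    patient_days: pd.DataFrame
    flags: list[PotentialMEFlag]
    elderly_flags: list[PotentialMEFlag]
    annotations: pd.DataFrame

    def flags_frame(self, stream: str = "me") -> pd.DataFrame:
        src = self.flags if stream == "me" else self.elderly_flags
        rows = [
            {
                "patient_id": f.patient_id,
                "hosp_id": f.hosp_id,
                "day": f.day,
                "mechanism": f.mechanism,
                "bdz_atc": f.bdz_atc,
                "trigger_drugs": ";".join(
                    f"{atc}@{off}" for atc, off in f.trigger_drugs
                ),
                "egfr": f.egfr,
                "evidence": f.evidence,
            }
            for f in src
        ]
        return pd.DataFrame(
            rows,
            columns=["patient_id", "hosp_id", "day", "mechanism", "bdz_atc",
                     "trigger_drugs", "egfr", "evidence"],
        )

    def flagged_hospitalizations(self) -> list[str]:
        return sorted({f.hosp_id for f in self.flags})


def _admin_index(administrations: pd.DataFrame) -> dict[tuple[str, date], list[dict]]:
    """(hosp_id, day) -> administration rows, insertion-order independent."""
    idx: dict[tuple[str, date], list[dict]] = {}
    for row in administrations.sort_values(
        ["hosp_id", "day", "atc_code", "dose_mg", "route"]
    ).to_dict("records"):
        idx.setdefault((row["hosp_id"], row["day"]), []).append(row)
    return idx


def detect_cyp_ddi(
    patient_days: pd.DataFrame,
    administrations: pd.DataFrame,
    catalog: Catalog,
) -> list[PotentialMEFlag]:
    """CYP drug-drug-interaction flags over all patient-days.

    A flag is placed on each BDZ day with at least one qualifying inhibitor
    inside its carryover window; multiple triggers merge into one flag per
    (day, BDZ) with all triggers listed.
    """
    idx = _admin_index(administrations)
    flags: list[PotentialMEFlag] = []
    for pd_row in patient_days.to_dict("records"):
        key = (pd_row["hosp_id"], pd_row["day"])
        admins = idx.get(key, [])
        bdz_here = {}
        for a in admins:
            profile = catalog.bdz_profile(a["atc_code"])
            if profile is not None and profile.trigger_rules():
                bdz_here[a["atc_code"]] = profile
        for bdz_atc, profile in sorted(bdz_here.items()):
            triggers: list[tuple[str, int]] = []
            names: list[str] = []
            for rule in profile.trigger_rules():
                for offset in range(0, 3):
                    prior_day = pd_row["day"] - timedelta(days=offset)
                    for a in idx.get((pd_row["hosp_id"], prior_day), []):
                        for entry in catalog.inhibitor_entries(a["atc_code"]):
                            if entry.pathway != rule.pathway:
                                continue
                            if entry.strength not in rule.strengths:
                                continue
                            if offset > entry.carryover_days:
                                continue
                            trig = (entry.atc_code, -offset)
                            if trig not in triggers:
                                triggers.append(trig)
                                names.append(
                                    f"{entry.drug_name} {entry.atc_code} "
                                    f"({entry.strength} {entry.pathway}) "
                                    f"day {-offset:+d}"
                                )
            if triggers:
                flags.append(
                    PotentialMEFlag(
                        patient_id=pd_row["patient_id"],
                        hosp_id=pd_row["hosp_id"],
                        day=pd_row["day"],
                        mechanism="cyp_ddi",
                        bdz_atc=bdz_atc,
                        trigger_drugs=tuple(sorted(triggers)),
                        egfr=None,
                        evidence=(
                            f"{profile.drug_name} {bdz_atc} with "
                            + "; ".join(sorted(names))
                        ),
                    )
                )
    return flags


def detect_lorazepam_renal(
    patient_days: pd.DataFrame,
    administrations: pd.DataFrame,
    catalog: Catalog,
    params: RenalParameters = DEFAULT_RENAL_PARAMS,
) -> list[PotentialMEFlag]:
    """Lorazepam-in-severe-renal-impairment flags.

    Requires ``patient_days`` to carry a ``current_egfr`` column (see
    :func:`bdzscreen.renal_function.attach_current_egfr`). A qualifying day
    has lorazepam, current eGFR below the profile threshold, and either
    lorazepam on the adjacent previous or next day of the same stay or at
    least one other BDZ the same day; each qualifying day gets its own flag.
    """
    if "current_egfr" not in patient_days.columns:
        raise ValueError("patient_days must carry current_egfr; "
                         "call attach_current_egfr first")
    lor = catalog.bdz_profile_by_name("lorazepam")
    threshold = lor.renal_contraindicated_below_egfr
    idx = _admin_index(administrations)
    flags: list[PotentialMEFlag] = []
    for pd_row in patient_days.to_dict("records"):
        egfr = pd_row.get("current_egfr")
        if egfr is None or pd.isna(egfr):
            continue
        if not egfr < threshold:
            continue
        key = (pd_row["hosp_id"], pd_row["day"])
        admins = idx.get(key, [])
        if not any(a["atc_code"] == lor.atc_code for a in admins):
            continue
        adjacent = any(
            any(a["atc_code"] == lor.atc_code
                for a in idx.get((pd_row["hosp_id"],
                                  pd_row["day"] + timedelta(days=step)), []))
            for step in (-1, 1)
        )
        other_bdz = sorted({
            a["atc_code"] for a in admins
            if a["atc_code"] != lor.atc_code and catalog.is_bdz(a["atc_code"])
        })
        if not (adjacent or other_bdz):
            continue
        qualifier = []
        if adjacent:
            qualifier.append("lorazepam on adjacent day")
        if other_bdz:
            qualifier.append("other BDZ same day: " + ",".join(other_bdz))
        flags.append(
            PotentialMEFlag(
                patient_id=pd_row["patient_id"],
                hosp_id=pd_row["hosp_id"],
                day=pd_row["day"],
                mechanism="lorazepam_renal",
                bdz_atc=lor.atc_code,
                trigger_drugs=tuple((atc, 0) for atc in other_bdz),
                egfr=float(egfr),
                evidence=(
                    f"lorazepam with current eGFR {egfr:.1f} < {threshold:g}"
                    f" mL/min; " + "; ".join(qualifier)
                ),
            )
        )
    return flags


def detect_flumazenil(
    patient_days: pd.DataFrame,
    administrations: pd.DataFrame,
    catalog: Catalog,
) -> list[PotentialMEFlag]:
    """Flag every patient-day with an administration of flumazenil."""
    flum = catalog.drug_classes.flumazenil_atc
    idx = _admin_index(administrations)
    flags: list[PotentialMEFlag] = []
    for pd_row in patient_days.to_dict("records"):
        key = (pd_row["hosp_id"], pd_row["day"])
        if not any(a["atc_code"] == flum for a in idx.get(key, [])):
            continue
        recent_bdz = sorted({
            a["atc_code"]
            for step in (0, -1)
            for a in idx.get((pd_row["hosp_id"],
                              pd_row["day"] + timedelta(days=step)), [])
            if catalog.is_bdz(a["atc_code"])
        })
        flags.append(
            PotentialMEFlag(
                patient_id=pd_row["patient_id"],
                hosp_id=pd_row["hosp_id"],
                day=pd_row["day"],
                mechanism="flumazenil_surrogate",
                bdz_atc=flum,
                trigger_drugs=tuple((atc, 0) for atc in recent_bdz),
                egfr=None,
                evidence=(
                    "flumazenil administered; BDZ on day/day-1: "
                    + (",".join(recent_bdz) if recent_bdz else "none")
                ),
            )
        )
    return flags


def detect_elderly_zolpidem(
    patient_days: pd.DataFrame,
    administrations: pd.DataFrame,
    catalog: Catalog,
) -> list[PotentialMEFlag]:
    """Zolpidem at a non-reduced daily dose in patients aged >= 65.

    The daily dose is the sum of all zolpidem records that day; the
    threshold is the adult standard dose (10 mg), which for the elderly is
    supposed to be halved.
    """
    zol = catalog.bdz_profile_by_name("zolpidem")
    doses = daily_doses(administrations)
    by_day = {
        (r["hosp_id"], r["day"]): r["dose_mg"]
        for r in doses[doses["atc_code"] == zol.atc_code].to_dict("records")
    }
    flags: list[PotentialMEFlag] = []
    for pd_row in patient_days.to_dict("records"):
        if pd_row["age_years"] < ELDERLY_AGE:
            continue
        dose = by_day.get((pd_row["hosp_id"], pd_row["day"]))
        if dose is None or dose < zol.standard_daily_dose_mg:
            continue
        flags.append(
            PotentialMEFlag(
                patient_id=pd_row["patient_id"],
                hosp_id=pd_row["hosp_id"],
                day=pd_row["day"],
                mechanism="elderly_zolpidem_dose",
                bdz_atc=zol.atc_code,
                trigger_drugs=(),
                egfr=None,
                evidence=(
                    f"zolpidem {dose:g} mg/day at age {pd_row['age_years']} "
                    f"(recommended {zol.elderly_daily_dose_mg:g} mg at >= "
                    f"{ELDERLY_AGE} y)"
                ),
            )
        )
    return flags


def annotate_risks(
    patient_days: pd.DataFrame,
    administrations: pd.DataFrame,
    catalog: Catalog,
) -> pd.DataFrame:
    """Per patient-day risk factors; never a medication error by themselves.

    Columns: n_distinct_bdz, n_opioids (distinct opioid ATC codes),
    muscle_relaxant, extra_inhibitors (subset of CYP2C19/CYP1A2, joined
    with '|').
    """
    idx = _admin_index(administrations)
    dc = catalog.drug_classes
    rows = []
    for pd_row in patient_days.to_dict("records"):
        admins = idx.get((pd_row["hosp_id"], pd_row["day"]), [])
        codes = {a["atc_code"] for a in admins}
        bdz = {c for c in codes if catalog.is_bdz(c)}
        opioids = {
            c for c in codes
            if any(atc_matches(c, p) for p in dc.opioid_atc_prefixes)
        }
        relaxant = any(
            atc_matches(c, p)
            for c in codes for p in dc.muscle_relaxant_atc_prefixes
        )
        extra = {
            e.pathway
            for c in codes for e in catalog.inhibitor_entries(c)
            if e.pathway in ("CYP2C19", "CYP1A2")
        }
        rows.append(
            {"patient_id": pd_row["patient_id"], "hosp_id": pd_row["hosp_id"],
             "day": pd_row["day"], "n_distinct_bdz": len(bdz),
             "n_opioids": len(opioids), "muscle_relaxant": relaxant,
             "extra_inhibitors": "|".join(sorted(extra))}
        )
    return pd.DataFrame(
        rows,
        columns=["patient_id", "hosp_id", "day", "n_distinct_bdz",
                 "n_opioids", "muscle_relaxant", "extra_inhibitors"],
    )


def screen_all(
    dataset: Dataset,
    catalog: Catalog,
    params: RenalParameters = DEFAULT_RENAL_PARAMS,
    mechanisms: Sequence[str] = MECHANISMS,
) -> ScreeningResult:
    """Run every enabled detection mechanism over a validated dataset.

    Deterministic: input row order never changes the output. Flags are
    sorted by (hosp_id, day, mechanism, bdz_atc).
    """
    unknown = set(mechanisms) - set(MECHANISMS)
    if unknown:
        raise ValueError(f"unknown mechanisms: {sorted(unknown)}")
    pdays = expand_patient_days(dataset)
    pdays = attach_current_egfr(pdays, dataset.labs, params)
    admins = dataset.administrations
    flags: list[PotentialMEFlag] = []
    if "cyp_ddi" in mechanisms:
        flags += detect_cyp_ddi(pdays, admins, catalog)
    if "lorazepam_renal" in mechanisms:
        flags += detect_lorazepam_renal(pdays, admins, catalog, params)
    if "flumazenil_surrogate" in mechanisms:
        flags += detect_flumazenil(pdays, admins, catalog)
    elderly: list[PotentialMEFlag] = []
    if "elderly_zolpidem_dose" in mechanisms:
        elderly = detect_elderly_zolpidem(pdays, admins, catalog)
    key = lambda f: (f.hosp_id, f.day, f.mechanism, f.bdz_atc)
    return ScreeningResult(
        patient_days=pdays,
        flags=sorted(flags, key=key),
        elderly_flags=sorted(elderly, key=key),
        annotations=annotate_risks(pdays, admins, catalog),
    )
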