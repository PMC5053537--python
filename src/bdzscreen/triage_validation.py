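"""Deterministic triage of flagged hospitalizations.

The clinical validation of a potential medication error is expert judgment
on free-text records; this module encodes only its deterministic skeleton
and is a triage assistant, not a replacement adjudicator. Per flagged
hospitalization it applies, in order:

* exclusions — a palliative situation or known BDZ abuse means the benefit
  outweighs the risk or high doses are tolerated (NO_ME); careful dosing
  (every flagged BDZ at no more than half its standard daily dose on every
  flagged day) also rules a medication error out;
* aggravators — at least one other BDZ on a flagged day, severe respiratory
  insufficiency, severe liver disease, or age >= 65 with the first
  administered dose of the flagged BDZ not reduced below standard. With no
  exclusion and at least ``aggravator_threshold`` aggravators the
  hospitalization is a VALIDATED_ME;
* anything the rules cannot decide is NEEDS_REVIEW.

Patients who withheld research consent are excluded from triage entirely.
WHO/CIOMS causality is carried as a reviewer-supplied annotation, never
computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import pandas as pd
from pydantic import BaseModel, Field

from .ehr_model import Dataset, age_at, daily_doses
from .me_screening import PotentialMEFlag, ScreeningResult
from .reference_catalog import Catalog

CLASSIFICATIONS = ("NO_ME", "VALIDATED_ME", "NEEDS_REVIEW")
EXCLUSION_RULES = ("palliative", "known_abuse", "low_dose")
AGGRAVATING_RULES = (
    "multi_bdz",
    "respiratory_insufficiency",
    "severe_liver_disease",
    "elderly_unreduced_dose",
)


class TriagePolicy(BaseModel):
    """Which rules are active and how many aggravators validate an ME."""

    palliative: bool = True
    known_abuse: bool = True
    low_dose: bool = True
    multi_bdz: bool = True
    respiratory_insufficiency: bool = True
    severe_liver_disease: bool = True
    elderly_unreduced_dose: bool = True
    aggravator_threshold: int = Field(default=1, ge=1)
    low_dose_fraction: float = Field(default=0.5, gt=0)

    def enabled_exclusions(self) -> list[str]:
        return [r for r in EXCLUSION_RULES if getattr(self, r)]

    def enabled_aggravators(self) -> list[str]:
        return [r for r in AGGRAVATING_RULES if getattr(self, r)]


@dataclass(frozen=True)
class TriageDecision:
    hosp_id: str
    classification: str
    exclusion_rules_fired: tuple[str, ...]
    aggravating_rules_fired: tuple[str, ...]
    notes: str
    cioms_causality: Optional[str] = None  # reviewer annotation, pass-through


def _flagged_bdz_doses(
    flags: list[PotentialMEFlag],
    administrations: pd.DataFrame,
    catalog: Catalog,
) -> list[tuple[PotentialMEFlag, float, float]]:
    """(flag, daily dose on flag day, standard dose) for dosable flagged BDZ."""
    doses = daily_doses(administrations)
    out = []
    for f in flags:
        profile = catalog.bdz_profile(f.bdz_atc)
        if profile is None:
            continue  # e.g. flumazenil surrogate: no BDZ dose to judge
        sel = doses[
            (doses["hosp_id"] == f.hosp_id)
            & (doses["day"] == f.day)
            & (doses["atc_code"] == f.bdz_atc)
        ]
        if sel.empty:
            continue
        out.append((f, float(sel["dose_mg"].iloc[0]),
                    profile.standard_daily_dose_mg))
    return out


def triage(
    hospitalization: pd.Series,
    flags: list[PotentialMEFlag],
    annotations: pd.DataFrame,
    dataset: Dataset,
    catalog: Catalog,
    policy: TriagePolicy = TriagePolicy(),
    cioms_causality: Optional[str] = None,
) -> TriageDecision:
    """Classify one flagged hospitalization as NO_ME / VALIDATED_ME / NEEDS_REVIEW."""
    if not flags:
        raise ValueError("triage requires at least one potential-ME flag")
    hid = hospitalization["hosp_id"]
    for f in flags:
        if f.hosp_id != hid:
            raise ValueError(
                f"flag for hospitalization {f.hosp_id!r} passed to {hid!r}"
            )
    admins = dataset.administrations[dataset.administrations["hosp_id"] == hid]

    exclusions: list[str] = []
    notes: list[str] = []
    if policy.palliative and bool(hospitalization["palliative"]):
        exclusions.append("palliative")
        notes.append("palliative situation: benefit outweighs risk")
    if policy.known_abuse and bool(hospitalization["known_bdz_abuse"]):
        exclusions.append("known_abuse")
        notes.append("known BDZ abuse: tolerance of high doses")
    dosed = _flagged_bdz_doses(flags, admins, catalog)
    if policy.low_dose and dosed and all(
        dose <= policy.low_dose_fraction * std for _, dose, std in dosed
    ):
        exclusions.append("low_dose")
        notes.append(
            f"all flagged BDZ at <= {policy.low_dose_fraction:g} of standard dose"
        )

    aggravators: list[str] = []
    flag_days = {(f.hosp_id, f.day) for f in flags}
    if policy.multi_bdz:
        ann = annotations[
            annotations.apply(
                lambda r: (r["hosp_id"], r["day"]) in flag_days, axis=1
            )
        ] if not annotations.empty else annotations
        if not ann.empty and (ann["n_distinct_bdz"] >= 2).any():
            aggravators.append("multi_bdz")
            notes.append(">=1 other BDZ on a flagged day")
    if policy.respiratory_insufficiency and bool(
        hospitalization["respiratory_insufficiency"]
    ):
        aggravators.append("respiratory_insufficiency")
        notes.append("severe respiratory insufficiency")
    if policy.severe_liver_disease and bool(
        hospitalization["severe_liver_disease"]
    ):
        aggravators.append("severe_liver_disease")
        notes.append("severe liver disease")
    if policy.elderly_unreduced_dose:
        ddoses = daily_doses(admins)
        birth = dict(zip(dataset.patients["patient_id"],
                         dataset.patients["birth_date"]))
        for f in flags:
            profile = catalog.bdz_profile(f.bdz_atc)
            if profile is None:
                continue
            drug_days = ddoses[ddoses["atc_code"] == f.bdz_atc]
            if drug_days.empty:
                continue
            first = drug_days.loc[drug_days["day"].idxmin()]
            age = age_at(birth[hospitalization["patient_id"]], first["day"])
            if age >= 65 and first["dose_mg"] >= profile.standard_daily_dose_mg:
                if "elderly_unreduced_dose" not in aggravators:
                    aggravators.append("elderly_unreduced_dose")
                    notes.append(
                        f"age {age} with initial {profile.drug_name} dose "
                        f"{first['dose_mg']:g} mg not reduced"
                    )

    if exclusions:
        cls = "NO_ME"
    elif len(aggravators) >= policy.aggravator_threshold:
        cls = "VALIDATED_ME"
    else:
        cls = "NEEDS_REVIEW"
        notes.append("rules cannot decide; manual review required")
    return TriageDecision(
        hosp_id=hid,
        classification=cls,
        exclusion_rules_fired=tuple(exclusions),
        aggravating_rules_fired=tuple(aggravators),
        notes="; ".join(notes),
        cioms_causality=cioms_causality,
    )


def triage_batch(
    screening: ScreeningResult,
    dataset: Dataset,
    catalog: Catalog,
    policy: TriagePolicy = TriagePolicy(),
    cioms: Optional[Mapping[str, str]] = None,
) -> tuple[list[TriageDecision], pd.DataFrame]:
    """One decision per flagged hospitalization, plus a summary.

    Hospitalizations of patients who withheld research consent are excluded
    from triage entirely. The summary counts hospitalizations per
    classification for each mechanism present (a hospitalization with two
    mechanisms appears in both mechanism rows, once in row ``all``).
    """
    cioms = cioms or {}
    consent = dict(zip(dataset.patients["patient_id"],
                       dataset.patients["research_consent"]))
    by_hosp: dict[str, list[PotentialMEFlag]] = {}
    for f in screening.flags:
        by_hosp.setdefault(f.hosp_id, []).append(f)
    decisions: list[TriageDecision] = []
    for hid in sorted(by_hosp):
        hosp = dataset.hospitalization(hid)
        if not consent.get(hosp["patient_id"], True):
            continue
        decisions.append(
            triage(hosp, by_hosp[hid], screening.annotations, dataset,
                   catalog, policy, cioms.get(hid))
        )
    rows = []
    mechs = sorted({f.mechanism for f in screening.flags})
    decided = {d.hosp_id: d for d in decisions}
    for mech in mechs + ["all"]:
        hids = (
            {f.hosp_id for f in screening.flags if f.mechanism == mech}
            if mech != "all" else set(by_hosp)
        )
        counts = {c: 0 for c in CLASSIFICATIONS}
        for hid in hids:
            if hid in decided:
                counts[decided[hid].classification] += 1
        rows.append({"mechanism": mech, "n_hospitalizations": len(hids & set(decided)),
                     **counts})
    summary = pd.DataFrame(
        rows, columns=["mechanism", "n_hospitalizations", *CLASSIFICATIONS]
    )
    return decisions, summary


def decisions_frame(decisions: Iterable[TriageDecision]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"hosp_id": d.hosp_id, "classification": d.classification,
             "exclusion_rules_fired": "|".join(d.exclusion_rules_fired),
             "aggravating_rules_fired": "|".join(d.aggravating_rules_fired),
             "notes": d.notes, "cioms_causality": d.cioms_causality or ""}
            for d in decisions
        ],
        columns=["hosp_id", "classification", "exclusion_rules_fired",
                 "aggravating_rules_fired", "notes", "cioms_causality"],
    )
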