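"""Prevalence aggregation over the three denominators.

Every frequency in this package is reported against one or more of three
denominators: patient-days, individual patients and hospitalizations. A
day with two different BDZ counts once toward "any BDZ" but once for each
drug, so per-drug counts do not sum to the any-BDZ count.

Percentages are rounded half-up (2.5 rounds to 3, unlike banker's
rounding) at one decimal, switching to two decimals when the one-decimal
value would fall below 0.3 so that very rare events stay visible.
Every percentage is emitted alongside its numerator and denominator, so
any printed value can be recomputed exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import date
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable

import pandas as pd

from .atc import atc_matches
from .ehr_model import Dataset, expand_patient_days
from .me_screening import ME_MECHANISMS, ScreeningResult
from .reference_catalog import Catalog
from .triage_validation import TriageDecision


def prevalence(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage with round-half-up at ``decimals`` decimal places.

    A zero denominator is an error, never NaN; the numerator may not
    exceed the denominator.
    """
    if denominator <= 0:
        raise ValueError(f"denominator must be positive, got {denominator}")
    if numerator < 0 or numerator > denominator:
        raise ValueError(
            f"numerator {numerator} outside [0, {denominator}]"
        )
    q = Decimal(1).scaleb(-decimals)
    pct = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def adaptive_prevalence(numerator: int, denominator: int) -> float:
    """One decimal normally; two decimals when the value is below 0.3%."""
    one = prevalence(numerator, denominator, 1)
    if one < 0.3:
        return prevalence(numerator, denominator, 2)
    return one


def _pct_entry(n: int, d: int) -> dict:
    return {"n": int(n), "denominator": int(d),
            "pct": adaptive_prevalence(n, d) if d else None}


@dataclass
class StudyWindow:
    start: date
    end: date

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1


DEFAULT_STUDY_WINDOW = StudyWindow(date(2011, 1, 1), date(2012, 12, 31))


def _tri_counts(
    pdays: pd.DataFrame, mask: pd.Series
) -> tuple[int, int, int]:
    """(patient-days, patients, hospitalizations) touched by ``mask``."""
    sel = pdays[mask]
    return (len(sel), sel["patient_id"].nunique(), sel["hosp_id"].nunique())


def usage_report(dataset: Dataset, catalog: Catalog) -> dict:
    """Population-characteristics report: BDZ use over all three denominators.

    Covers any-BDZ use, age and sex strata, per-drug frequencies,
    multi-BDZ day distribution, opioid co-medication and concomitant-drug
    count bands, each with numerator, denominator and percentage.
    """
    pdays = expand_patient_days(dataset)
    admins = dataset.administrations
    denom_days = len(pdays)
    denom_patients = len(dataset.patients)
    denom_hosp = len(dataset.hospitalizations)

    bdz_admins = admins[[catalog.is_bdz(c) for c in admins["atc_code"]]]
    day_key = pd.MultiIndex.from_frame(pdays[["hosp_id", "day"]])
    bdz_days_set = set(zip(bdz_admins["hosp_id"], bdz_admins["day"]))
    on_bdz = pd.Series(
        [k in bdz_days_set for k in zip(pdays["hosp_id"], pdays["day"])],
        index=pdays.index,
    )
    n_days, n_pat, n_hosp = _tri_counts(pdays, on_bdz)

    report: dict = {
        "denominators": {
            "patient_days": denom_days,
            "patients": denom_patients,
            "hospitalizations": denom_hosp,
        },
        "any_bdz": {
            "patient_days": _pct_entry(n_days, denom_days),
            "patients": _pct_entry(n_pat, denom_patients),
            "hospitalizations": _pct_entry(n_hosp, denom_hosp),
        },
    }

    # strata over BDZ-exposed patient-days (study-population denominators)
    bdz_pdays = pdays[on_bdz]
    sp_days = max(len(bdz_pdays), 1)
    age_bands = [("<18", 0, 17), ("18-44", 18, 44), ("45-64", 45, 64),
                 ("65-85", 65, 85), (">85", 86, 200)]
    report["age_bands_patient_days"] = {
        label: _pct_entry(
            int(((bdz_pdays["age_years"] >= lo)
                 & (bdz_pdays["age_years"] <= hi)).sum()),
            sp_days,
        )
        for label, lo, hi in age_bands
    }
    report["sex_patient_days"] = {
        s: _pct_entry(int((bdz_pdays["sex"] == s).sum()), sp_days)
        for s in ("male", "female")
    }

    # per-drug frequencies over BDZ-study-population denominators
    sp_patients = max(bdz_pdays["patient_id"].nunique(), 1)
    sp_hosp = max(bdz_pdays["hosp_id"].nunique(), 1)
    per_drug = {}
    for profile in catalog.bdz:
        sel = bdz_admins[bdz_admins["atc_code"] == profile.atc_code]
        d = sel.drop_duplicates(["hosp_id", "day"])
        per_drug[profile.drug_name] = {
            "patient_days": _pct_entry(len(d), sp_days),
            "patients": _pct_entry(sel["patient_id"].nunique(), sp_patients),
            "hospitalizations": _pct_entry(sel["hosp_id"].nunique(), sp_hosp),
        }
    report["per_bdz"] = per_drug

    # distribution of distinct BDZ per day / opioids per day
    if not bdz_admins.empty:
        per_day_bdz = (
            bdz_admins.groupby(["hosp_id", "day"])["atc_code"].nunique()
        )
        report["multi_bdz_patient_days"] = {
            "2": _pct_entry(int((per_day_bdz == 2).sum()), sp_days),
            "3": _pct_entry(int((per_day_bdz == 3).sum()), sp_days),
            ">=4": _pct_entry(int((per_day_bdz >= 4).sum()), sp_days),
        }
    else:
        report["multi_bdz_patient_days"] = {
            k: _pct_entry(0, sp_days) for k in ("2", "3", ">=4")
        }

    opioid_admins = admins[
        [any(atc_matches(c, p)
             for p in catalog.drug_classes.opioid_atc_prefixes)
         for c in admins["atc_code"]]
    ]
    op_on_bdz = opioid_admins[
        [k in bdz_days_set
         for k in zip(opioid_admins["hosp_id"], opioid_admins["day"])]
    ]
    if not op_on_bdz.empty:
        per_day_op = op_on_bdz.groupby(["hosp_id", "day"])["atc_code"].nunique()
        any_op = int(len(per_day_op))
        multi_op = int((per_day_op >= 2).sum())
    else:
        any_op = multi_op = 0
    report["opioid_comedication_patient_days"] = {
        "any": _pct_entry(any_op, sp_days),
        ">=2": _pct_entry(multi_op, sp_days),
    }

    # concomitant drug count bands on BDZ days (distinct ATC codes - BDZ)
    if not admins.empty:
        per_day_total = admins.groupby(["hosp_id", "day"])["atc_code"].nunique()
        bands = {"1-5": 0, "6-10": 0, "11-20": 0, ">=21": 0}
        for (h, d), n_bdz in (
            bdz_admins.groupby(["hosp_id", "day"])["atc_code"].nunique().items()
        ):
            conc = int(per_day_total.loc[(h, d)]) - int(n_bdz)
            if conc <= 5:
                bands["1-5"] += 1
            elif conc <= 10:
                bands["6-10"] += 1
            elif conc <= 20:
                bands["11-20"] += 1
            else:
                bands[">=21"] += 1
        report["concomitant_drug_bands_patient_days"] = {
            k: _pct_entry(v, sp_days) for k, v in bands.items()
        }
    return report


def potential_me_report(
    screening: ScreeningResult,
    dataset: Dataset,
    catalog: Catalog,
    window: StudyWindow = DEFAULT_STUDY_WINDOW,
) -> dict:
    """Algorithm-hit report: potential ME per mechanism and per BDZ.

    Per drug: flagged patient-days and hospitalizations with the share of
    that drug's own use; overall: total flagged patient-days, the mean
    number of potential ME per calendar day of the study window, and each
    mechanism's share of all potential ME.
    """
    admins = dataset.administrations
    flags = screening.flags
    per_drug: dict = {}
    drug_of = {p.atc_code: p.drug_name for p in catalog.bdz}
    for atc, name in drug_of.items():
        use = admins[admins["atc_code"] == atc]
        use_days = len(use.drop_duplicates(["hosp_id", "day"]))
        use_hosp = use["hosp_id"].nunique()
        fl = [f for f in flags if f.bdz_atc == atc]
        fl_days = len({(f.hosp_id, f.day) for f in fl})
        fl_hosp = len({f.hosp_id for f in fl})
        per_drug[name] = {
            "use_patient_days": use_days,
            "use_hospitalizations": use_hosp,
            "me_patient_days": _pct_entry(fl_days, use_days) if use_days
            else {"n": 0, "denominator": 0, "pct": None},
            "me_hospitalizations": _pct_entry(fl_hosp, use_hosp) if use_hosp
            else {"n": 0, "denominator": 0, "pct": None},
        }
    total_days = len({(f.hosp_id, f.day) for f in flags})
    total_hosp = len({f.hosp_id for f in flags})
    per_mech = {}
    for mech in ME_MECHANISMS:
        md = len({(f.hosp_id, f.day) for f in flags if f.mechanism == mech})
        per_mech[mech] = (
            _pct_entry(md, total_days) if total_days
            else {"n": 0, "denominator": 0, "pct": None}
        )
    mean_per_day = round(total_days / window.n_days, 1)
    elderly_days = len(
        {(f.hosp_id, f.day) for f in screening.elderly_flags}
    )
    return {
        "per_bdz": per_drug,
        "totals": {
            "potential_me_patient_days": total_days,
            "potential_me_hospitalizations": total_hosp,
            "study_window_days": window.n_days,
            "mean_potential_me_per_calendar_day": mean_per_day,
        },
        "per_mechanism_share": per_mech,
        "elderly_zolpidem_patient_days": elderly_days,  # separate stream
    }


def triage_report(
    decisions: Iterable[TriageDecision],
    screening: ScreeningResult,
    catalog: Catalog,
) -> dict:
    """Validation report per BDZ: potential vs validated medication errors."""
    decided = {d.hosp_id: d for d in decisions}
    drug_of = {p.atc_code: p.drug_name for p in catalog.bdz}
    drug_of[catalog.drug_classes.flumazenil_atc] = "flumazenil"
    per_drug: dict = {}
    for atc, name in drug_of.items():
        hids = sorted({
            f.hosp_id for f in screening.flags if f.bdz_atc == atc
            and f.hosp_id in decided
        })
        if not hids:
            continue
        counts = {"NO_ME": 0, "VALIDATED_ME": 0, "NEEDS_REVIEW": 0}
        for hid in hids:
            counts[decided[hid].classification] += 1
        n = len(hids)
        per_drug[name] = {
            "potential_me_hospitalizations": n,
            "no_me": _pct_entry(counts["NO_ME"], n),
            "validated_me": _pct_entry(counts["VALIDATED_ME"], n),
            "needs_review": _pct_entry(counts["NEEDS_REVIEW"], n),
        }
    n_all = len(decided)
    n_val = sum(
        1 for d in decided.values() if d.classification == "VALIDATED_ME"
    )
    return {
        "per_bdz": per_drug,
        "totals": {
            "triaged_hospitalizations": n_all,
            "validated_me": _pct_entry(n_val, n_all) if n_all
            else {"n": 0, "denominator": 0, "pct": None},
        },
    }


def write_report_json(report: dict, path: str | Path) -> Path:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n",
                 encoding="utf-8")
    return p


def _md_pct(entry: dict) -> str:
    if entry.get("pct") is None:
        return f"{entry.get('n', 0)} / -"
    return f"{entry['n']:,} ({entry['pct']}%)"


def write_report_md(reports: dict[str, dict], path: str | Path) -> Path:
    """Small human-readable digest of the usage / potential-ME / triage reports."""
    lines = ["# Screening report", ""]
    usage = reports.get("usage")
    if usage:
        lines += ["## BDZ use", ""]
        for denom, entry in usage["any_bdz"].items():
            lines.append(f"- any BDZ, {denom.replace('_', ' ')}: {_md_pct(entry)}")
        lines.append("")
        lines += ["| drug | patient-days | patients | hospitalizations |",
                  "|---|---|---|---|"]
        for drug, row in usage["per_bdz"].items():
            lines.append(
                f"| {drug} | {_md_pct(row['patient_days'])} | "
                f"{_md_pct(row['patients'])} | "
                f"{_md_pct(row['hospitalizations'])} |"
            )
        lines.append("")
    pme = reports.get("potential_me")
    if pme:
        t = pme["totals"]
        lines += [
            "## Potential medication errors", "",
            f"- flagged patient-days: {t['potential_me_patient_days']:,}",
            f"- flagged hospitalizations: {t['potential_me_hospitalizations']:,}",
            f"- mean potential ME per calendar day: "
            f"{t['mean_potential_me_per_calendar_day']}",
            "",
        ]
    tri = reports.get("triage")
    if tri:
        lines += ["## Triage", ""]
        for drug, row in tri["per_bdz"].items():
            lines.append(
                f"- {drug}: {row['potential_me_hospitalizations']} flagged "
                f"hospitalizations, validated {_md_pct(row['validated_me'])}"
            )
        lines.append("")
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text("\n".join(lines), encoding="utf-8")
    return p
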