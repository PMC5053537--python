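"""CKD-EPI eGFR and the 72-hour creatinine recency rule.

The 2009 creatinine-based CKD-EPI equation (no race term — the data model
carries none) estimates glomerular filtration rate in mL/min/1.73 m² from
serum creatinine, age and sex:

    eGFR = 141 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.209
           * 0.993^age * (1.018 if female)

with k = 0.7 / a = -0.329 for women and k = 0.9 / a = -0.411 for men,
Scr in mg/dL. Creatinine reported in µmol/L is converted by dividing
by 88.4.

A "current eGFR" on a given administration day is derived from the most
recent creatinine drawn within 72 hours before that day. Administrations
are day-granular while labs are timestamped, so the window is anchored at
the start of the administration day: (day 00:00 − 72 h, day 00:00]. A day
with no qualifying creatinine has no current eGFR (absence is a value: the
renal rule simply cannot fire).
"""

from __future__ import annotations

from datetime import date, datetime, timedelta
from typing import Optional

import pandas as pd
from pydantic import BaseModel

UMOL_PER_L_TO_MG_PER_DL = 88.4


class RenalParameters(BaseModel):
    """CKD-EPI 2009 constants plus the screening thresholds.

    The equation constants are fixed; ``severe_threshold`` (mL/min) and
    ``recency_window_hours`` are configurable and default to the screening
    rule's values (30 mL/min, 72 h).
    """

    kappa_female: float = 0.7
    kappa_male: float = 0.9
    alpha_female: float = -0.329
    alpha_male: float = -0.411
    nonlinear_exponent: float = -1.209
    age_factor: float = 0.993
    female_factor: float = 1.018
    intercept: float = 141.0
    severe_threshold: float = 30.0
    recency_window_hours: float = 72.0


DEFAULT_RENAL_PARAMS = RenalParameters()


def egfr_ckdepi(
    scr_mg_dl: float,
    age_years: float,
    sex: str,
    params: RenalParameters = DEFAULT_RENAL_PARAMS,
    decimals: int | None = 1,
) -> float:
    """CKD-EPI 2009 eGFR in mL/min/1.73 m², reported to one decimal.

    ``scr_mg_dl`` must be positive and ``age_years`` at least 18 (the
    equation is adult-only); violations raise rather than default.
    ``decimals=None`` returns the unrounded value (for numerical
    cross-checks).
    """
    if not scr_mg_dl > 0:
        raise ValueError(f"creatinine must be positive, got {scr_mg_dl}")
    if age_years < 18:
        raise ValueError(f"CKD-EPI is adult-only, got age {age_years}")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if sex == "female":
        kappa, alpha = params.kappa_female, params.alpha_female
    else:
        kappa, alpha = params.kappa_male, params.alpha_male
    ratio = scr_mg_dl / kappa
    egfr = (
        params.intercept
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** params.nonlinear_exponent
        * params.age_factor ** age_years
    )
    if sex == "female":
        egfr *= params.female_factor
    return egfr if decimals is None else round(egfr, decimals)


def creatinine_mg_dl(value: float, units: str) -> float:
    """Convert a creatinine value to mg/dL; units are declared, never guessed."""
    if units == "mg_per_dL":
        return value
    if units == "umol_per_L":
        return value / UMOL_PER_L_TO_MG_PER_DL
    raise ValueError(f"unknown creatinine units {units!r}")


def current_egfr(
    labs: pd.DataFrame,
    patient_id: str,
    day: date,
    age_years: float,
    sex: str,
    params: RenalParameters = DEFAULT_RENAL_PARAMS,
) -> Optional[float]:
    """eGFR from the most recent creatinine within the recency window.

    Candidate labs are the patient's creatinine measurements with
    timestamp in (day 00:00 − window, day 00:00]; the most recent wins,
    independent of row order. Returns None when no lab qualifies or the
    patient is under 18 (the equation does not apply).
    """
    if age_years < 18:
        return None
    window_end = datetime(day.year, day.month, day.day)
    window_start = window_end - timedelta(hours=params.recency_window_hours)
    cand = labs[
        (labs["patient_id"] == patient_id)
        & (labs["analyte"] == "creatinine")
        & (labs["timestamp"] > window_start)
        & (labs["timestamp"] <= window_end)
    ]
    if cand.empty:
        return None
    best = cand.loc[cand["timestamp"].idxmax()]
    scr = creatinine_mg_dl(float(best["value"]), str(best["units"]))
    return egfr_ckdepi(scr, age_years, sex, params)


def attach_current_egfr(
    patient_days: pd.DataFrame,
    labs: pd.DataFrame,
    params: RenalParameters = DEFAULT_RENAL_PARAMS,
) -> pd.DataFrame:
    """Add a ``current_egfr`` column (None where absent) to patient-days.

    Same semantics as calling :func:`current_egfr` per row; labs are
    pre-grouped per patient and scanned sorted, so the result is
    independent of input row order.
    """
    by_patient: dict[str, list[tuple[datetime, float, str]]] = {}
    cre = labs[labs["analyte"] == "creatinine"]
    for row in cre.itertuples(index=False):
        by_patient.setdefault(row.patient_id, []).append(
            (row.timestamp, float(row.value), str(row.units))
        )
    for entries in by_patient.values():
        entries.sort(key=lambda t: t[0])

    window = timedelta(hours=params.recency_window_hours)
    values: list[Optional[float]] = []
    for row in patient_days.itertuples(index=False):
        if row.age_years < 18:
            values.append(None)
            continue
        end = datetime(row.day.year, row.day.month, row.day.day)
        start = end - window
        best = None
        for ts, value, units in reversed(by_patient.get(row.patient_id, [])):
            if ts <= end:
                if ts > start:
                    best = (ts, value, units)
                break  # sorted: everything earlier is older still
        if best is None:
            values.append(None)
        else:
            scr = creatinine_mg_dl(best[1], best[2])
            values.append(egfr_ckdepi(scr, row.age_years, row.sex, params))
    out = patient_days.copy()
    out["current_egfr"] = pd.Series(values, index=out.index, dtype=object)
    return out
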