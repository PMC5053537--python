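"""Domain model and delimited-text I/O for the hospital dataset.

Four tables describe an inpatient population at calendar-day granularity:
patients (demographics), hospitalizations (stays with validation-relevant
flags), administrations (one drug given to one patient on one day, with
ATC code, dose in mg and route) and labs (timestamped creatinine values).

Administrations are day-granular because every screening rule operates on
patient-days; lab results keep their timestamp because the renal rule needs
a 72-hour recency window. A stay contributes ``discharge - admit + 1``
patient-days (both bounds inclusive), so a same-day admission and discharge
counts as one patient-day.

Readers validate every row against the referential and range invariants and
collect violating rows into a rejection report rather than dropping them
silently.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Mapping

import pandas as pd

from .atc import is_valid_atc

SEXES = ("male", "female")
ROUTES = ("oral", "intravenous", "other")
LAB_UNITS = ("umol_per_L", "mg_per_dL")
ANALYTES = ("creatinine",)

TABLE_COLUMNS: dict[str, list[str]] = {
    "patients": ["patient_id", "birth_date", "sex", "research_consent"],
    "hospitalizations": [
        "hosp_id",
        "patient_id",
        "admit_date",
        "discharge_date",
        "palliative",
        "known_bdz_abuse",
        "respiratory_insufficiency",
        "severe_liver_disease",
    ],
    "administrations": [
        "patient_id",
        "hosp_id",
        "day",
        "atc_code",
        "drug_name",
        "dose_mg",
        "route",
    ],
    "labs": ["patient_id", "timestamp", "analyte", "value", "units"],
}

_TRUE = {"true", "1", "yes", "y"}
_FALSE = {"false", "0", "no", "n"}


class DatasetError(ValueError):
    """Fatal dataset-level problem (missing file, missing column)."""


@dataclass(frozen=True)
class Rejection:
    """One input row that violated an invariant, with the reason."""

    table: str
    row: int  # 1-based data-row index within its table
    reason: str


@dataclass
class Dataset:
    """Validated hospital dataset: four tables plus the rejection report."""

    patients: pd.DataFrame
    hospitalizations: pd.DataFrame
    administrations: pd.DataFrame
    labs: pd.DataFrame
    rejections: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["table", "row", "reason"])
    )

    def hospitalization(self, hosp_id: str) -> pd.Series:
        rows = self.hospitalizations[self.hospitalizations["hosp_id"] == hosp_id]
        if rows.empty:
            raise KeyError(f"unknown hospitalization {hosp_id!r}")
        return rows.iloc[0]


def _parse_date(text: str) -> date:
    return date.fromisoformat(text.strip())


def _parse_timestamp(text: str) -> datetime:
    return datetime.fromisoformat(text.strip())


def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ValueError(f"not a boolean: {text!r}")


def age_at(birth_date: date, on: date) -> int:
    """Completed years between ``birth_date`` and ``on``."""
    years = on.year - birth_date.year
    if (on.month, on.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _read_rows(path: Path, table: str) -> list[dict[str, str]]:
    if not path.exists():
        raise DatasetError(f"missing input file for table {table!r}: {path}")
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise DatasetError(f"empty file for table {table!r}: {path}")
    delim = _sniff_delimiter(text.splitlines()[0])
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    cols = set(reader.fieldnames or [])
    missing = set(TABLE_COLUMNS[table]) - cols
    if missing:
        raise DatasetError(
            f"table {table!r} is missing columns: {sorted(missing)}"
        )
    return list(reader)


def read_dataset(paths: Mapping[str, str | Path]) -> Dataset:
    """Read and validate the four tables.

    ``paths`` maps table names (``patients``, ``hospitalizations``,
    ``administrations``, ``labs``) to delimited-text files (comma or tab,
    auto-detected from the header row).

    Rows that violate an invariant — unparseable date, malformed ATC code,
    dangling reference, administration day outside its stay — are collected
    into ``Dataset.rejections`` with a reason; they never crash the read and
    are never silently dropped.
    """
    for table in TABLE_COLUMNS:
        if table not in paths:
            raise DatasetError(f"no path given for table {table!r}")

    rejections: list[Rejection] = []

    # --- patients ---
    pat_rows = []
    seen_patients: set[str] = set()
    for i, row in enumerate(_read_rows(Path(paths["patients"]), "patients"), start=1):
        pid = (row["patient_id"] or "").strip()
        try:
            if not pid:
                raise ValueError("empty patient_id")
            if pid in seen_patients:
                raise ValueError(f"duplicate patient_id {pid!r}")
            bdate = _parse_date(row["birth_date"])
            sex = row["sex"].strip().lower()
            if sex not in SEXES:
                raise ValueError(f"unknown sex {row['sex']!r}")
            consent = _parse_bool(row["research_consent"])
        except ValueError as exc:
            rejections.append(Rejection("patients", i, str(exc)))
            continue
        seen_patients.add(pid)
        pat_rows.append(
            {"patient_id": pid, "birth_date": bdate, "sex": sex,
             "research_consent": consent}
        )
    patients = pd.DataFrame(pat_rows, columns=TABLE_COLUMNS["patients"])

    # --- hospitalizations ---
    hosp_rows = []
    hosp_index: dict[str, tuple[str, date, date]] = {}
    for i, row in enumerate(
        _read_rows(Path(paths["hospitalizations"]), "hospitalizations"), start=1
    ):
        hid = (row["hosp_id"] or "").strip()
        pid = (row["patient_id"] or "").strip()
        try:
            if not hid:
                raise ValueError("empty hosp_id")
            if hid in hosp_index:
                raise ValueError(f"duplicate hosp_id {hid!r}")
            if pid not in seen_patients:
                raise ValueError(f"dangling patient reference {pid!r}")
            admit = _parse_date(row["admit_date"])
            discharge = _parse_date(row["discharge_date"])
            if admit > discharge:
                raise ValueError("admit_date after discharge_date")
            flags = {
                name: _parse_bool(row[name])
                for name in ("palliative", "known_bdz_abuse",
                             "respiratory_insufficiency", "severe_liver_disease")
            }
        except ValueError as exc:
            rejections.append(Rejection("hospitalizations", i, str(exc)))
            continue
        hosp_index[hid] = (pid, admit, discharge)
        hosp_rows.append(
            {"hosp_id": hid, "patient_id": pid, "admit_date": admit,
             "discharge_date": discharge, **flags}
        )
    hospitalizations = pd.DataFrame(
        hosp_rows, columns=TABLE_COLUMNS["hospitalizations"]
    )

    # --- administrations ---
    adm_rows = []
    for i, row in enumerate(
        _read_rows(Path(paths["administrations"]), "administrations"), start=1
    ):
        pid = (row["patient_id"] or "").strip()
        hid = (row["hosp_id"] or "").strip()
        try:
            if hid not in hosp_index:
                raise ValueError(f"dangling hospitalization reference {hid!r}")
            hosp_pid, admit, discharge = hosp_index[hid]
            if pid != hosp_pid:
                raise ValueError(
                    f"patient {pid!r} does not match hospitalization {hid!r}"
                )
            day = _parse_date(row["day"])
            if not (admit <= day <= discharge):
                raise ValueError("day outside hospitalization")
            atc = (row["atc_code"] or "").strip().upper()
            if not is_valid_atc(atc):
                raise ValueError(f"malformed ATC: {row['atc_code']!r}")
            dose = float(row["dose_mg"])
            if not dose >= 0:
                raise ValueError(f"negative dose_mg: {row['dose_mg']!r}")
            route = row["route"].strip().lower()
            if route not in ROUTES:
                raise ValueError(f"unknown route {row['route']!r}")
        except ValueError as exc:
            rejections.append(Rejection("administrations", i, str(exc)))
            continue
        adm_rows.append(
            {"patient_id": pid, "hosp_id": hid, "day": day, "atc_code": atc,
             "drug_name": row["drug_name"].strip(), "dose_mg": dose,
             "route": route}
        )
    administrations = pd.DataFrame(
        adm_rows, columns=TABLE_COLUMNS["administrations"]
    )

    # --- labs ---
    lab_rows = []
    for i, row in enumerate(_read_rows(Path(paths["labs"]), "labs"), start=1):
        pid = (row["patient_id"] or "").strip()
        try:
            if pid not in seen_patients:
                raise ValueError(f"dangling patient reference {pid!r}")
            ts = _parse_timestamp(row["timestamp"])
            analyte = row["analyte"].strip().lower()
            if analyte not in ANALYTES:
                raise ValueError(f"unknown analyte {row['analyte']!r}")
            value = float(row["value"])
            if not value > 0:
                raise ValueError(f"non-positive lab value: {row['value']!r}")
            units = row["units"].strip()
            if units not in LAB_UNITS:
                raise ValueError(f"unknown units {row['units']!r}")
        except ValueError as exc:
            rejections.append(Rejection("labs", i, str(exc)))
            continue
        lab_rows.append(
            {"patient_id": pid, "timestamp": ts, "analyte": analyte,
             "value": value, "units": units}
        )
    labs = pd.DataFrame(lab_rows, columns=TABLE_COLUMNS["labs"])

    rej = pd.DataFrame(
        [(r.table, r.row, r.reason) for r in rejections],
        columns=["table", "row", "reason"],
    )
    return Dataset(patients, hospitalizations, administrations, labs, rej)


def _fmt_value(col: str, v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, datetime):
        return v.isoformat(sep="T", timespec="minutes")
    if isinstance(v, date):
        return v.isoformat()
    if isinstance(v, float):
        return format(v, "g")
    return str(v)


def write_dataset(dataset: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write canonical normalized copies plus ``rejections.csv``.

    Canonical formatting: comma-delimited UTF-8, ISO dates, lowercase
    ``true``/``false`` booleans, shortest-round-trip numbers. Re-reading a
    canonical file and writing it again is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    tables = {
        "patients": dataset.patients,
        "hospitalizations": dataset.hospitalizations,
        "administrations": dataset.administrations,
        "labs": dataset.labs,
    }
    for table, df in tables.items():
        cols = TABLE_COLUMNS[table]
        path = out / f"{table}.csv"
        with path.open("w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(cols)
            for _, row in df.iterrows():
                w.writerow([_fmt_value(c, row[c]) for c in cols])
        written[table] = path
    rej_path = out / "rejections.csv"
    dataset.rejections.to_csv(rej_path, index=False, lineterminator="\n")
    written["rejections"] = rej_path
    return written


def expand_patient_days(dataset: Dataset) -> pd.DataFrame:
    """One row per (hospitalization, calendar day), bounds inclusive.

    Days with zero administrations are still emitted — they carry the
    denominator for prevalence over patient-days. ``age_years`` is the
    patient's completed age on that day.

    Returns a DataFrame with columns ``patient_id, hosp_id, day, age_years,
    sex, research_consent``.
    """
    birth = dict(
        zip(dataset.patients["patient_id"], dataset.patients["birth_date"])
    )
    sex = dict(zip(dataset.patients["patient_id"], dataset.patients["sex"]))
    consent = dict(
        zip(dataset.patients["patient_id"], dataset.patients["research_consent"])
    )
    rows = []
    for _, h in dataset.hospitalizations.iterrows():
        pid, hid = h["patient_id"], h["hosp_id"]
        d = h["admit_date"]
        while d <= h["discharge_date"]:
            rows.append(
                {"patient_id": pid, "hosp_id": hid, "day": d,
                 "age_years": age_at(birth[pid], d), "sex": sex[pid],
                 "research_consent": consent[pid]}
            )
            d += timedelta(days=1)
    return pd.DataFrame(
        rows,
        columns=["patient_id", "hosp_id", "day", "age_years", "sex",
                 "research_consent"],
    )


def daily_doses(administrations: pd.DataFrame) -> pd.DataFrame:
    """Sum dose_mg per (hosp_id, day, atc_code): the daily dose per drug."""
    if administrations.empty:
        return pd.DataFrame(
            columns=["patient_id", "hosp_id", "day", "atc_code", "dose_mg"]
        )
    return (
        administrations.groupby(
            ["patient_id", "hosp_id", "day", "atc_code"], as_index=False
        )["dose_mg"].sum()
    )
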