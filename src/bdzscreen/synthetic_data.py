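"""Seeded synthetic hospital dataset generator with spike-in ground truth.

The generator emulates the statistical structure of a two-year tertiary-care
inpatient population: about 23% of patient-days carry a BDZ administration,
roughly half of patients see at least one BDZ, stay lengths are lognormal
(mean 10 d, median 5 d, truncated at 1–397), the BDZ mix and age/sex
structure follow the published population characteristics, opioids
accompany about 27% of BDZ days, and strong CYP inhibitors and severe renal
impairment occur sporadically.

Two deliberate unrealisms make the generator a usable test oracle:

* The background is constructed to contain *no* qualifying rule violations
  — inhibitors are never placed within the carryover window of a
  CYP-metabolized BDZ, severely renally impaired patients receive no
  background lorazepam, elderly background zolpidem doses are always
  reduced, and flumazenil never appears in the background.
* Violations exist only as explicit spike-ins whose location, mechanism and
  intended triage classification are recorded in :class:`SpikeInTruth`, so
  recovery by the screening pipeline must be exact (precision = recall = 1).

After generation the production screener is run and any mismatch with the
planted truth raises, so an emitted dataset is guaranteed consistent.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .ehr_model import Dataset, age_at, write_dataset
from .me_screening import screen_all
from .reference_catalog import Catalog, load_catalog
from .renal_function import (
    UMOL_PER_L_TO_MG_PER_DL,
    egfr_ckdepi,
)


class GenerationError(RuntimeError):
    """Infeasible configuration or a spike-in/screen mismatch."""


class SimConfig(BaseModel):
    """Parameters of the synthetic population.

    Defaults reproduce the published population marginals: BDZ on 23.2% of
    patient-days, the per-drug mix over BDZ patient-days, 7.1% multi-BDZ
    days, opioids on 27.2% of BDZ days, lognormal stays with mean 10 and
    median 5 days truncated to 1–397.
    """

    n_patients: int = Field(default=150, ge=1)
    study_start: date = date(2011, 1, 1)
    study_end: date = date(2012, 12, 31)
    stay_mean_days: float = Field(default=10.0, gt=0)
    stay_median_days: float = Field(default=5.0, gt=0)
    stay_max_days: int = 397
    age_band_weights: dict[str, float] = {
        "<18": 0.026, "18-44": 0.308, "45-64": 0.334,
        "65-85": 0.297, ">85": 0.034,
    }
    sex_ratio_male: float = Field(default=0.5, ge=0, le=1)
    p_bdz_day: float = Field(default=0.232, ge=0, le=1)
    drug_mix: dict[str, float] = {
        "lorazepam": 0.361, "zolpidem": 0.303, "midazolam": 0.177,
        "oxazepam": 0.099, "diazepam": 0.015, "alprazolam": 0.014,
        "triazolam": 0.005,
    }
    p_multi_bdz_day: float = Field(default=0.071, ge=0, le=1)
    p_opioid_on_bdz_day: float = Field(default=0.272, ge=0, le=1)
    p_second_opioid: float = Field(default=0.15, ge=0, le=1)
    p_muscle_relaxant_on_bdz_day: float = Field(default=0.016, ge=0, le=1)
    p_strong_inhibitor_day: float = Field(default=0.01, ge=0, le=1)
    p_other_inhibitor_day: float = Field(default=0.01, ge=0, le=1)
    p_severe_renal_patient: float = Field(default=0.02, ge=0, le=1)
    p_palliative: float = Field(default=0.05, ge=0, le=1)
    p_abuse: float = Field(default=0.02, ge=0, le=1)
    p_respiratory: float = Field(default=0.08, ge=0, le=1)
    p_liver: float = Field(default=0.03, ge=0, le=1)
    p_no_consent: float = Field(default=0.02, ge=0, le=1)
    mean_filler_drugs: float = Field(default=5.0, ge=0)
    lab_cadence_days: int = Field(default=3, ge=1)
    n_spike_cyp: int = Field(default=3, ge=0)
    n_spike_renal: int = Field(default=3, ge=0)
    n_spike_flumazenil: int = Field(default=2, ge=0)
    n_spike_elderly: int = Field(default=2, ge=0)
    seed: int

    @model_validator(mode="after")
    def _feasible(self) -> "SimConfig":
        if self.p_multi_bdz_day > self.p_bdz_day:
            raise GenerationError(
                "infeasible config: p_multi_bdz_day "
                f"({self.p_multi_bdz_day}) exceeds p_bdz_day "
                f"({self.p_bdz_day}) — a multi-BDZ day is a BDZ day"
            )
        if self.stay_median_days > self.stay_mean_days:
            raise GenerationError(
                "infeasible config: lognormal stay needs median <= mean"
            )
        total = sum(self.drug_mix.values())
        if total > 1 + 1e-9:
            raise GenerationError(
                f"infeasible config: drug_mix sums to {total:.3f} > 1"
            )
        return self


@dataclass(frozen=True)
class PlantedViolation:
    hosp_id: str
    day: date
    mechanism: str
    bdz_atc: str
    intended_triage: Optional[str]  # None for the elderly-dose stream
    rule_path: str


@dataclass
class SpikeInTruth:
    """Ground truth of every violation planted into the dataset."""

    violations: list[PlantedViolation] = field(default_factory=list)

    def me_keys(self) -> set[tuple[str, date, str]]:
        return {
            (v.hosp_id, v.day, v.mechanism)
            for v in self.violations
            if v.mechanism != "elderly_zolpidem_dose"
        }

    def elderly_keys(self) -> set[tuple[str, date, str]]:
        return {
            (v.hosp_id, v.day, v.mechanism)
            for v in self.violations
            if v.mechanism == "elderly_zolpidem_dose"
        }

    def to_json(self, path: str | Path) -> Path:
        p = Path(path)
        p.write_text(
            json.dumps(
                [
                    {"hosp_id": v.hosp_id, "day": v.day.isoformat(),
                     "mechanism": v.mechanism, "bdz_atc": v.bdz_atc,
                     "intended_triage": v.intended_triage,
                     "rule_path": v.rule_path}
                    for v in self.violations
                ],
                indent=2,
            ) + "\n",
            encoding="utf-8",
        )
        return p


# drugs used by the generator beyond the screened BDZ
OXAZEPAM = ("oxazepam", "N05BA04")
OPIOIDS = [("morphine", "N02AA01", 10.0), ("oxycodone", "N02AA05", 10.0)]
MUSCLE_RELAXANT = ("tizanidine", "M03BX02", 4.0)
STRONG_3A4 = [("clarithromycin", "J01FA09", 500.0),
              ("itraconazole", "J02AC02", 200.0)]
OTHER_INHIBITORS = [("fluconazole", "J02AC01", 200.0),
                    ("ciprofloxacin", "J01MA02", 500.0)]
FILLERS = [
    ("pantoprazole", "A02BC02", 40.0), ("paracetamol", "N02BE01", 1000.0),
    ("metoprolol", "C07AB02", 50.0), ("amlodipine", "C08CA01", 5.0),
    ("atorvastatin", "C10AA05", 40.0), ("aspirin", "B01AC06", 100.0),
    ("enoxaparin", "B01AB05", 40.0), ("furosemide", "C03CA01", 40.0),
]
AGE_BANDS = {"<18": (2, 17), "18-44": (18, 44), "45-64": (45, 64),
             "65-85": (65, 85), ">85": (86, 99)}
DOSE_MULTIPLIERS = [0.25, 0.5, 1.0, 2.0]
DOSE_WEIGHTS = [0.15, 0.25, 0.45, 0.15]


def scr_for_egfr(target: float, age: float, sex: str) -> float:
    """Serum creatinine (mg/dL) whose CKD-EPI eGFR equals ``target``.

    Bisection on the strictly decreasing equation; used to plant renal
    impairment of a chosen severity.
    """
    lo, hi = 0.1, 25.0
    for _ in range(80):
        mid = (lo + hi) / 2
        if egfr_ckdepi(mid, age, sex) > target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _stay_length(rng: np.random.Generator, cfg: SimConfig) -> int:
    mu = math.log(cfg.stay_median_days)
    sigma = math.sqrt(2 * math.log(cfg.stay_mean_days / cfg.stay_median_days))
    n = int(round(rng.lognormal(mu, sigma)))
    return max(1, min(cfg.stay_max_days, n))


class _Builder:
    """Accumulates table rows and hands out sequential identifiers."""

    def __init__(self) -> None:
        self.patients: list[dict] = []
        self.hospitalizations: list[dict] = []
        self.administrations: list[dict] = []
        self.labs: list[dict] = []
        self._pid = 0
        self._hid = 0

    def new_patient(self, birth: date, sex: str, consent: bool = True) -> str:
        self._pid += 1
        pid = f"P{self._pid:05d}"
        self.patients.append(
            {"patient_id": pid, "birth_date": birth, "sex": sex,
             "research_consent": consent}
        )
        return pid

    def new_hosp(self, pid: str, admit: date, discharge: date,
                 palliative=False, abuse=False, respiratory=False,
                 liver=False) -> str:
        self._hid += 1
        hid = f"H{self._hid:05d}"
        self.hospitalizations.append(
            {"hosp_id": hid, "patient_id": pid, "admit_date": admit,
             "discharge_date": discharge, "palliative": palliative,
             "known_bdz_abuse": abuse, "respiratory_insufficiency": respiratory,
             "severe_liver_disease": liver}
        )
        return hid

    def give(self, pid: str, hid: str, day: date, name: str, atc: str,
             dose: float, route: str = "oral") -> None:
        self.administrations.append(
            {"patient_id": pid, "hosp_id": hid, "day": day, "atc_code": atc,
             "drug_name": name, "dose_mg": dose, "route": route}
        )

    def lab(self, pid: str, ts: datetime, value_umol: float) -> None:
        self.labs.append(
            {"patient_id": pid, "timestamp": ts, "analyte": "creatinine",
             "value": round(value_umol, 1), "units": "umol_per_L"}
        )

    def dataset(self) -> Dataset:
        from .ehr_model import TABLE_COLUMNS
        return Dataset(
            patients=pd.DataFrame(self.patients,
                                  columns=TABLE_COLUMNS["patients"]),
            hospitalizations=pd.DataFrame(
                self.hospitalizations,
                columns=TABLE_COLUMNS["hospitalizations"]),
            administrations=pd.DataFrame(
                self.administrations,
                columns=TABLE_COLUMNS["administrations"]),
            labs=pd.DataFrame(self.labs, columns=TABLE_COLUMNS["labs"]),
        )


def _birth_for_age(rng: np.random.Generator, age: int, ref: date) -> date:
    # birthday placed >6 months before the window so age is stable in-window
    day_offset = int(rng.integers(200, 360))
    return ref - timedelta(days=age * 365 + day_offset)


def _draw_bdz(
    rng: np.random.Generator,
    cfg: SimConfig,
    catalog: Catalog,
    age: int,
    severe_renal: bool,
    exclude: set[str] = frozenset(),
) -> tuple[str, str, float, str]:
    """One background BDZ (name, atc, daily dose, route), violation-free."""
    names = list(cfg.drug_mix)
    weights = np.array([cfg.drug_mix[n] for n in names], dtype=float)
    for i, n in enumerate(names):
        if n in exclude or (severe_renal and n == "lorazepam"):
            weights[i] = 0.0
    weights = weights / weights.sum()
    name = names[int(rng.choice(len(names), p=weights))]
    if name == "oxazepam":
        atc, std = OXAZEPAM[1], 30.0
    else:
        profile = catalog.bdz_profile_by_name(name)
        atc, std = profile.atc_code, profile.standard_daily_dose_mg
    mult = DOSE_MULTIPLIERS[int(rng.choice(4, p=DOSE_WEIGHTS))]
    if name == "zolpidem" and age >= 65:
        mult = float(rng.choice([0.25, 0.5]))  # background elderly stay reduced
    dose = std * mult
    route = "intravenous" if (name == "midazolam" and rng.random() < 0.5) \
        else "oral"
    return name, atc, dose, route


def _cyp_bdz_atcs(catalog: Catalog) -> set[str]:
    return {p.atc_code for p in catalog.bdz if p.trigger_rules()}


def generate(
    config: SimConfig, catalog: Optional[Catalog] = None
) -> tuple[Dataset, SpikeInTruth]:
    """Generate a violation-free background population plus spike-ins.

    Reproducible: the same config (including seed) yields an identical
    dataset. Raises :class:`GenerationError` if the production screener
    does not recover exactly the planted truth.
    """
    catalog = catalog or load_catalog()
    rng = np.random.default_rng(config.seed)
    b = _Builder()
    cyp_atcs = _cyp_bdz_atcs(catalog)
    window_days = (config.study_end - config.study_start).days + 1

    for _ in range(config.n_patients):
        band = list(config.age_band_weights)
        w = np.array([config.age_band_weights[k] for k in band])
        lo, hi = AGE_BANDS[band[int(rng.choice(len(band), p=w / w.sum()))]]
        age = int(rng.integers(lo, hi + 1))
        sex = "male" if rng.random() < config.sex_ratio_male else "female"
        birth = _birth_for_age(rng, age, config.study_start)
        consent = rng.random() >= config.p_no_consent
        pid = b.new_patient(birth, sex, consent)
        severe_renal = age >= 18 and rng.random() < config.p_severe_renal_patient
        if severe_renal:
            egfr_target = float(rng.uniform(10, 29))
        else:
            egfr_target = float(rng.uniform(60, 120))
        if age >= 18:
            baseline_scr = scr_for_egfr(egfr_target, age, sex)
        else:
            baseline_scr = 0.5

        n_hosp = 1 + int(rng.poisson(0.55))
        used: list[tuple[date, date]] = []
        for _ in range(n_hosp):
            stay = _stay_length(rng, config)
            last_start = window_days - stay
            if last_start < 0:
                stay, last_start = window_days, 0
            admit = config.study_start + timedelta(
                days=int(rng.integers(0, last_start + 1))
            )
            discharge = admit + timedelta(days=stay - 1)
            if any(a <= discharge and admit <= d for a, d in used):
                continue  # overlapping stay: drop rather than bias placement
            used.append((admit, discharge))
            hid = b.new_hosp(
                pid, admit, discharge,
                palliative=rng.random() < config.p_palliative,
                abuse=rng.random() < config.p_abuse,
                respiratory=rng.random() < config.p_respiratory,
                liver=rng.random() < config.p_liver,
            )
            days = [admit + timedelta(days=i) for i in range(stay)]
            # labs on a fixed cadence
            if age >= 18:
                for i in range(0, stay, config.lab_cadence_days):
                    noise = float(rng.lognormal(0, 0.05))
                    b.lab(
                        pid,
                        datetime.combine(days[i], time(8, 0)),
                        baseline_scr * noise * UMOL_PER_L_TO_MG_PER_DL,
                    )
            # first pass: BDZ and co-medication per day
            cyp_bdz_days: set[date] = set()
            for d in days:
                if rng.random() >= config.p_bdz_day:
                    n_fill = int(rng.poisson(config.mean_filler_drugs * 0.6))
                    for fi in rng.choice(
                        len(FILLERS), size=min(n_fill, len(FILLERS)),
                        replace=False,
                    ):
                        fn, fa, fd = FILLERS[int(fi)]
                        b.give(pid, hid, d, fn, fa, fd)
                    continue
                age_today = age_at(birth, d)  # the rules see this age
                name, atc, dose, route = _draw_bdz(
                    rng, config, catalog, age_today, severe_renal
                )
                b.give(pid, hid, d, name, atc, dose, route)
                if atc in cyp_atcs:
                    cyp_bdz_days.add(d)
                if rng.random() < config.p_multi_bdz_day / config.p_bdz_day:
                    n2, a2, d2, r2 = _draw_bdz(
                        rng, config, catalog, age_today, severe_renal,
                        exclude={name},
                    )
                    b.give(pid, hid, d, n2, a2, d2, r2)
                    if a2 in cyp_atcs:
                        cyp_bdz_days.add(d)
                if rng.random() < config.p_opioid_on_bdz_day:
                    on, oa, od = OPIOIDS[0]
                    b.give(pid, hid, d, on, oa, od)
                    if rng.random() < config.p_second_opioid:
                        on, oa, od = OPIOIDS[1]
                        b.give(pid, hid, d, on, oa, od)
                if rng.random() < config.p_muscle_relaxant_on_bdz_day:
                    mn, ma, md = MUSCLE_RELAXANT
                    b.give(pid, hid, d, mn, ma, md)
                n_fill = int(rng.poisson(config.mean_filler_drugs))
                for fi in rng.choice(
                    len(FILLERS), size=min(n_fill, len(FILLERS)),
                    replace=False,
                ):
                    fn, fa, fd = FILLERS[int(fi)]
                    b.give(pid, hid, d, fn, fa, fd)
            # second pass: inhibitors only where no CYP-BDZ lies in the
            # forward carryover window (keeps the background violation-free)
            for d in days:
                if rng.random() < config.p_strong_inhibitor_day:
                    fwd = {d + timedelta(days=k) for k in range(0, 3)}
                    if not (fwd & cyp_bdz_days):
                        sn, sa, sd = STRONG_3A4[int(rng.integers(2))]
                        b.give(pid, hid, d, sn, sa, sd)
                if rng.random() < config.p_other_inhibitor_day:
                    on, oa, od = OTHER_INHIBITORS[int(rng.integers(2))]
                    b.give(pid, hid, d, on, oa, od)

    truth = SpikeInTruth()
    _plant_spikes(b, rng, config, catalog, truth)

    dataset = b.dataset()
    _verify_against_truth(dataset, catalog, truth)
    return dataset, truth


def _spike_window(rng: np.random.Generator, cfg: SimConfig,
                  stay: int) -> tuple[date, date]:
    last = (cfg.study_end - cfg.study_start).days + 1 - stay
    admit = cfg.study_start + timedelta(days=int(rng.integers(0, last + 1)))
    return admit, admit + timedelta(days=stay - 1)


def _plant_spikes(
    b: _Builder,
    rng: np.random.Generator,
    cfg: SimConfig,
    catalog: Catalog,
    truth: SpikeInTruth,
) -> None:
    """Append dedicated hospitalizations carrying exactly one violation each.

    The intended triage classification rotates across exclusion /
    aggravator / residual paths so the triage stage is exercised end to
    end.
    """
    zol = catalog.bdz_profile_by_name("zolpidem")
    lor = catalog.bdz_profile_by_name("lorazepam")
    mid = catalog.bdz_profile_by_name("midazolam")
    flum = catalog.drug_classes.flumazenil_atc

    for i in range(cfg.n_spike_cyp):
        age = 45
        sex = "female" if i % 2 else "male"
        pid = b.new_patient(_birth_for_age(rng, age, cfg.study_start), sex)
        admit, discharge = _spike_window(rng, cfg, 6)
        variant = i % 3  # 0: NEEDS_REVIEW, 1: VALIDATED, 2: NO_ME
        hid = b.new_hosp(pid, admit, discharge,
                         palliative=(variant == 2),
                         respiratory=(variant == 1))
        day = admit + timedelta(days=3)
        offset = int(rng.integers(0, 3))
        b.give(pid, hid, day, "zolpidem", zol.atc_code,
               zol.standard_daily_dose_mg)
        sn, sa, sd = STRONG_3A4[0]
        b.give(pid, hid, day - timedelta(days=offset), sn, sa, sd)
        intended = ["NEEDS_REVIEW", "VALIDATED_ME", "NO_ME"][variant]
        path = ["no exclusion, no aggravator",
                "aggravator respiratory_insufficiency",
                "exclusion palliative"][variant]
        truth.violations.append(PlantedViolation(
            hid, day, "cyp_ddi", zol.atc_code, intended,
            f"strong CYP3A4 inhibitor at offset -{offset}; {path}",
        ))

    for i in range(cfg.n_spike_renal):
        age = 50
        sex = "male" if i % 2 else "female"
        pid = b.new_patient(_birth_for_age(rng, age, cfg.study_start), sex)
        admit, discharge = _spike_window(rng, cfg, 7)
        variant = i % 3  # 0: consecutive-day arm, 1: multi-BDZ arm, 2: NO_ME
        hid = b.new_hosp(pid, admit, discharge, palliative=(variant == 2))
        day = admit + timedelta(days=3)
        scr = scr_for_egfr(float(rng.uniform(15, 25)), age, sex)
        b.lab(pid, datetime.combine(day - timedelta(days=1), time(8, 0)),
              scr * UMOL_PER_L_TO_MG_PER_DL)
        if variant == 1:
            b.give(pid, hid, day, "lorazepam", lor.atc_code,
                   lor.standard_daily_dose_mg)
            b.give(pid, hid, day, "midazolam", mid.atc_code,
                   mid.standard_daily_dose_mg)
            truth.violations.append(PlantedViolation(
                hid, day, "lorazepam_renal", lor.atc_code, "VALIDATED_ME",
                "eGFR<30 + other BDZ same day; aggravator multi_bdz",
            ))
        else:
            for d in (day, day + timedelta(days=1)):
                b.give(pid, hid, d, "lorazepam", lor.atc_code,
                       lor.standard_daily_dose_mg)
            intended = "NO_ME" if variant == 2 else "NEEDS_REVIEW"
            path = ("exclusion palliative" if variant == 2
                    else "no exclusion, no aggravator")
            for d in (day, day + timedelta(days=1)):
                truth.violations.append(PlantedViolation(
                    hid, d, "lorazepam_renal", lor.atc_code, intended,
                    f"eGFR<30 + consecutive lorazepam days; {path}",
                ))

    for i in range(cfg.n_spike_flumazenil):
        age = 40
        pid = b.new_patient(_birth_for_age(rng, age, cfg.study_start), "male")
        admit, discharge = _spike_window(rng, cfg, 5)
        hid = b.new_hosp(pid, admit, discharge)
        day = admit + timedelta(days=2)
        b.give(pid, hid, day, "midazolam", mid.atc_code,
               mid.standard_daily_dose_mg, route="intravenous")
        b.give(pid, hid, day, "flumazenil", flum, 0.5, route="intravenous")
        truth.violations.append(PlantedViolation(
            hid, day, "flumazenil_surrogate", flum, "NEEDS_REVIEW",
            "flumazenil given after midazolam; no exclusion, no aggravator",
        ))

    for i in range(cfg.n_spike_elderly):
        age = 75
        pid = b.new_patient(_birth_for_age(rng, age, cfg.study_start),
                            "female" if i % 2 else "male")
        admit, discharge = _spike_window(rng, cfg, 4)
        hid = b.new_hosp(pid, admit, discharge)
        day = admit + timedelta(days=1)
        b.give(pid, hid, day, "zolpidem", zol.atc_code,
               zol.standard_daily_dose_mg)
        truth.violations.append(PlantedViolation(
            hid, day, "elderly_zolpidem_dose", zol.atc_code, None,
            "age >= 65 with zolpidem >= 10 mg/day (separate stream)",
        ))


def _verify_against_truth(
    dataset: Dataset, catalog: Catalog, truth: SpikeInTruth
) -> None:
    result = screen_all(dataset, catalog)
    found_me = {(f.hosp_id, f.day, f.mechanism) for f in result.flags}
    found_eld = {(f.hosp_id, f.day, f.mechanism)
                 for f in result.elderly_flags}
    if found_me != truth.me_keys() or found_eld != truth.elderly_keys():
        extra = (found_me | found_eld) - (truth.me_keys() | truth.elderly_keys())
        missing = (truth.me_keys() | truth.elderly_keys()) - (found_me | found_eld)
        raise GenerationError(
            f"spike-in mismatch: {len(extra)} accidental background flags "
            f"{sorted(extra)[:5]}, {len(missing)} unrecovered plants "
            f"{sorted(missing)[:5]}"
        )


def write_generated(
    dataset: Dataset, truth: SpikeInTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Write the four dataset files plus ``truth.json``."""
    out = Path(out_dir)
    written = write_dataset(dataset, out)
    written["truth"] = truth.to_json(out / "truth.json")
    return written


def make_case_vignette_fixture(
    catalog: Optional[Catalog] = None,
) -> tuple[Dataset, dict]:
    """Deterministic hand-built fixture echoing documented case vignettes.

    Contains, among ~20 hospitalizations: a lorazepam course in severe
    renal impairment (eGFR 18 mL/min); an intentional 510 mg/day zolpidem
    course in a patient with known severe BDZ addiction (flags fire, triage
    excludes); a day combining 2 BDZ, 2 strong CYP3A4 inhibitors, 2 opioids
    and a muscle relaxant; a flumazenil rescue; a half-dose interaction day
    (low-dose exclusion); and clean stays. Returns the dataset and a dict
    of the vignette hospitalization ids.
    """
    catalog = catalog or load_catalog()
    b = _Builder()
    zol = catalog.bdz_profile_by_name("zolpidem")
    lor = catalog.bdz_profile_by_name("lorazepam")
    mid = catalog.bdz_profile_by_name("midazolam")
    dia = catalog.bdz_profile_by_name("diazepam")
    flum = catalog.drug_classes.flumazenil_atc
    ids: dict[str, str] = {}

    def patient(age: int, sex: str, consent: bool = True) -> str:
        return b.new_patient(
            date(2010, 6, 15) - timedelta(days=age * 365 + 300), sex, consent
        )

    # 1) lorazepam in severe renal impairment, eGFR 18, consecutive days
    pid = patient(78, "female")
    hid = b.new_hosp(pid, date(2011, 3, 1), date(2011, 3, 10))
    scr = scr_for_egfr(18.0, 78, "female")
    b.lab(pid, datetime(2011, 3, 3, 8, 0), scr * UMOL_PER_L_TO_MG_PER_DL)
    b.lab(pid, datetime(2011, 3, 6, 8, 0), scr * UMOL_PER_L_TO_MG_PER_DL)
    for d in (date(2011, 3, 4), date(2011, 3, 5)):
        b.give(pid, hid, d, "lorazepam", lor.atc_code, 2.0)
    ids["renal_egfr18"] = hid

    # 2) 510 mg/day zolpidem, known BDZ abuse -> triage NO_ME
    pid = patient(42, "male")
    hid = b.new_hosp(pid, date(2011, 5, 1), date(2011, 5, 14), abuse=True)
    for i in range(5):
        d = date(2011, 5, 3) + timedelta(days=i)
        b.give(pid, hid, d, "zolpidem", zol.atc_code, 510.0)
    b.give(pid, hid, date(2011, 5, 4), "clarithromycin", "J01FA09", 500.0)
    ids["abuse_zolpidem_510"] = hid

    # 3) 2 BDZ + 2 strong CYP3A4 inhibitors + 2 opioids + muscle relaxant
    pid = patient(60, "male")
    hid = b.new_hosp(pid, date(2012, 2, 10), date(2012, 2, 20))
    d = date(2012, 2, 14)
    b.give(pid, hid, d, "zolpidem", zol.atc_code, 10.0)
    b.give(pid, hid, d, "diazepam", dia.atc_code, 10.0)
    b.give(pid, hid, d, "clarithromycin", "J01FA09", 500.0)
    b.give(pid, hid, d, "itraconazole", "J02AC02", 200.0)
    b.give(pid, hid, d, "morphine", "N02AA01", 10.0)
    b.give(pid, hid, d, "oxycodone", "N02AA05", 10.0)
    b.give(pid, hid, d, "tizanidine", "M03BX02", 4.0)
    ids["polypharmacy_day"] = hid

    # 4) flumazenil rescue after midazolam
    pid = patient(55, "female")
    hid = b.new_hosp(pid, date(2012, 6, 1), date(2012, 6, 6))
    b.give(pid, hid, date(2012, 6, 3), "midazolam", mid.atc_code, 7.5,
           route="intravenous")
    b.give(pid, hid, date(2012, 6, 4), "flumazenil", flum, 0.5,
           route="intravenous")
    ids["flumazenil_rescue"] = hid

    # 5) interaction at half-standard dose -> low-dose exclusion
    pid = patient(50, "male")
    hid = b.new_hosp(pid, date(2011, 9, 1), date(2011, 9, 8))
    d = date(2011, 9, 4)
    b.give(pid, hid, d, "zolpidem", zol.atc_code,
           zol.standard_daily_dose_mg / 2)
    b.give(pid, hid, d, "clarithromycin", "J01FA09", 500.0)
    ids["low_dose_interaction"] = hid

    # 6) elderly unreduced zolpidem (prescribing-quality stream)
    pid = patient(82, "female")
    hid = b.new_hosp(pid, date(2011, 11, 1), date(2011, 11, 5))
    b.give(pid, hid, date(2011, 11, 2), "zolpidem", zol.atc_code, 5.0)
    b.give(pid, hid, date(2011, 11, 2), "zolpidem", zol.atc_code, 5.0)
    ids["elderly_zolpidem_split_dose"] = hid

    # 7) palliative interaction -> NO_ME
    pid = patient(68, "male")
    hid = b.new_hosp(pid, date(2012, 9, 10), date(2012, 9, 20),
                     palliative=True)
    d = date(2012, 9, 12)
    b.give(pid, hid, d, "midazolam", mid.atc_code, 7.5)
    b.give(pid, hid, d, "clarithromycin", "J01FA09", 500.0)
    ids["palliative_interaction"] = hid

    # 8) consent withheld: interaction present, excluded from triage
    pid = patient(45, "female", consent=False)
    hid = b.new_hosp(pid, date(2012, 4, 1), date(2012, 4, 7))
    d = date(2012, 4, 3)
    b.give(pid, hid, d, "zolpidem", zol.atc_code, 10.0)
    b.give(pid, hid, d, "itraconazole", "J02AC02", 200.0)
    ids["no_consent_interaction"] = hid

    # 9) carryover boundary pair: inhibitor 2 days before (flags) vs 3 (not)
    pid = patient(52, "male")
    hid = b.new_hosp(pid, date(2011, 7, 1), date(2011, 7, 10))
    b.give(pid, hid, date(2011, 7, 2), "clarithromycin", "J01FA09", 500.0)
    b.give(pid, hid, date(2011, 7, 4), "zolpidem", zol.atc_code, 10.0)
    ids["carryover_minus2"] = hid
    pid = patient(52, "female")
    hid = b.new_hosp(pid, date(2011, 7, 1), date(2011, 7, 10))
    b.give(pid, hid, date(2011, 7, 2), "clarithromycin", "J01FA09", 500.0)
    b.give(pid, hid, date(2011, 7, 5), "zolpidem", zol.atc_code, 10.0)
    ids["carryover_minus3"] = hid

    # 10) lorazepam + strong inhibitor: glucuronidation-only, never cyp_ddi
    pid = patient(47, "male")
    hid = b.new_hosp(pid, date(2012, 1, 5), date(2012, 1, 12))
    d = date(2012, 1, 7)
    b.give(pid, hid, d, "lorazepam", lor.atc_code, 2.0)
    b.give(pid, hid, d, "clarithromycin", "J01FA09", 500.0)
    ids["lorazepam_glucuronidation"] = hid

    # clean stays (denominator padding, no drugs at all)
    for i in range(10):
        pid = patient(30 + i, "male" if i % 2 else "female")
        start = date(2011, 1, 10) + timedelta(days=20 * i)
        b.new_hosp(pid, start, start + timedelta(days=3))

    return b.dataset(), ids
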