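"""Reference data: screened BDZ profiles, CYP inhibitor lists, drug classes.

The catalog is pure data behind the screening rules. A default is shipped
with the package; any part can be overridden or extended from a user YAML
file, so that the detection algorithm — not one particular inhibitor list —
is the contract. Strong CYP3A4 inhibitors carry a 2-day carryover window
(they keep suppressing metabolism after cessation); moderate entries are
annotation-only and never trigger a potential medication error on their own,
with one data-driven exception: a profile may declare an ``extra_trigger``
(prazepam flags on strong *or* moderate CYP2C19 inhibition).
"""

from __future__ import annotations

import csv
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .atc import AtcError, atc_matches, normalize_atc

Pathway = Literal["CYP3A4", "CYP2C19", "CYP1A2", "glucuronidation_only"]
Strength = Literal["strong", "moderate"]

#: the 11 drugs the screen covers; the default catalog must profile each
SCREENED_DRUGS = (
    "zolpidem", "midazolam", "diazepam", "alprazolam", "triazolam",
    "zopiclone", "flunitrazepam", "clorazepate", "nitrazepam", "prazepam",
    "lorazepam",
)


class CatalogError(ValueError):
    """Fatal catalog problem: duplicate conflicting entries, broken invariant."""


class TriggerRule(BaseModel):
    """Inhibitor (pathway, strength) pairs that flag a given BDZ."""

    pathway: Pathway
    strengths: list[Strength]


class BdzProfile(BaseModel):
    drug_name: str
    atc_code: str
    pathways: set[Pathway]
    standard_daily_dose_mg: float = Field(gt=0)
    elderly_daily_dose_mg: Optional[float] = Field(default=None, gt=0)
    renal_contraindicated_below_egfr: Optional[float] = None
    extra_trigger: Optional[TriggerRule] = None

    @field_validator("atc_code")
    @classmethod
    def _atc(cls, v: str) -> str:
        return normalize_atc(v)

    @property
    def cyp_metabolized(self) -> bool:
        return bool(self.pathways - {"glucuronidation_only"})

    def trigger_rules(self) -> list[TriggerRule]:
        """Inhibitor classes whose co-administration flags this BDZ.

        Any CYP3A4-metabolized BDZ is flagged by strong CYP3A4 inhibitors;
        a glucuronidation-only drug has no CYP trigger at all.
        """
        rules: list[TriggerRule] = []
        if "CYP3A4" in self.pathways:
            rules.append(TriggerRule(pathway="CYP3A4", strengths=["strong"]))
        if self.extra_trigger is not None:
            rules.append(self.extra_trigger)
        return rules


class InhibitorEntry(BaseModel):
    drug_name: str
    atc_code: str
    pathway: Literal["CYP3A4", "CYP2C19", "CYP1A2"]
    strength: Strength
    carryover_days: int = Field(ge=0)

    @field_validator("atc_code")
    @classmethod
    def _atc(cls, v: str) -> str:
        return normalize_atc(v)

    @model_validator(mode="after")
    def _strong_3a4_carryover(self) -> "InhibitorEntry":
        if self.pathway == "CYP3A4" and self.strength == "strong" \
                and self.carryover_days != 2:
            raise ValueError(
                f"{self.drug_name}: strong CYP3A4 entries must have "
                f"carryover_days=2, got {self.carryover_days}"
            )
        return self


class DrugClassMap(BaseModel):
    opioid_atc_prefixes: list[str] = ["N02A"]
    muscle_relaxant_atc_prefixes: list[str] = ["M03"]
    flumazenil_atc: str = "V03AB25"
    bdz_atc_prefixes: list[str] = ["N05BA", "N05CD", "N05CF"]

    @field_validator(
        "opioid_atc_prefixes", "muscle_relaxant_atc_prefixes", "bdz_atc_prefixes"
    )
    @classmethod
    def _prefixes(cls, v: list[str]) -> list[str]:
        return [normalize_atc(p) for p in v]

    @field_validator("flumazenil_atc")
    @classmethod
    def _flum(cls, v: str) -> str:
        return normalize_atc(v)


class Catalog(BaseModel):
    """Validated reference catalog with lookup helpers."""

    bdz: list[BdzProfile]
    inhibitors: list[InhibitorEntry]
    drug_classes: DrugClassMap = DrugClassMap()

    @model_validator(mode="after")
    def _invariants(self) -> "Catalog":
        by_name: dict[str, BdzProfile] = {}
        by_atc: dict[str, BdzProfile] = {}
        for p in self.bdz:
            if p.drug_name in by_name or p.atc_code in by_atc:
                raise CatalogError(f"duplicate BDZ profile: {p.drug_name}")
            by_name[p.drug_name] = p
            by_atc[p.atc_code] = p
        for name in SCREENED_DRUGS:
            if name not in by_name:
                raise CatalogError(f"catalog is missing screened drug {name!r}")
        lor = by_name["lorazepam"]
        if lor.renal_contraindicated_below_egfr is None:
            raise CatalogError("lorazepam profile must set a renal eGFR threshold")
        seen: dict[tuple[str, str], InhibitorEntry] = {}
        for e in self.inhibitors:
            key = (e.atc_code, e.pathway)
            if key in seen and seen[key] != e:
                raise CatalogError(
                    f"conflicting inhibitor entries for {key}: "
                    f"{seen[key]!r} vs {e!r}"
                )
            seen[key] = e
        return self

    # -- lookups -------------------------------------------------------

    def bdz_profile(self, atc_code: str) -> Optional[BdzProfile]:
        code = normalize_atc(atc_code)
        for p in self.bdz:
            if p.atc_code == code:
                return p
        return None

    def bdz_profile_by_name(self, name: str) -> BdzProfile:
        for p in self.bdz:
            if p.drug_name == name:
                return p
        raise KeyError(name)

    def inhibitor_entries(self, atc_code: str) -> list[InhibitorEntry]:
        code = normalize_atc(atc_code)
        return [e for e in self.inhibitors if e.atc_code == code]

    def is_bdz(self, atc_code: str) -> bool:
        return any(
            atc_matches(atc_code, pre)
            for pre in self.drug_classes.bdz_atc_prefixes
        )


def classify_drug(atc_code: str, catalog: Catalog) -> set[str]:
    """Roles a drug plays in the screen, from its ATC code.

    Returns a subset of {bdz, strong_3a4_inhibitor, inhibitor_2c19,
    inhibitor_1a2, opioid, muscle_relaxant, flumazenil, other}; a drug may
    hold several roles, and a code in no list is {other}. Malformed ATC
    raises, never returns a silent empty set.
    """
    code = normalize_atc(atc_code)
    roles: set[str] = set()
    dc = catalog.drug_classes
    if catalog.is_bdz(code):
        roles.add("bdz")
    for entry in catalog.inhibitor_entries(code):
        if entry.pathway == "CYP3A4" and entry.strength == "strong":
            roles.add("strong_3a4_inhibitor")
        elif entry.pathway == "CYP2C19":
            roles.add("inhibitor_2c19")
        elif entry.pathway == "CYP1A2":
            roles.add("inhibitor_1a2")
    if any(atc_matches(code, p) for p in dc.opioid_atc_prefixes):
        roles.add("opioid")
    if any(atc_matches(code, p) for p in dc.muscle_relaxant_atc_prefixes):
        roles.add("muscle_relaxant")
    if code == dc.flumazenil_atc:
        roles.add("flumazenil")
    return roles or {"other"}


def _default_raw() -> dict:
    text = (
        resources.files("bdzscreen").joinpath("data/default_catalog.yaml")
        .read_text(encoding="utf-8")
    )
    return yaml.safe_load(text)


def load_catalog(path: str | Path | None = None) -> Catalog:
    """Load the shipped default catalog, optionally merged with a user file.

    User BDZ profiles replace same-ATC defaults; user inhibitor entries are
    unioned with the defaults, replacing any default row for the same
    (ATC, pathway) pair. ``drug_classes`` keys in the user file override the
    defaults wholesale. A user file with two conflicting rows for the same
    key is fatal.
    """
    raw = _default_raw()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if "bdz" in user:
            merged = {normalize_atc(p["atc_code"]): p for p in raw["bdz"]}
            for p in user["bdz"]:
                merged[normalize_atc(p["atc_code"])] = p
            raw["bdz"] = list(merged.values())
        if "inhibitors" in user:
            merged_i = {
                (normalize_atc(e["atc_code"]), e["pathway"]): e
                for e in raw["inhibitors"]
            }
            for e in user["inhibitors"]:
                key = (normalize_atc(e["atc_code"]), e["pathway"])
                merged_i[key] = e
            raw["inhibitors"] = list(merged_i.values())
        if "drug_classes" in user:
            raw["drug_classes"] = {**raw["drug_classes"], **user["drug_classes"]}
    try:
        return Catalog.model_validate(raw)
    except (ValueError, AtcError) as exc:
        raise CatalogError(str(exc)) from exc


def export_catalog_csv(catalog: Catalog, out_dir: str | Path) -> list[Path]:
    """Audit export: the catalog as two flat CSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bdz_path = out / "catalog_bdz.csv"
    with bdz_path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(
            ["drug_name", "atc_code", "pathways", "standard_daily_dose_mg",
             "elderly_daily_dose_mg", "renal_contraindicated_below_egfr"]
        )
        for p in catalog.bdz:
            w.writerow(
                [p.drug_name, p.atc_code, "|".join(sorted(p.pathways)),
                 p.standard_daily_dose_mg, p.elderly_daily_dose_mg or "",
                 p.renal_contraindicated_below_egfr or ""]
            )
    inh_path = out / "catalog_inhibitors.csv"
    with inh_path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(
            ["drug_name", "atc_code", "pathway", "strength", "carryover_days"]
        )
        for e in catalog.inhibitors:
            w.writerow(
                [e.drug_name, e.atc_code, e.pathway, e.strength,
                 e.carryover_days]
            )
    return [bdz_path, inh_path]
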