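"""Organ-system knowledge dimensions, practice profiles, and frequency-of-use labels.

The exam blueprint divides medical knowledge into 14 organ-system dimensions
(cardiovascular through reproductive).  Each examinee reports one of 64
practice profiles (medical specialties).  For every (specialty, system) pair a
frequency-of-use label describes how often a practitioner in that specialty
exercises that system knowledge:

* ``reference`` — the specialty is general practice (multi-specialization);
  every system is used comparably often and serves as the comparison group.
* ``dominant`` — the single most-used system for the specialty.
* ``relevant`` — often used but not core; at most two per specialty.
* ``distant`` — everything else; rarely used in daily practice.

The registries packaged here are illustrative: only the neurological-surgery
profile (dominant neurologic; relevant cardiovascular and endocrine) and the
general-practice rule are fixed by the study design the package implements.
"""

from __future__ import annotations

import csv
import enum
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping


class BlueprintError(ValueError):
    """Raised for invalid registries, label files, or lookups."""


class FrequencyLabel(enum.IntEnum):
    """Frequency-of-use category of a system for a specialty."""

    REFERENCE = 0
    DOMINANT = 1
    RELEVANT = 2
    DISTANT = 3

    @classmethod
    def parse(cls, text: str) -> "FrequencyLabel":
        key = str(text).strip().lower()
        try:
            return cls[key.upper()]
        except KeyError:
            raise BlueprintError(f"unknown frequency label {text!r}") from None


@dataclass(frozen=True)
class SystemDomain:
    """One organ-system knowledge dimension of the exam blueprint."""

    id: str
    name: str


@dataclass(frozen=True)
class Specialty:
    """A practice profile (medical specialty) an examinee can report."""

    id: str
    name: str
    is_multi_specialization: bool = False


def _registry(items: Iterable) -> dict:
    out: dict = {}
    for item in items:
        key = item.id.strip().lower()
        if key != item.id:
            item = type(item)(**{**item.__dict__, "id": key})
        if key in out:
            raise BlueprintError(f"duplicate registry id {key!r}")
        out[key] = item
    return out


_SYSTEM_ROWS = [
    ("cardiovascular", "Cardiovascular"),
    ("dermatologic", "Dermatologic"),
    ("endocrine", "Endocrine"),
    ("eent", "Eyes/Ears/Nose/Throat"),
    ("gastrointestinal_nutrition", "Gastrointestinal/Nutrition"),
    ("genitourinary", "Genitourinary"),
    ("hematologic", "Hematologic"),
    ("infectious_diseases", "Infectious Diseases"),
    ("musculoskeletal", "Musculoskeletal"),
    ("neurologic", "Neurologic"),
    ("psychiatry_behavioral", "Psychiatry/Behavioral Science"),
    ("pulmonary", "Pulmonary"),
    ("renal", "Renal"),
    ("reproductive", "Reproductive"),
]

# Multi-specialization (general practice) profiles: all systems -> reference.
_MULTI_SPECIALTIES = [
    ("family_medicine", "Family Medicine"),
    ("internal_medicine", "Internal Medicine"),
    ("emergency_medicine", "Emergency Medicine"),
    ("urgent_care", "Urgent Care"),
    ("hospital_medicine", "Hospital Medicine"),
]

# Single-specialization profiles: (id, name, dominant system, relevant systems).
# Only neurological_surgery is fixed by the study design; the rest are
# illustrative but clinically plausible assignments.
_SINGLE_SPECIALTIES = [
    ("addiction_medicine", "Addiction Medicine", "psychiatry_behavioral", ["neurologic"]),
    ("allergy_immunology", "Allergy & Immunology", "pulmonary", ["dermatologic", "eent"]),
    ("anesthesiology", "Anesthesiology", "cardiovascular", ["pulmonary", "neurologic"]),
    ("bariatric_surgery", "Bariatric Surgery", "gastrointestinal_nutrition", ["endocrine", "cardiovascular"]),
    ("cardiology", "Cardiology", "cardiovascular", ["pulmonary", "endocrine"]),
    ("cardiothoracic_surgery", "Cardiothoracic Surgery", "cardiovascular", ["pulmonary"]),
    ("child_adolescent_psychiatry", "Child & Adolescent Psychiatry", "psychiatry_behavioral", ["neurologic"]),
    ("colorectal_surgery", "Colorectal Surgery", "gastrointestinal_nutrition", ["infectious_diseases"]),
    ("critical_care_medicine", "Critical Care Medicine", "pulmonary", ["cardiovascular", "infectious_diseases"]),
    ("dermatology", "Dermatology", "dermatologic", ["infectious_diseases"]),
    ("diabetes_management", "Diabetes Management", "endocrine", ["cardiovascular", "renal"]),
    ("electrophysiology", "Cardiac Electrophysiology", "cardiovascular", []),
    ("endocrinology", "Endocrinology", "endocrine", ["cardiovascular", "renal"]),
    ("gastroenterology", "Gastroenterology", "gastrointestinal_nutrition", ["hematologic"]),
    ("general_surgery", "General Surgery", "gastrointestinal_nutrition", ["cardiovascular", "hematologic"]),
    ("geriatrics", "Geriatric Medicine", "neurologic", ["cardiovascular", "psychiatry_behavioral"]),
    ("gynecologic_oncology", "Gynecologic Oncology", "reproductive", ["gastrointestinal_nutrition"]),
    ("hand_surgery", "Hand Surgery", "musculoskeletal", ["dermatologic"]),
    ("head_neck_surgery", "Head & Neck Surgery", "eent", ["dermatologic"]),
    ("hematology", "Hematology", "hematologic", ["infectious_diseases"]),
    ("hepatobiliary_surgery", "Hepatobiliary Surgery", "gastrointestinal_nutrition", ["hematologic"]),
    ("hepatology", "Hepatology", "gastrointestinal_nutrition", ["infectious_diseases", "hematologic"]),
    ("hiv_medicine", "HIV Medicine", "infectious_diseases", ["hematologic"]),
    ("infectious_disease", "Infectious Disease", "infectious_diseases", ["pulmonary"]),
    ("interventional_cardiology", "Interventional Cardiology", "cardiovascular", ["renal"]),
    ("interventional_radiology", "Interventional Radiology", "cardiovascular", ["genitourinary"]),
    ("maternal_fetal_medicine", "Maternal-Fetal Medicine", "reproductive", ["endocrine", "cardiovascular"]),
    ("medical_oncology", "Medical Oncology", "hematologic", ["gastrointestinal_nutrition", "reproductive"]),
    ("neonatology", "Neonatology", "pulmonary", ["cardiovascular", "infectious_diseases"]),
    ("nephrology", "Nephrology", "renal", ["cardiovascular", "endocrine"]),
    ("neurological_surgery", "Neurological Surgery", "neurologic", ["cardiovascular", "endocrine"]),
    ("neurology", "Neurology", "neurologic", ["psychiatry_behavioral", "cardiovascular"]),
    ("obstetrics_gynecology", "Obstetrics & Gynecology", "reproductive", ["endocrine", "genitourinary"]),
    ("occupational_medicine", "Occupational Medicine", "musculoskeletal", ["pulmonary", "dermatologic"]),
    ("ophthalmology", "Ophthalmology", "eent", ["endocrine", "neurologic"]),
    ("orthopedic_surgery", "Orthopedic Surgery", "musculoskeletal", ["neurologic"]),
    ("otolaryngology", "Otolaryngology", "eent", ["pulmonary"]),
    ("pain_medicine", "Pain Medicine", "neurologic", ["musculoskeletal", "psychiatry_behavioral"]),
    ("palliative_medicine", "Palliative Medicine", "neurologic", ["psychiatry_behavioral"]),
    ("pediatrics", "Pediatrics", "infectious_diseases", ["eent", "pulmonary"]),
    ("physical_medicine_rehabilitation", "Physical Medicine & Rehabilitation", "musculoskeletal", ["neurologic"]),
    ("plastic_surgery", "Plastic Surgery", "dermatologic", ["musculoskeletal"]),
    ("psychiatry", "Psychiatry", "psychiatry_behavioral", ["neurologic", "endocrine"]),
    ("pulmonology", "Pulmonology", "pulmonary", ["cardiovascular", "infectious_diseases"]),
    ("radiation_oncology", "Radiation Oncology", "hematologic", ["neurologic"]),
    ("reproductive_endocrinology", "Reproductive Endocrinology", "reproductive", ["endocrine"]),
    ("rheumatology", "Rheumatology", "musculoskeletal", ["dermatologic", "hematologic"]),
    ("sleep_medicine", "Sleep Medicine", "pulmonary", ["neurologic", "psychiatry_behavioral"]),
    ("spine_surgery", "Spine Surgery", "musculoskeletal", ["neurologic"]),
    ("sports_medicine", "Sports Medicine", "musculoskeletal", ["cardiovascular"]),
    ("surgical_oncology", "Surgical Oncology", "gastrointestinal_nutrition", ["hematologic", "reproductive"]),
    ("thoracic_surgery", "Thoracic Surgery", "pulmonary", ["cardiovascular"]),
    ("transplant_surgery", "Transplant Surgery", "renal", ["gastrointestinal_nutrition", "infectious_diseases"]),
    ("trauma_surgery", "Trauma Surgery", "musculoskeletal", ["cardiovascular", "neurologic"]),
    ("travel_medicine", "Travel Medicine", "infectious_diseases", ["gastrointestinal_nutrition", "dermatologic"]),
    ("urology", "Urology", "genitourinary", ["renal", "reproductive"]),
    ("vascular_surgery", "Vascular Surgery", "cardiovascular", ["hematologic", "renal"]),
    ("womens_health", "Women's Health", "reproductive", ["genitourinary", "endocrine"]),
    ("wound_care", "Wound Care", "dermatologic", ["infectious_diseases", "endocrine"]),
]


def default_systems() -> dict[str, SystemDomain]:
    """The 14-system blueprint registry, keyed by id."""
    return _registry(SystemDomain(i, n) for i, n in _SYSTEM_ROWS)


def default_specialties() -> dict[str, Specialty]:
    """The packaged 64-profile specialty registry, keyed by id."""
    multi = (Specialty(i, n, True) for i, n in _MULTI_SPECIALTIES)
    single = (Specialty(i, n, False) for i, n, _, _ in _SINGLE_SPECIALTIES)
    return _registry(list(multi) + list(single))


@dataclass(frozen=True)
class FrequencyLabelMap:
    """Complete mapping (specialty id, system id) -> FrequencyLabel.

    Covers the full cross product of the two registries it was built against.
    """

    entries: Mapping[tuple[str, str], FrequencyLabel]
    systems: Mapping[str, SystemDomain]
    specialties: Mapping[str, Specialty]

    def label_of(self, specialty: str, system: str) -> FrequencyLabel:
        """Frequency label for one (specialty, system) pair."""
        key = (specialty.strip().lower(), system.strip().lower())
        if key[0] not in self.specialties:
            raise BlueprintError(f"unknown specialty id {specialty!r}")
        if key[1] not in self.systems:
            raise BlueprintError(f"unknown system id {system!r}")
        return self.entries[key]


def build_label_map(
    assignments: Mapping[tuple[str, str], FrequencyLabel],
    systems: Mapping[str, SystemDomain],
    specialties: Mapping[str, Specialty],
    validate: bool = True,
) -> FrequencyLabelMap:
    """Complete explicit assignments over the registry cross product.

    Omitted pairs default to ``reference`` for multi-specialization profiles
    and ``distant`` otherwise, so a file only needs to list the dominant and
    relevant rows.
    """
    entries: dict[tuple[str, str], FrequencyLabel] = {}
    for spec in specialties.values():
        fill = FrequencyLabel.REFERENCE if spec.is_multi_specialization else FrequencyLabel.DISTANT
        for sys_id in systems:
            entries[(spec.id, sys_id)] = assignments.get((spec.id, sys_id), fill)
    label_map = FrequencyLabelMap(entries, dict(systems), dict(specialties))
    if validate:
        violations = validate_label_map(label_map)
        if violations:
            raise BlueprintError("invalid label map: " + "; ".join(violations))
    return label_map


def example_label_map(
    systems: Mapping[str, SystemDomain] | None = None,
    specialties: Mapping[str, Specialty] | None = None,
) -> FrequencyLabelMap:
    """The packaged illustrative label map over the default registries."""
    systems = default_systems() if systems is None else systems
    specialties = default_specialties() if specialties is None else specialties
    assignments: dict[tuple[str, str], FrequencyLabel] = {}
    for spec_id, _, dominant, relevant in _SINGLE_SPECIALTIES:
        if spec_id not in specialties:
            continue
        assignments[(spec_id, dominant)] = FrequencyLabel.DOMINANT
        for sys_id in relevant:
            assignments[(spec_id, sys_id)] = FrequencyLabel.RELEVANT
    return build_label_map(assignments, systems, specialties)


def load_label_map(
    path: str | Path | io.TextIOBase,
    systems: Mapping[str, SystemDomain],
    specialties: Mapping[str, Specialty],
) -> FrequencyLabelMap:
    """Read a ``specialty,system,label`` CSV and return a validated map.

    Rows may be listed in any order; distant (and, for general practice,
    reference) rows may be omitted.  Label strings are matched
    case-insensitively after trimming.
    """
    close = False
    if isinstance(path, (str, Path)):
        handle = open(path, newline="", encoding="utf-8")
        close = True
    else:
        handle = path
    try:
        reader = csv.DictReader(handle)
        required = {"specialty", "system", "label"}
        fields = {f.strip().lower() for f in (reader.fieldnames or [])}
        if not required <= fields:
            raise BlueprintError(
                f"label map header must contain {sorted(required)}, got {reader.fieldnames}"
            )
        assignments: dict[tuple[str, str], FrequencyLabel] = {}
        for lineno, row in enumerate(reader, start=2):
            row = {k.strip().lower(): (v or "") for k, v in row.items()}
            spec_id = row["specialty"].strip().lower()
            sys_id = row["system"].strip().lower()
            if spec_id not in specialties:
                raise BlueprintError(f"line {lineno}: unknown specialty id {row['specialty']!r}")
            if sys_id not in systems:
                raise BlueprintError(f"line {lineno}: unknown system id {row['system']!r}")
            if (spec_id, sys_id) in assignments:
                raise BlueprintError(f"line {lineno}: duplicate row for ({spec_id}, {sys_id})")
            assignments[(spec_id, sys_id)] = FrequencyLabel.parse(row["label"])
    finally:
        if close:
            handle.close()
    return build_label_map(assignments, systems, specialties)


def write_label_map(label_map: FrequencyLabelMap, path: str | Path) -> None:
    """Write a map as ``specialty,system,label`` CSV (full cross product)."""
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["specialty", "system", "label"])
        for (spec_id, sys_id), label in sorted(label_map.entries.items()):
            writer.writerow([spec_id, sys_id, label.name.lower()])


def validate_label_map(label_map: FrequencyLabelMap) -> list[str]:
    """Check the cardinality rules; return human-readable violations.

    Multi-specialization profiles must map every system to reference.  Every
    other profile must have exactly one dominant system, at most two relevant
    systems, no reference systems, and distant for the rest.
    """
    violations: list[str] = []
    n_systems = len(label_map.systems)
    for spec in label_map.specialties.values():
        counts = {label: 0 for label in FrequencyLabel}
        for sys_id in label_map.systems:
            key = (spec.id, sys_id)
            if key not in label_map.entries:
                violations.append(f"{spec.id}: missing entry for system {sys_id}")
                continue
            counts[label_map.entries[key]] += 1
        if spec.is_multi_specialization:
            if counts[FrequencyLabel.REFERENCE] != n_systems:
                violations.append(
                    f"{spec.id}: multi-specialization reference count "
                    f"{counts[FrequencyLabel.REFERENCE]} != {n_systems}"
                )
        else:
            if counts[FrequencyLabel.DOMINANT] != 1:
                violations.append(
                    f"{spec.id}: dominant count {counts[FrequencyLabel.DOMINANT]} != 1"
                )
            if counts[FrequencyLabel.RELEVANT] > 2:
                violations.append(
                    f"{spec.id}: relevant count {counts[FrequencyLabel.RELEVANT]} > 2"
                )
            if counts[FrequencyLabel.REFERENCE] > 0:
                violations.append(
                    f"{spec.id}: reference count {counts[FrequencyLabel.REFERENCE]} > 0"
                )
    return violations
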