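"""Scheduling-instance data model, JSON/CSV serialization and validation.

An instance describes one clinical specialty in one geographic region: a
planning horizon of working days (each split into a morning and an afternoon
period, so the period set has ``2 * horizon_days`` elements), the hospitals
with their consulting-office counts, the doctors with their duty calendars and
per-period appointment quotas, and the waiting list of patients with the
number of days each has already waited (their scheduling priority).

Period indexing is 1-based: period ``d`` belongs to day ``ceil(d / 2)``; odd
periods are mornings, even periods afternoons.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

MORNING = "morning"
AFTERNOON = "afternoon"


def day_of_period(d: int) -> int:
    """Working day (1-based) that period ``d`` belongs to."""
    return (d + 1) // 2


def period_of_day(d: int) -> str:
    """``'morning'`` for odd period indices, ``'afternoon'`` for even ones."""
    return MORNING if d % 2 == 1 else AFTERNOON


class InstanceParseError(ValueError):
    """Raised when an instance document is structurally invalid."""


@dataclass(frozen=True)
class HospitalSpec:
    """A hospital with ``offices`` consulting rooms available per period."""

    id: str
    offices: int


@dataclass(frozen=True)
class DoctorSpec:
    """A specialist doctor.

    ``appointments_per_period`` is the consultation quota per duty period,
    ``works_at`` the hospitals where the doctor holds a contract, and
    ``duty_periods`` the horizon periods in which the doctor is available for
    outpatient consultations.
    """

    id: str
    appointments_per_period: int
    works_at: frozenset[str]
    duty_periods: frozenset[int]


@dataclass(frozen=True)
class PatientSpec:
    """A wait-listed patient; ``waiting_days`` drives scheduling priority.

    ``severity_score`` is an optional clinical-severity priority used by the
    severity objective variant; it plays no role in the default
    waiting-time objective.
    """

    id: str
    waiting_days: int
    severity_score: float | None = None


@dataclass(frozen=True)
class Instance:
    horizon_days: int
    hospitals: tuple[HospitalSpec, ...]
    doctors: tuple[DoctorSpec, ...]
    patients: tuple[PatientSpec, ...]
    specialty: str = ""

    @property
    def n_periods(self) -> int:
        return 2 * self.horizon_days

    @property
    def periods(self) -> range:
        """Period indices 1..|D|, |D| = 2 * horizon_days."""
        return range(1, self.n_periods + 1)

    def hospital(self, hospital_id: str) -> HospitalSpec:
        for h in self.hospitals:
            if h.id == hospital_id:
                return h
        raise KeyError(f"unknown hospital {hospital_id!r}")

    def hospital_ids(self) -> list[str]:
        return [h.id for h in self.hospitals]

    def doctors_at(self, hospital_id: str) -> list[DoctorSpec]:
        return [m for m in self.doctors if hospital_id in m.works_at]

    def restrict_to_hospital(
        self, hospital_id: str, patients: Sequence[PatientSpec] | None = None
    ) -> "Instance":
        """Single-hospital sub-instance: one hospital, its doctors, and an
        optionally replaced patient list (used by the hybrid stage loop)."""
        h = self.hospital(hospital_id)
        docs = tuple(
            replace(m, works_at=frozenset({hospital_id}))
            for m in self.doctors_at(hospital_id)
        )
        return Instance(
            horizon_days=self.horizon_days,
            hospitals=(h,),
            doctors=docs,
            patients=tuple(patients if patients is not None else self.patients),
            specialty=self.specialty,
        )


@dataclass(frozen=True)
class ValidationReport:
    violations: tuple[tuple[str, str], ...] = ()

    @property
    def ok(self) -> bool:
        return not self.violations

    def message(self) -> str:
        return "; ".join(f"[{code}] {msg}" for code, msg in self.violations) or "ok"


def validate_instance(instance: Instance) -> ValidationReport:
    """Check every structural invariant an instance must satisfy before
    optimization: positive horizon, unique identifiers, referential integrity
    of ``works_at``, duty periods within 1..|D|, non-negative capacities, and
    strictly positive waiting days."""
    v: list[tuple[str, str]] = []
    if instance.horizon_days < 1:
        v.append(("horizon", f"horizon_days must be >= 1, got {instance.horizon_days}"))
    n_periods = instance.n_periods

    seen: set[str] = set()
    for kind, items in (
        ("hospital", instance.hospitals),
        ("doctor", instance.doctors),
        ("patient", instance.patients),
    ):
        for item in items:
            if item.id in seen:
                v.append(("duplicate_id", f"duplicate {kind} id {item.id!r}"))
            seen.add(item.id)

    hospital_ids = {h.id for h in instance.hospitals}
    for h in instance.hospitals:
        if h.offices < 0:
            v.append(("offices", f"hospital {h.id}: offices < 0"))

    for m in instance.doctors:
        if m.appointments_per_period < 0:
            v.append(("quota", f"doctor {m.id}: appointments_per_period < 0"))
        if not m.works_at:
            v.append(("works_at", f"doctor {m.id}: works at no hospital"))
        for hid in m.works_at:
            if hid not in hospital_ids:
                v.append(("works_at", f"doctor {m.id}: unknown hospital {hid!r}"))
        for d in m.duty_periods:
            if not 1 <= d <= n_periods:
                v.append(
                    ("duty_periods", f"doctor {m.id}: period {d} outside 1..{n_periods}")
                )

    for p in instance.patients:
        if p.waiting_days < 1:
            v.append(("waiting_days", f"patient {p.id}: waiting_days < 1"))
        if p.severity_score is not None and p.severity_score < 0:
            v.append(("severity_score", f"patient {p.id}: severity_score < 0"))

    return ValidationReport(tuple(v))


# ---------------------------------------------------------------------------
# JSON serialization

_KNOWN_TOP = {"specialty", "horizon_days", "hospitals", "doctors", "patients"}


def _require(doc: dict, key: str, context: str):
    if key not in doc:
        raise InstanceParseError(f"{context}: missing required field {key!r}")
    return doc[key]


def instance_to_dict(instance: Instance) -> dict:
    doc: dict = {
        "specialty": instance.specialty,
        "horizon_days": instance.horizon_days,
        "hospitals": [{"id": h.id, "offices": h.offices} for h in instance.hospitals],
        "doctors": [
            {
                "id": m.id,
                "appointments_per_period": m.appointments_per_period,
                "works_at": sorted(m.works_at),
                "duty_periods": sorted(m.duty_periods),
            }
            for m in instance.doctors
        ],
        "patients": [],
    }
    for p in instance.patients:
        rec: dict = {"id": p.id, "waiting_days": p.waiting_days}
        if p.severity_score is not None:
            rec["severity_score"] = p.severity_score
        doc["patients"].append(rec)
    return doc


def instance_from_dict(doc: dict) -> Instance:
    if not isinstance(doc, dict):
        raise InstanceParseError("instance document must be a JSON object")
    unknown = set(doc) - _KNOWN_TOP
    if unknown:
        logger.warning("ignoring unknown instance fields: %s", sorted(unknown))

    horizon_days = _require(doc, "horizon_days", "instance")
    if not isinstance(horizon_days, int) or horizon_days < 1:
        raise InstanceParseError("horizon_days must be a positive integer")

    hospitals = []
    for rec in _require(doc, "hospitals", "instance"):
        hospitals.append(
            HospitalSpec(
                id=str(_require(rec, "id", "hospital")),
                offices=int(_require(rec, "offices", f"hospital {rec.get('id')!r}")),
            )
        )
    doctors = []
    for rec in _require(doc, "doctors", "instance"):
        mid = str(_require(rec, "id", "doctor"))
        doctors.append(
            DoctorSpec(
                id=mid,
                appointments_per_period=int(
                    _require(rec, "appointments_per_period", f"doctor {mid!r}")
                ),
                works_at=frozenset(
                    str(h) for h in _require(rec, "works_at", f"doctor {mid!r}")
                ),
                duty_periods=frozenset(
                    int(d) for d in _require(rec, "duty_periods", f"doctor {mid!r}")
                ),
            )
        )
    patients = []
    for rec in _require(doc, "patients", "instance"):
        pid = str(_require(rec, "id", "patient"))
        sev = rec.get("severity_score")
        patients.append(
            PatientSpec(
                id=pid,
                waiting_days=int(_require(rec, "waiting_days", f"patient {pid!r}")),
                severity_score=float(sev) if sev is not None else None,
            )
        )
    return Instance(
        horizon_days=horizon_days,
        hospitals=tuple(hospitals),
        doctors=tuple(doctors),
        patients=tuple(patients),
        specialty=str(doc.get("specialty", "")),
    )


def load_instance(path: str | Path) -> Instance:
    """Load an instance JSON document; unknown fields are ignored with a
    warning, missing required fields raise :class:`InstanceParseError`."""
    path = Path(path)
    with path.open() as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise InstanceParseError(f"{path}: not valid JSON: {exc}") from exc
    return instance_from_dict(doc)


def write_instance(instance: Instance, path: str | Path) -> None:
    """Write the instance as a JSON document that round-trips through
    :func:`load_instance`."""
    report = validate_instance(instance)
    if not report.ok:
        raise ValueError(f"refusing to write invalid instance: {report.message()}")
    path = Path(path)
    with path.open("w") as fh:
        json.dump(instance_to_dict(instance), fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# CSV waiting-list import

def load_waitlist_csv(path: str | Path) -> tuple[PatientSpec, ...]:
    """Read a waiting list from CSV with header
    ``patient_id,waiting_days[,severity_score]``."""
    path = Path(path)
    patients: list[PatientSpec] = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {
            "patient_id",
            "waiting_days",
        }.issubset(reader.fieldnames):
            raise InstanceParseError(
                f"{path}: waiting-list CSV needs columns patient_id,waiting_days"
            )
        for row in reader:
            sev = row.get("severity_score")
            patients.append(
                PatientSpec(
                    id=row["patient_id"],
                    waiting_days=int(row["waiting_days"]),
                    severity_score=float(sev) if sev not in (None, "") else None,
                )
            )
    return tuple(patients)
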