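"""Integer linear program for prioritized outpatient appointment scheduling.

The model assigns each wait-listed patient at most one appointment with a
doctor, in a period of the planning horizon, at a hospital, maximizing the
total waiting time of the patients scheduled — so the patients who have
waited longest are scheduled first, and any leftover capacity is never wasted
while a longer-waiting patient sits unscheduled.

Decision variables (all binary):

* ``x[p, m, d, h]`` — patient ``p`` sees doctor ``m`` in period ``d`` at
  hospital ``h``;
* ``y[m, h]`` — doctor ``m`` is assigned to work at hospital ``h`` during the
  horizon;
* ``z[m, d]`` — doctor ``m`` holds consultations in period ``d``.

Constraints: each patient is scheduled at most once; a doctor only works at
hospitals in their contract and in their duty periods (enforced structurally:
variables for other combinations are never created); at most ``nc_m``
appointments per doctor per period, summed across hospitals; at most ``g_h``
distinct active doctors per hospital (the office cap, applied horizon-wide
with a single ``y`` per doctor-hospital pair); and the linking constraints
``x <= y`` and ``x <= z`` in per-tuple form, which keeps the LP relaxation
tight.

The objective is either the waiting-time priority ``wt_p`` (default) or an
optional clinical-severity score per patient.

The solver is HiGHS branch-and-bound via :func:`scipy.optimize.milp`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable

import numpy as np
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, milp

from .instances import (
    AFTERNOON,
    Instance,
    MORNING,
    ValidationReport,
    day_of_period,
    period_of_day,
)

DEFAULT_GAP_TOLERANCE = 1e-9
DEFAULT_TIME_LIMIT_S = 600.0


class ObjectiveMode(str, Enum):
    WAITING_TIME = "waiting_time"
    SEVERITY = "severity"


@dataclass
class ModelHandle:
    """Constructed model plus variable index maps.

    ``x_keys[i] = (patient_id, doctor_id, period, hospital_id)`` is the tuple
    carried by column ``i``; ``y`` and ``z`` columns follow the ``x`` block.
    Only combinations with a valid doctor-hospital contract and duty period
    are materialized.
    """

    instance: Instance
    objective_mode: ObjectiveMode
    x_keys: list[tuple[str, str, int, str]]
    y_keys: list[tuple[str, str]]
    z_keys: list[tuple[str, int]]
    c: np.ndarray
    constraints: list[LinearConstraint]

    @property
    def n_vars(self) -> int:
        return len(self.x_keys) + len(self.y_keys) + len(self.z_keys)


@dataclass
class Solution:
    status: str  # optimal | feasible | infeasible | error
    objective: float
    gap_percent: float
    assignments: frozenset[tuple[str, str, int, str]] = frozenset()
    active_doctor_hospital: frozenset[tuple[str, str]] = frozenset()
    active_doctor_period: frozenset[tuple[str, int]] = frozenset()
    objective_mode: ObjectiveMode = ObjectiveMode.WAITING_TIME
    solver_message: str = ""

    @property
    def scheduled_patient_ids(self) -> set[str]:
        return {p for p, _, _, _ in self.assignments}


@dataclass(frozen=True)
class Appointment:
    patient_id: str
    hospital_id: str
    doctor_id: str
    day: int
    period_of_day: str  # morning | afternoon
    slot_time: str  # HH:MM
    office_number: int


@dataclass
class Schedule:
    appointments: list[Appointment]
    unscheduled_patient_ids: list[str]


def build_model(
    instance: Instance,
    objective_mode: ObjectiveMode | str = ObjectiveMode.WAITING_TIME,
) -> ModelHandle:
    """Build the scheduling ILP with sparse variable construction.

    ``x`` variables exist only where the doctor works at the hospital and is
    on duty in the period; doctor-eligibility constraints therefore never
    need explicit rows. In severity mode every patient must carry a
    ``severity_score``.
    """
    mode = ObjectiveMode(objective_mode)
    if mode is ObjectiveMode.SEVERITY:
        missing = [p.id for p in instance.patients if p.severity_score is None]
        if missing:
            raise ValueError(
                f"severity objective requires severity_score for all patients; "
                f"missing for {missing[:5]}"
            )

    y_keys = [
        (m.id, h) for m in instance.doctors for h in sorted(m.works_at)
    ]
    z_keys = [
        (m.id, d) for m in instance.doctors for d in sorted(m.duty_periods)
    ]
    x_keys = [
        (p.id, m.id, d, h)
        for p in instance.patients
        for m in instance.doctors
        for d in sorted(m.duty_periods)
        for h in sorted(m.works_at)
    ]

    nx, ny, nz = len(x_keys), len(y_keys), len(z_keys)
    n = nx + ny + nz
    y_off = {k: nx + i for i, k in enumerate(y_keys)}
    z_off = {k: nx + ny + i for i, k in enumerate(z_keys)}

    weight = {
        p.id: (p.waiting_days if mode is ObjectiveMode.WAITING_TIME else p.severity_score)
        for p in instance.patients
    }
    c = np.zeros(n)
    for i, (pid, _, _, _) in enumerate(x_keys):
        c[i] = -float(weight[pid])  # milp minimizes

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    ub: list[float] = []
    r = 0

    # (1) each patient scheduled at most once
    patient_rows: dict[str, int] = {}
    for p in instance.patients:
        patient_rows[p.id] = r
        ub.append(1.0)
        r += 1
    # (4) per-doctor-per-period quota, summed over hospitals
    quota_rows: dict[tuple[str, int], int] = {}
    for m in instance.doctors:
        for d in sorted(m.duty_periods):
            quota_rows[(m.id, d)] = r
            ub.append(float(m.appointments_per_period))
            r += 1
    # (5) office cap: at most g_h active doctors per hospital
    for h in instance.hospitals:
        for (mid, hid) in y_keys:
            if hid == h.id:
                rows.append(r)
                cols.append(y_off[(mid, hid)])
                vals.append(1.0)
        ub.append(float(h.offices))
        r += 1
    # (6)/(7) per-tuple linking x <= y, x <= z
    for i, (pid, mid, d, hid) in enumerate(x_keys):
        rows += [patient_rows[pid], quota_rows[(mid, d)]]
        cols += [i, i]
        vals += [1.0, 1.0]
        rows += [r, r, r + 1, r + 1]
        cols += [i, y_off[(mid, hid)], i, z_off[(mid, d)]]
        vals += [1.0, -1.0, 1.0, -1.0]
        ub += [0.0, 0.0]
        r += 2

    constraints: list[LinearConstraint] = []
    if r and n:
        A = sp.csr_matrix(
            (vals, (rows, cols)), shape=(r, n)
        )
        constraints.append(LinearConstraint(A, -np.inf, np.asarray(ub)))

    return ModelHandle(
        instance=instance,
        objective_mode=mode,
        x_keys=x_keys,
        y_keys=y_keys,
        z_keys=z_keys,
        c=c,
        constraints=constraints,
    )


def solve(
    model: ModelHandle,
    time_limit_s: float = DEFAULT_TIME_LIMIT_S,
    gap_tolerance: float = DEFAULT_GAP_TOLERANCE,
    seed: int | None = None,
) -> Solution:
    """Run branch-and-bound to the requested relative gap and decode the
    incumbent.

    The reported objective is recomputed exactly (integer arithmetic over the
    decoded assignment set), not read back from solver floating point. The
    ``seed`` parameter is part of the call contract for solver backends with
    randomized components; HiGHS through scipy takes no seed, and its results
    are objective-deterministic.
    """
    del seed  # no randomized component in the HiGHS backend
    if not model.x_keys:
        return Solution(
            status="optimal", objective=0.0, gap_percent=0.0,
            objective_mode=model.objective_mode,
            solver_message="empty model: no schedulable patient-slot pairs",
        )

    res = milp(
        c=model.c,
        constraints=model.constraints,
        integrality=np.ones(model.n_vars),
        bounds=Bounds(0, 1),
        options={
            "time_limit": float(time_limit_s),
            "mip_rel_gap": float(gap_tolerance),
            "disp": False,
        },
    )

    if res.status == 2:
        return Solution(
            status="infeasible", objective=0.0, gap_percent=float("inf"),
            objective_mode=model.objective_mode, solver_message=res.message,
        )
    if res.x is None:
        return Solution(
            status="error", objective=0.0, gap_percent=float("inf"),
            objective_mode=model.objective_mode, solver_message=res.message,
        )

    nx, ny = len(model.x_keys), len(model.y_keys)
    xv = res.x
    assignments = frozenset(
        model.x_keys[i] for i in range(nx) if xv[i] > 0.5
    )
    active_mh = frozenset(
        model.y_keys[i] for i in range(ny) if xv[nx + i] > 0.5
    )
    active_md = frozenset(
        model.z_keys[i] for i in range(len(model.z_keys)) if xv[nx + ny + i] > 0.5
    )
    weight = {
        p.id: (
            p.waiting_days
            if model.objective_mode is ObjectiveMode.WAITING_TIME
            else p.severity_score
        )
        for p in model.instance.patients
    }
    objective = float(sum(weight[p] for p, _, _, _ in assignments))
    gap = float(res.mip_gap) * 100.0 if res.mip_gap is not None else float("inf")
    status = "optimal" if res.status == 0 else "feasible"
    return Solution(
        status=status,
        objective=objective,
        gap_percent=max(gap, 0.0),
        assignments=assignments,
        active_doctor_hospital=active_mh,
        active_doctor_period=active_md,
        objective_mode=model.objective_mode,
        solver_message=res.message,
    )


def check_solution(instance: Instance, solution: Solution) -> ValidationReport:
    """Re-verify a decoded solution against every model constraint without
    going through the solver: assignment uniqueness, contract and duty
    eligibility, per-period quotas, the office cap, the linking constraints,
    and exact objective recomputation."""
    v: list[tuple[str, str]] = []
    doctors = {m.id: m for m in instance.doctors}
    hospitals = {h.id: h for h in instance.hospitals}
    patients = {p.id: p for p in instance.patients}

    seen_patients: set[str] = set()
    per_md_count: dict[tuple[str, int], int] = {}
    for (pid, mid, d, hid) in solution.assignments:
        if pid not in patients or mid not in doctors or hid not in hospitals:
            v.append(("reference", f"assignment ({pid},{mid},{d},{hid}) references unknown entity"))
            continue
        if pid in seen_patients:
            v.append(("constraint (1)", f"patient {pid} scheduled more than once"))
        seen_patients.add(pid)
        m = doctors[mid]
        if hid not in m.works_at:
            v.append(("constraint (2)", f"doctor {mid} does not work at {hid}"))
        if d not in m.duty_periods:
            v.append(("constraint (3)", f"doctor {mid} is off duty in period {d}"))
        per_md_count[(mid, d)] = per_md_count.get((mid, d), 0) + 1
        if (mid, hid) not in solution.active_doctor_hospital:
            v.append(("constraint (6)", f"x set but y[{mid},{hid}] = 0"))
        if (mid, d) not in solution.active_doctor_period:
            v.append(("constraint (7)", f"x set but z[{mid},{d}] = 0"))

    for (mid, d), count in per_md_count.items():
        if mid in doctors and count > doctors[mid].appointments_per_period:
            v.append(
                ("constraint (4)",
                 f"doctor {mid} holds {count} appointments in period {d}, "
                 f"quota {doctors[mid].appointments_per_period}")
            )

    for hid, h in hospitals.items():
        active = {m for (m, hh) in solution.active_doctor_hospital if hh == hid}
        if len(active) > h.offices:
            v.append(
                ("constraint (5)",
                 f"hospital {hid}: {len(active)} active doctors exceed {h.offices} offices")
            )
    for (mid, hid) in solution.active_doctor_hospital:
        if mid in doctors and hid not in doctors[mid].works_at:
            v.append(("constraint (2)", f"y set for non-contract pair ({mid},{hid})"))
    for (mid, d) in solution.active_doctor_period:
        if mid in doctors and d not in doctors[mid].duty_periods:
            v.append(("constraint (3)", f"z set for off-duty pair ({mid},{d})"))

    weight = {
        p.id: (
            p.waiting_days
            if solution.objective_mode is ObjectiveMode.WAITING_TIME
            else (p.severity_score or 0.0)
        )
        for p in instance.patients
    }
    recomputed = float(
        sum(weight[pid] for (pid, _, _, _) in solution.assignments if pid in weight)
    )
    if recomputed != solution.objective:
        v.append(
            ("objective",
             f"reported objective {solution.objective} != recomputed {recomputed}")
        )
    return ValidationReport(tuple(v))


_MORNING_START = 9 * 60  # 09:00
_AFTERNOON_START = 14 * 60  # 14:00
APPOINTMENT_MINUTES = 20


def _slot_time(period_label: str, slot_index: int) -> str:
    base = _MORNING_START if period_label == MORNING else _AFTERNOON_START
    minutes = base + APPOINTMENT_MINUTES * slot_index
    return f"{minutes // 60:02d}:{minutes % 60:02d}"


def extract_schedule(instance: Instance, solution: Solution) -> Schedule:
    """Turn the solved assignment set into per-patient appointment records.

    Within each (hospital, period), active doctors are numbered into offices
    1..g_h in doctor-id order; within each (doctor, period), patients receive
    consecutive 20-minute slots (mornings from 09:00, afternoons from 14:00)
    ordered by waiting time (longest first, ties by patient id)."""
    report = check_solution(instance, solution)
    if not report.ok:
        raise ValueError(f"cannot extract schedule from invalid solution: {report.message()}")

    waiting = {p.id: p.waiting_days for p in instance.patients}
    by_hd: dict[tuple[str, int], list[tuple[str, str]]] = {}
    for (pid, mid, d, hid) in solution.assignments:
        by_hd.setdefault((hid, d), []).append((mid, pid))

    appointments: list[Appointment] = []
    for (hid, d), pairs in by_hd.items():
        label = period_of_day(d)
        day = day_of_period(d)
        doctors_here = sorted({mid for mid, _ in pairs})
        office = {mid: i + 1 for i, mid in enumerate(doctors_here)}
        for mid in doctors_here:
            pids = sorted(
                (pid for m2, pid in pairs if m2 == mid),
                key=lambda pid: (-waiting[pid], pid),
            )
            for slot, pid in enumerate(pids):
                appointments.append(
                    Appointment(
                        patient_id=pid,
                        hospital_id=hid,
                        doctor_id=mid,
                        day=day,
                        period_of_day=label,
                        slot_time=_slot_time(label, slot),
                        office_number=office[mid],
                    )
                )

    appointments.sort(
        key=lambda a: (a.hospital_id, a.day, a.period_of_day == AFTERNOON,
                       a.office_number, a.slot_time)
    )
    scheduled = {a.patient_id for a in appointments}
    unscheduled = sorted(
        (p.id for p in instance.patients if p.id not in scheduled),
        key=lambda pid: (-waiting[pid], pid),
    )
    return Schedule(appointments=appointments, unscheduled_patient_ids=unscheduled)


def solve_instance(
    instance: Instance,
    objective_mode: ObjectiveMode | str = ObjectiveMode.WAITING_TIME,
    time_limit_s: float = DEFAULT_TIME_LIMIT_S,
    gap_tolerance: float = DEFAULT_GAP_TOLERANCE,
    seed: int | None = None,
) -> Solution:
    """Convenience wrapper: build and solve in one call."""
    return solve(
        build_model(instance, objective_mode),
        time_limit_s=time_limit_s,
        gap_tolerance=gap_tolerance,
        seed=seed,
    )


def write_schedule_csv(instance: Instance, schedule: Schedule, path: str | Path) -> None:
    """Schedule CSV, one row per appointment, ordered by
    (hospital, day, period, office, slot)."""
    import csv

    waiting = {p.id: p.waiting_days for p in instance.patients}
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["patient_id", "waiting_days", "hospital_id", "doctor_id",
             "day", "period", "slot_time", "office_number"]
        )
        for a in schedule.appointments:
            w.writerow(
                [a.patient_id, waiting[a.patient_id], a.hospital_id, a.doctor_id,
                 a.day, a.period_of_day, a.slot_time, a.office_number]
            )


def write_unscheduled_csv(instance: Instance, schedule: Schedule, path: str | Path) -> None:
    import csv

    waiting = {p.id: p.waiting_days for p in instance.patients}
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["patient_id", "waiting_days"])
        for pid in schedule.unscheduled_patient_ids:
            w.writerow([pid, waiting[pid]])
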