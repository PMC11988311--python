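"""Host-hospital-first hybrid scheduling across a region.

A region's hospitals share one specialty waiting list. The host hospital
(where the run is initiated) is scheduled first with the full list; patients
it cannot absorb spill over to support hospitals chosen by the decision
maker, one at a time, each stage solving a single-hospital ILP on the
patients still waiting. The loop stops when (i) the decision maker offers no
further hospital, (ii) the waiting list empties, or (iii) no remaining
hospital has capacity.

The decision maker is abstracted as a :class:`HospitalChoicePolicy`:
``scripted`` mode fixes the hospital order up front (deterministic, used in
tests and batch runs); ``interactive`` mode asks before each support
hospital.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

from . import ilp, oracle
from .instances import Instance, PatientSpec

__all__ = [
    "HospitalChoicePolicy",
    "HybridResult",
    "SummaryStats",
    "capacity_available",
    "merge_region",
    "run_hybrid",
    "summarize",
]


@dataclass(frozen=True)
class HospitalChoicePolicy:
    mode: str = "scripted"  # scripted | interactive
    ordered_hospital_ids: tuple[str, ...] = ()
    # interactive mode: called with the next candidate id, returns True to use it
    confirm: Callable[[str], bool] | None = None

    def __post_init__(self):
        if self.mode not in ("scripted", "interactive"):
            raise ValueError(f"unknown policy mode {self.mode!r}")
        ids = self.ordered_hospital_ids
        if len(set(ids)) != len(ids):
            raise ValueError("ordered_hospital_ids must be distinct")
        if not ids:
            raise ValueError("policy needs at least the host hospital")

    @property
    def host(self) -> str:
        return self.ordered_hospital_ids[0]


@dataclass
class StageRecord:
    hospital_id: str
    capacity: int
    solution: ilp.Solution | None  # None when skipped for zero capacity
    n_scheduled: int


@dataclass
class HybridResult:
    combined_schedule: ilp.Schedule
    per_hospital_solutions: list[tuple[str, ilp.Solution]]
    stages: list[StageRecord]
    remaining_waitlist: list[str]
    support_hospitals_used: list[str]
    host_unattended_percent: float
    initial_waitlist_size: int
    termination: str  # policy_exhausted | waitlist_empty | no_capacity | error
    specialty: str = ""
    horizon_days: int = 0


@dataclass
class SummaryStats:
    host_unattended_percent: float
    n_support_hospitals: int
    max_gap_percent: float
    max_additional_wait_days: int
    per_specialty_label: str = ""


def capacity_available(instance: Instance, hospital_id: str) -> int:
    """Appointment capacity of one hospital for the horizon: doctors with
    free periods, capped by the office count (top-``g_h`` doctor capacities)."""
    instance.hospital(hospital_id)  # raises KeyError for unknown ids
    return oracle.hospital_capacity(instance, hospital_id)


def merge_region(fragments: Sequence[Instance]) -> Instance:
    """Combine per-hospital instance fragments that share one specialty,
    horizon and waiting list into a single regional instance."""
    if not fragments:
        raise ValueError("empty region")
    first = fragments[0]
    hospitals: list = []
    doctors: list = []
    seen_h: set[str] = set()
    seen_m: set[str] = set()
    patients: dict[str, PatientSpec] = {}
    for frag in fragments:
        if frag.horizon_days != first.horizon_days:
            raise ValueError("fragments disagree on horizon_days")
        if frag.specialty != first.specialty:
            raise ValueError("fragments disagree on specialty")
        for h in frag.hospitals:
            if h.id not in seen_h:
                hospitals.append(h)
                seen_h.add(h.id)
        for m in frag.doctors:
            if m.id not in seen_m:
                doctors.append(m)
                seen_m.add(m.id)
        for p in frag.patients:
            prev = patients.setdefault(p.id, p)
            if prev != p:
                raise ValueError(f"fragments disagree on patient {p.id!r}")
    return Instance(
        horizon_days=first.horizon_days,
        hospitals=tuple(hospitals),
        doctors=tuple(doctors),
        patients=tuple(patients.values()),
        specialty=first.specialty,
    )


def run_hybrid(
    region: Instance | Sequence[Instance],
    policy: HospitalChoicePolicy,
    time_limit_s: float = ilp.DEFAULT_TIME_LIMIT_S,
    gap_tolerance: float = ilp.DEFAULT_GAP_TOLERANCE,
    seed: int | None = None,
    objective_mode: ilp.ObjectiveMode | str = ilp.ObjectiveMode.WAITING_TIME,
) -> HybridResult:
    """Run the host-first stage loop over the region.

    Each stage restricts the region to one hospital and the patients not yet
    scheduled, solves the single-hospital ILP, and removes the newly
    scheduled patients from the waiting list. A stage with zero capacity or
    an empty solve falls through to the next hospital choice.
    """
    instance = region if isinstance(region, Instance) else merge_region(list(region))
    for hid in policy.ordered_hospital_ids:
        instance.hospital(hid)  # fail fast on unknown ids

    waitlist: list[PatientSpec] = list(instance.patients)
    initial_size = len(waitlist)
    stages: list[StageRecord] = []
    per_hospital_solutions: list[tuple[str, ilp.Solution]] = []
    all_appointments: list[ilp.Appointment] = []
    support_used: list[str] = []
    host_scheduled = 0
    termination = "policy_exhausted"

    for stage_idx, hid in enumerate(policy.ordered_hospital_ids):
        if not waitlist:
            termination = "waitlist_empty"
            break
        if policy.mode == "interactive" and stage_idx > 0:
            ask = policy.confirm or (lambda _h: True)
            if not ask(hid):
                termination = "policy_exhausted"
                break
        sub = instance.restrict_to_hospital(hid, patients=waitlist)
        cap = capacity_available(sub, hid)
        if cap <= 0:
            stages.append(StageRecord(hid, cap, None, 0))
            continue
        solution = ilp.solve_instance(
            sub,
            objective_mode=objective_mode,
            time_limit_s=time_limit_s,
            gap_tolerance=gap_tolerance,
            seed=seed,
        )
        if solution.status in ("error", "infeasible"):
            stages.append(StageRecord(hid, cap, solution, 0))
            per_hospital_solutions.append((hid, solution))
            termination = "error"
            break
        scheduled_ids = solution.scheduled_patient_ids
        stages.append(StageRecord(hid, cap, solution, len(scheduled_ids)))
        if not scheduled_ids:
            # valid solve but no new appointments: same fallback as no capacity
            continue
        per_hospital_solutions.append((hid, solution))
        schedule = ilp.extract_schedule(sub, solution)
        all_appointments.extend(schedule.appointments)
        if stage_idx == 0:
            host_scheduled = len(scheduled_ids)
        elif hid not in support_used:
            support_used.append(hid)
        waitlist = [p for p in waitlist if p.id not in scheduled_ids]
    else:
        if not waitlist:
            termination = "waitlist_empty"
        elif all(s.capacity <= s.n_scheduled for s in stages):
            # every offered hospital was drained to its capacity
            termination = "no_capacity"
        else:
            termination = "policy_exhausted"

    waiting = {p.id: p.waiting_days for p in instance.patients}
    remaining = sorted((p.id for p in waitlist), key=lambda pid: (-waiting[pid], pid))
    all_appointments.sort(
        key=lambda a: (a.hospital_id, a.day, a.period_of_day == "afternoon",
                       a.office_number, a.slot_time)
    )
    combined = ilp.Schedule(
        appointments=all_appointments, unscheduled_patient_ids=remaining
    )
    host_unattended = (
        100.0 * (initial_size - host_scheduled) / initial_size if initial_size else 0.0
    )
    return HybridResult(
        combined_schedule=combined,
        per_hospital_solutions=per_hospital_solutions,
        stages=stages,
        remaining_waitlist=remaining,
        support_hospitals_used=support_used,
        host_unattended_percent=host_unattended,
        initial_waitlist_size=initial_size,
        termination=termination,
        specialty=instance.specialty,
        horizon_days=instance.horizon_days,
    )


def summarize(result: HybridResult, horizon_days: int | None = None) -> SummaryStats:
    """Key outcome figures of a hybrid run: share of the list the host could
    not absorb, number of support hospitals engaged, worst solver gap over
    the stages, and the worst additional wait (the latest appointment day —
    bounded by the horizon whenever everyone was scheduled)."""
    del horizon_days  # carried on the result; kept for call-site symmetry
    gaps = [
        s.solution.gap_percent
        for s in result.stages
        if s.solution is not None and s.solution.status in ("optimal", "feasible")
    ]
    max_day = max((a.day for a in result.combined_schedule.appointments), default=0)
    return SummaryStats(
        host_unattended_percent=result.host_unattended_percent,
        n_support_hospitals=len(result.support_hospitals_used),
        max_gap_percent=max(gaps, default=0.0),
        max_additional_wait_days=max_day,
        per_specialty_label=result.specialty,
    )


def result_to_report(result: HybridResult) -> dict:
    """JSON-serializable report: summary statistics plus per-stage solver
    metadata."""
    stats = summarize(result)
    return {
        "specialty": result.specialty,
        "horizon_days": result.horizon_days,
        "initial_waitlist_size": result.initial_waitlist_size,
        "host_unattended_percent": stats.host_unattended_percent,
        "n_support_hospitals": stats.n_support_hospitals,
        "support_hospitals_used": result.support_hospitals_used,
        "max_gap_percent": stats.max_gap_percent,
        "max_additional_wait_days": stats.max_additional_wait_days,
        "n_scheduled": len(result.combined_schedule.appointments),
        "n_remaining": len(result.remaining_waitlist),
        "termination": result.termination,
        "stages": [
            {
                "hospital_id": s.hospital_id,
                "capacity": s.capacity,
                "n_scheduled": s.n_scheduled,
                "status": s.solution.status if s.solution else "skipped_no_capacity",
                "objective": s.solution.objective if s.solution else 0.0,
                "gap_percent": s.solution.gap_percent if s.solution else 0.0,
            }
            for s in result.stages
        ],
    }


def write_report(result: HybridResult, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(result_to_report(result), fh, indent=1)
        fh.write("\n")
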