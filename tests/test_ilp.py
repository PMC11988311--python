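import dataclasses

import numpy as np
import pytest

from waitsched import (
    ObjectiveMode,
    PatientSpec,
    Solution,
    build_model,
    builtin_instance,
    check_solution,
    extract_schedule,
    solve,
    solve_instance,
)
from waitsched.ilp import write_schedule_csv, write_unscheduled_csv

from conftest import make_instance, random_single_hospital_instance


def test_sparse_variable_counts(toy_t1):
    m = build_model(toy_t1)
    assert len(m.x_keys) == 8  # 4 patients x 1 doctor x 2 periods x 1 hospital
    assert len(m.y_keys) == 1
    assert len(m.z_keys) == 2


def test_off_duty_doctor_gets_no_variables():
    inst = make_instance(
        [("H1", 1)],
        [("M1", 2, {"H1"}, set()), ("M2", 2, {"H1"}, {1})],
        [("P1", 5)],
        1,
    )
    m = build_model(inst)
    assert all(mid != "M1" for (_, mid, _, _) in m.x_keys)


def test_sensitivity_class_indexes_over_ten_periods():
    inst = builtin_instance("I31", seed=0)
    m = build_model(inst)
    assert inst.n_periods == 10
    assert max(d for (_, _, d, _) in m.x_keys) <= 10


def test_empty_patient_list_is_optimal_zero():
    inst = make_instance([("H1", 1)], [("M1", 2, {"H1"}, {1, 2})], [], 1)
    sol = solve_instance(inst)
    assert sol.status == "optimal"
    assert sol.objective == 0


def test_toy_objectives_match_enumeration(toy_t1, toy_t2):
    s1 = solve_instance(toy_t1)
    assert (s1.status, s1.objective) == ("optimal", 25)
    assert s1.scheduled_patient_ids == {"P1", "P2", "P3", "P4"}
    s2 = solve_instance(toy_t2)
    assert (s2.status, s2.objective) == ("optimal", 17)
    assert s2.scheduled_patient_ids == {"P1", "P2"}


def test_solver_solution_passes_independent_check(toy_t1):
    sol = solve_instance(toy_t1)
    assert check_solution(toy_t1, sol).ok


def test_double_assignment_violates_patient_uniqueness(toy_t1):
    sol = solve_instance(toy_t1)
    extra = next(iter(sol.assignments))
    doubled = dataclasses.replace(
        sol,
        assignments=sol.assignments | {(extra[0], extra[1], 2 if extra[2] == 1 else 1,
                                        extra[3])},
    )
    report = check_solution(toy_t1, doubled)
    assert any(code == "constraint (1)" for code, _ in report.violations)


def test_office_cap_violation_detected():
    inst = make_instance(
        [("H1", 1)],
        [("M1", 1, {"H1"}, {1}), ("M2", 1, {"H1"}, {1})],
        [("P1", 9), ("P2", 8)],
        1,
    )
    bad = Solution(
        status="feasible",
        objective=17,
        gap_percent=0.0,
        assignments=frozenset({("P1", "M1", 1, "H1"), ("P2", "M2", 1, "H1")}),
        active_doctor_hospital=frozenset({("M1", "H1"), ("M2", "H1")}),
        active_doctor_period=frozenset({("M1", 1), ("M2", 1)}),
    )
    report = check_solution(inst, bad)
    assert any(code == "constraint (5)" for code, _ in report.violations)


def test_objective_mismatch_detected(toy_t2):
    sol = solve_instance(toy_t2)
    lied = dataclasses.replace(sol, objective=sol.objective + 1)
    assert any(c == "objective" for c, _ in check_solution(toy_t2, lied).violations)


def test_schedule_slot_times_and_offices(toy_t1):
    sol = solve_instance(toy_t1)
    sched = extract_schedule(toy_t1, sol)
    assert len(sched.appointments) == 4
    assert sched.unscheduled_patient_ids == []
    times = sorted((a.period_of_day, a.slot_time) for a in sched.appointments)
    assert times == [
        ("afternoon", "14:00"), ("afternoon", "14:20"),
        ("morning", "09:00"), ("morning", "09:20"),
    ]
    assert all(a.office_number == 1 for a in sched.appointments)
    assert all(a.day == 1 for a in sched.appointments)


def test_three_morning_appointments_spaced_20_minutes():
    inst = make_instance(
        [("H1", 1)], [("M1", 3, {"H1"}, {1})],
        [("P1", 9), ("P2", 8), ("P3", 7)], 1,
    )
    sched = extract_schedule(inst, solve_instance(inst))
    assert sorted(a.slot_time for a in sched.appointments) == [
        "09:00", "09:20", "09:40"
    ]


def test_schedule_csv_round(tmp_path, toy_t2):
    sol = solve_instance(toy_t2)
    sched = extract_schedule(toy_t2, sol)
    write_schedule_csv(toy_t2, sched, tmp_path / "s.csv")
    write_unscheduled_csv(toy_t2, sched, tmp_path / "u.csv")
    lines = (tmp_path / "s.csv").read_text().strip().splitlines()
    assert lines[0] == (
        "patient_id,waiting_days,hospital_id,doctor_id,day,period,slot_time,"
        "office_number"
    )
    assert len(lines) == 3
    ulines = (tmp_path / "u.csv").read_text().strip().splitlines()
    assert ulines[1:] == ["P3,5", "P4,3"]


def test_severity_mode_requires_scores(toy_t1):
    with pytest.raises(ValueError, match="severity"):
        build_model(toy_t1, objective_mode="severity")


def test_severity_mode_prioritizes_high_scores(toy_t2):
    # invert priorities: the two shortest waits carry the highest severity
    patients = tuple(
        PatientSpec(p.id, p.waiting_days, severity_score=s)
        for p, s in zip(toy_t2.patients, [0.5, 1.0, 9.0, 8.0])
    )
    inst = dataclasses.replace(toy_t2, patients=patients)
    sol = solve_instance(inst, objective_mode=ObjectiveMode.SEVERITY)
    assert sol.scheduled_patient_ids == {"P3", "P4"}
    assert sol.objective == 17.0
    assert check_solution(inst, sol).ok


def test_unscheduled_never_outwait_scheduled():
    """Longest-waiting patients are scheduled first: no unscheduled patient
    may wait strictly longer than a scheduled one."""
    rng = np.random.default_rng(99)
    for _ in range(25):
        inst = random_single_hospital_instance(rng)
        sol = solve_instance(inst)
        assert sol.status == "optimal"
        waits = {p.id: p.waiting_days for p in inst.patients}
        scheduled = sol.scheduled_patient_ids
        unscheduled = set(waits) - scheduled
        if scheduled and unscheduled:
            assert max(waits[p] for p in unscheduled) <= min(
                waits[p] for p in scheduled
            )


def test_objective_never_decreases_with_more_resources():
    rng = np.random.default_rng(31)
    for _ in range(10):
        inst = random_single_hospital_instance(rng)
        base = solve_instance(inst).objective
        m = inst.doctors[0]
        richer_doctor = dataclasses.replace(
            m,
            appointments_per_period=m.appointments_per_period + 1,
            duty_periods=frozenset(set(m.duty_periods) | {1}),
        )
        richer = dataclasses.replace(
            inst, doctors=(richer_doctor,) + inst.doctors[1:]
        )
        assert solve_instance(richer).objective >= base
        h = inst.hospitals[0]
        roomier = dataclasses.replace(
            inst,
            hospitals=(dataclasses.replace(h, offices=h.offices + 1),)
            + inst.hospitals[1:],
        )
        assert solve_instance(roomier).objective >= base


def test_objective_recomputes_exactly_from_assignments():
    rng = np.random.default_rng(12)
    for _ in range(10):
        inst = random_single_hospital_instance(rng)
        sol = solve_instance(inst)
        waits = {p.id: p.waiting_days for p in inst.patients}
        assert sol.objective == sum(waits[p] for p in sol.scheduled_patient_ids)
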