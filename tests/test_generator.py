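import math

import numpy as np
import pytest

from waitsched import (
    ClassSpec,
    builtin_class_names,
    builtin_instance,
    generate_group_instance,
    generate_instance,
    generate_waiting_times,
    greedy_objective,
    perturb_duty,
    perturb_offices,
    perturb_quota,
    validate_instance,
)
from waitsched.generator import group_parameters


def test_degenerate_average_gives_all_ones():
    assert generate_waiting_times(5, 1, seed=0) == [1, 1, 1, 1, 1]


def test_waiting_times_are_reproducible_and_bounded():
    a = generate_waiting_times(100, 196, seed=42)
    b = generate_waiting_times(100, 196, seed=42)
    assert a == b
    assert all(1 <= w <= 196 for w in a)


def test_waiting_time_mean_matches_uniform_expectation():
    n, avg = 10000, 196
    waits = generate_waiting_times(n, avg, seed=7)
    expected = (1 + avg) / 2
    sd = math.sqrt((avg**2 - 1) / 12)
    assert abs(np.mean(waits) - expected) <= 3 * sd / math.sqrt(n)


def test_invalid_bounds_rejected():
    with pytest.raises(ValueError):
        generate_waiting_times(-1, 10, seed=0)
    with pytest.raises(ValueError):
        generate_waiting_times(3, 0, seed=0)


@pytest.mark.parametrize(
    "name,n_hospitals,n_periods,max_wait,offices_mean",
    [("I31", 4, 10, 196, 4.5), ("I33", 4, 10, 196, 2.5),
     ("I41", 6, 20, 284, 4.5), ("I43", 6, 20, 284, 2.5)],
)
def test_sensitivity_class_structure(name, n_hospitals, n_periods, max_wait,
                                     offices_mean):
    inst = builtin_instance(name, seed=9)
    assert len(inst.hospitals) == n_hospitals
    assert inst.n_periods == n_periods
    assert all(1 <= p.waiting_days <= max_wait for p in inst.patients)
    assert sum(h.offices for h in inst.hospitals) == round(
        offices_mean * n_hospitals
    )
    assert all(2 <= m.appointments_per_period <= 8 for m in inst.doctors)
    assert all(1 <= len(m.duty_periods) <= 10 for m in inst.doctors)
    assert validate_instance(inst).ok


def test_all_builtin_classes_generate_and_validate():
    for name in builtin_class_names():
        inst = builtin_instance(name, seed=4)
        assert validate_instance(inst).ok, name


def test_generated_instances_validate_across_seeds():
    spec = ClassSpec("small", 3, 2, 60, (2, 5), (5, 20), 2.0, "heterogeneous",
                     duty_periods_range=(1, 4), appointments_per_duty_day=(1, 4))
    import dataclasses

    for seed in range(100):
        inst = generate_instance(dataclasses.replace(spec, seed=seed))
        assert validate_instance(inst).ok, seed


def test_generation_is_deterministic():
    spec = ClassSpec("det", 2, 3, 90, 4, 15, 2.0, seed=123)
    assert generate_instance(spec) == generate_instance(spec)
    assert generate_group_instance("I1", 3, seed=5) == generate_group_instance(
        "I1", 3, seed=5
    )


def test_group_published_parameters():
    assert [group_parameters("I1", i)["n_patients"] for i in range(1, 7)] == [
        639, 3017, 4202, 803, 2128, 1780
    ]
    assert [group_parameters("I2", i)["n_doctors"] for i in range(1, 7)] == [
        24, 49, 46, 23, 55, 41
    ]


def test_group_instance_encodes_stated_assumptions():
    inst = generate_group_instance("I1", 1, seed=0)
    assert inst.horizon_days == 22
    assert len(inst.hospitals) == 4
    assert len(inst.doctors) == 16
    assert len(inst.patients) == 639
    # offices equal the hospital's doctor head-count
    for h in inst.hospitals:
        assert h.offices == len(inst.doctors_at(h.id))
    # one half-day period per duty day, quota of eight
    assert all(m.appointments_per_period == 8 for m in inst.doctors)
    for m in inst.doctors:
        days = [(d + 1) // 2 for d in m.duty_periods]
        assert len(days) == len(set(days))
    # ceil(half) of each hospital's doctors on duty every day
    for h in inst.hospitals:
        docs = inst.doctors_at(h.id)
        for day in range(1, 23):
            on_duty = sum(
                1 for m in docs
                if {2 * day - 1, 2 * day} & set(m.duty_periods)
            )
            assert on_duty == math.ceil(len(docs) / 2)
    assert validate_instance(inst).ok


def test_group_scaled_overrides():
    inst = generate_group_instance("I2", 2, seed=1, n_patients=100, n_doctors=8)
    assert len(inst.patients) == 100
    assert len(inst.doctors) == 8


def test_perturb_identity_cases():
    inst = builtin_instance("I31", seed=1)
    assert perturb_offices(inst, 0.0, "even") == inst
    assert perturb_duty(inst, 0.0) == inst
    assert perturb_quota(inst, 0.0) == inst


def test_office_perturbation_hits_target_mean():
    inst = builtin_instance("I31", seed=2)
    assert sum(h.offices for h in inst.hospitals) == 18  # mean 4.5 over 4
    reduced = perturb_offices(inst, 1 - 3.5 / 4.5, "heterogeneous", seed=3)
    assert sum(h.offices for h in reduced.hospitals) == 14  # mean 3.5
    assert all(
        r.offices <= o.offices
        for r, o in zip(reduced.hospitals, inst.hospitals)
    )


def test_duty_reduction_rounds_half_up():
    inst = builtin_instance("I41", seed=6)
    ten = next(m for m in inst.doctors if len(m.duty_periods) == 10)
    reduced = perturb_duty(inst, 0.12, seed=1)
    after = next(m for m in reduced.doctors if m.id == ten.id)
    assert len(after.duty_periods) == 9  # round(1.2) = 1 dropped
    assert after.duty_periods <= ten.duty_periods


def test_quota_reduction_floors():
    inst = generate_group_instance("I1", 4, seed=0, n_patients=10)
    reduced = perturb_quota(inst, 0.20)
    assert all(m.appointments_per_period == 6 for m in reduced.doctors)  # floor(6.4)


@pytest.mark.parametrize("base", ["I31", "I42"])
def test_reducing_perturbations_never_raise_the_optimum(base):
    inst = builtin_instance(base, seed=8)
    baseline = greedy_objective(inst)
    for perturbed in (
        perturb_offices(inst, 0.3, "heterogeneous", seed=1),
        perturb_offices(inst, 0.3, "even", seed=1),
        perturb_duty(inst, 0.12, seed=1),
        perturb_quota(inst, 0.20),
    ):
        assert validate_instance(perturbed).ok
        assert greedy_objective(perturbed) <= baseline
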