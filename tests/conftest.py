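import numpy as np
import pytest

from waitsched import DoctorSpec, HospitalSpec, Instance, PatientSpec


def make_instance(hospitals, doctors, patients, horizon_days, specialty=""):
    return Instance(
        horizon_days=horizon_days,
        hospitals=tuple(HospitalSpec(h, g) for h, g in hospitals),
        doctors=tuple(
            DoctorSpec(m, nc, frozenset(works), frozenset(duty))
            for m, nc, works, duty in doctors
        ),
        patients=tuple(PatientSpec(p, wt) for p, wt in patients),
        specialty=specialty,
    )


@pytest.fixture
def toy_t1():
    """1 hospital, 1 doctor on duty in both periods of a single day,
    quota 2, 1 office, patients waiting 10/7/5/3 — capacity 4 covers all."""
    return make_instance(
        hospitals=[("H1", 1)],
        doctors=[("M1", 2, {"H1"}, {1, 2})],
        patients=[("P1", 10), ("P2", 7), ("P3", 5), ("P4", 3)],
        horizon_days=1,
    )


@pytest.fixture
def toy_t2():
    """Same as toy_t1 but quota 1: capacity 2, only the two longest waits fit."""
    return make_instance(
        hospitals=[("H1", 1)],
        doctors=[("M1", 1, {"H1"}, {1, 2})],
        patients=[("P1", 10), ("P2", 7), ("P3", 5), ("P4", 3)],
        horizon_days=1,
    )


@pytest.fixture
def two_hospital_toy():
    """Host capacity 2, support capacity 3, four patients waiting 9/8/7/6."""
    return make_instance(
        hospitals=[("H1", 1), ("H2", 1)],
        doctors=[("M1", 1, {"H1"}, {1, 2}), ("M2", 2, {"H2"}, {1, 2})],
        patients=[("P1", 9), ("P2", 8), ("P3", 7), ("P4", 6)],
        horizon_days=1,
    )


def random_single_hospital_instance(rng: np.random.Generator) -> Instance:
    """Random instance where each doctor works at exactly one hospital:
    <=3 hospitals, <=6 doctors, <=10 periods, <=30 patients."""
    n_h = int(rng.integers(1, 4))
    horizon_days = int(rng.integers(1, 6))
    n_periods = 2 * horizon_days
    n_m = int(rng.integers(1, 7))
    n_p = int(rng.integers(0, 31))
    hospitals = [(f"H{i+1}", int(rng.integers(0, 4))) for i in range(n_h)]
    doctors = []
    for j in range(n_m):
        hid = f"H{int(rng.integers(0, n_h)) + 1}"
        n_duty = int(rng.integers(0, n_periods + 1))
        duty = set(
            int(d) + 1
            for d in rng.choice(n_periods, size=n_duty, replace=False)
        )
        doctors.append((f"M{j+1}", int(rng.integers(0, 4)), {hid}, duty))
    patients = [(f"P{i+1}", int(rng.integers(1, 200))) for i in range(n_p)]
    return make_instance(hospitals, doctors, patients, horizon_days)


def random_tiny_instance(rng: np.random.Generator) -> Instance:
    """Tiny instance with arbitrary doctor-hospital contracts (doctors may
    work at several hospitals): <=2 hospitals, <=2 doctors, <=4 periods,
    <=6 patients — small enough for exhaustive enumeration."""
    n_h = int(rng.integers(1, 3))
    horizon_days = int(rng.integers(1, 3))
    n_periods = 2 * horizon_days
    n_m = int(rng.integers(1, 3))
    n_p = int(rng.integers(0, 7))
    hospitals = [(f"H{i+1}", int(rng.integers(0, 3))) for i in range(n_h)]
    doctors = []
    for j in range(n_m):
        n_works = int(rng.integers(1, n_h + 1))
        works = set(
            f"H{int(i) + 1}" for i in rng.choice(n_h, size=n_works, replace=False)
        )
        n_duty = int(rng.integers(0, n_periods + 1))
        duty = set(
            int(d) + 1 for d in rng.choice(n_periods, size=n_duty, replace=False)
        )
        doctors.append((f"M{j+1}", int(rng.integers(0, 3)), works, duty))
    patients = [(f"P{i+1}", int(rng.integers(1, 50))) for i in range(n_p)]
    return make_instance(hospitals, doctors, patients, horizon_days)
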