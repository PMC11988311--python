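"""Seeded synthetic scheduling-instance generation.

Real NHS waiting-list data publishes only aggregate figures per specialty and
hospital (list size, average wait, doctor head-counts); individual waits,
duty rosters and office counts are confidential. The generator fills those
gaps the way the study instances were built:

* appointments last 20 minutes; a half-day period therefore holds up to
  eight consultations;
* each patient's waiting time is an integer drawn uniformly between 1 day
  and the specialty's average published wait;
* doctors are partitioned round-robin across the region's hospitals (each
  doctor works at exactly one hospital, which keeps the greedy capacity
  oracle applicable);
* duty calendars and per-period quotas are drawn per class parameters.

Two families of builtin classes are provided:

* sensitivity classes ``I31/I32/I33`` (otolaryngology: 4 hospitals, 5-day
  horizon, 196-day average wait) and ``I41/I42/I43`` (ophthalmology: 6
  hospitals, 10-day horizon, 284-day average wait), with perturbation
  suffixes ``.1`` (fewer/more unevenly spread offices), ``.2`` (duty periods
  cut by 12%) and ``.3`` (per-period quotas cut by 20%);
* regional groups ``I1``/``I2`` (4 hospitals, 22-day horizon, six
  specialties each) where offices equal the hospital's doctor head-count,
  ceil(half) of a hospital's doctors are on duty each day, and each duty
  doctor offers one half-day of eight appointments.

All draws flow from a single integer seed through ``numpy`` generators, so
identical parameters and seed reproduce the instance bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .instances import DoctorSpec, HospitalSpec, Instance, PatientSpec

EVEN = "even"
HETEROGENEOUS = "heterogeneous"

APPOINTMENTS_PER_HALF_DAY = 8  # 20-minute slots in a half-day clinic


@dataclass(frozen=True)
class ClassSpec:
    """Parameter bundle describing one synthetic instance class.

    ``n_doctors``, ``n_patients`` and ``appointments_per_duty_day`` may be a
    single integer or an inclusive ``(low, high)`` range to draw from.
    Duty calendars come either from ``duty_density`` (fraction of the
    horizon's periods each doctor is on duty) or, when set, from
    ``duty_periods_range`` (inclusive range for the number of duty periods
    per doctor).
    """

    name: str
    n_hospitals: int
    horizon_days: int
    avg_wait_days: int
    n_doctors: int | tuple[int, int]
    n_patients: int | tuple[int, int]
    offices_mean: float
    offices_distribution: str = EVEN
    duty_density: float = 0.5
    duty_periods_range: tuple[int, int] | None = None
    appointments_per_duty_day: int | tuple[int, int] = APPOINTMENTS_PER_HALF_DAY
    seed: int = 0

    def validate(self) -> None:
        if self.n_hospitals < 1:
            raise ValueError("n_hospitals must be >= 1")
        if self.horizon_days < 1:
            raise ValueError("horizon_days must be >= 1")
        if self.avg_wait_days < 1:
            raise ValueError("avg_wait_days must be >= 1")
        if self.offices_mean < 0:
            raise ValueError("offices_mean must be >= 0")
        if self.offices_distribution not in (EVEN, HETEROGENEOUS):
            raise ValueError(f"unknown offices_distribution {self.offices_distribution!r}")
        if not 0 < self.duty_density <= 1:
            raise ValueError("duty_density must be in (0, 1]")


def _draw(rng: np.random.Generator, value: int | tuple[int, int]) -> int:
    if isinstance(value, tuple):
        lo, hi = value
        return int(rng.integers(lo, hi + 1))
    return int(value)


def generate_waiting_times(n: int, avg_wait_days: int, seed: int) -> list[int]:
    """``n`` integer waits, each uniform on ``{1, ..., avg_wait_days}``."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if avg_wait_days < 1:
        raise ValueError("avg_wait_days must be >= 1")
    rng = np.random.default_rng(seed)
    return [int(w) for w in rng.integers(1, avg_wait_days + 1, size=n)]


def _allocate_offices(
    n_hospitals: int, mean: float, distribution: str, rng: np.random.Generator
) -> list[int]:
    total = int(round(mean * n_hospitals))
    if distribution == EVEN:
        base, rem = divmod(total, n_hospitals)
        return [base + (1 if i < rem else 0) for i in range(n_hospitals)]
    # heterogeneous: random composition of the same total
    if total == 0:
        return [0] * n_hospitals
    probs = rng.dirichlet(np.ones(n_hospitals))
    counts = rng.multinomial(total, probs)
    return [int(c) for c in counts]


def generate_instance(spec: ClassSpec) -> Instance:
    """Generate a full instance from a class parameter bundle.

    Doctors ``M1..Mn`` are assigned round-robin to hospitals ``H1..Hk``;
    each doctor draws a duty-period count (range or density), the duty
    periods themselves, and a per-period quota; patients draw waits via
    :func:`generate_waiting_times` with a child seed.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    rng_struct, rng_wait = (np.random.default_rng(s) for s in ss.spawn(2))

    n_periods = 2 * spec.horizon_days
    n_doctors = _draw(rng_struct, spec.n_doctors)
    n_patients = _draw(rng_struct, spec.n_patients)
    if n_doctors < 1:
        raise ValueError("class yields zero doctors")

    offices = _allocate_offices(
        spec.n_hospitals, spec.offices_mean, spec.offices_distribution, rng_struct
    )
    hospitals = tuple(
        HospitalSpec(id=f"H{i + 1}", offices=offices[i])
        for i in range(spec.n_hospitals)
    )

    doctors = []
    for i in range(n_doctors):
        hid = f"H{(i % spec.n_hospitals) + 1}"
        if spec.duty_periods_range is not None:
            lo, hi = spec.duty_periods_range
            n_duty = int(rng_struct.integers(lo, min(hi, n_periods) + 1))
        else:
            n_duty = max(1, int(round(spec.duty_density * n_periods)))
        duty = rng_struct.choice(n_periods, size=min(n_duty, n_periods), replace=False) + 1
        nc = _draw(rng_struct, spec.appointments_per_duty_day)
        doctors.append(
            DoctorSpec(
                id=f"M{i + 1}",
                appointments_per_period=nc,
                works_at=frozenset({hid}),
                duty_periods=frozenset(int(d) for d in duty),
            )
        )

    wait_seed = int(rng_wait.integers(0, 2**31 - 1))
    waits = generate_waiting_times(n_patients, spec.avg_wait_days, wait_seed)
    patients = tuple(
        PatientSpec(id=f"P{i + 1}", waiting_days=waits[i]) for i in range(n_patients)
    )
    return Instance(
        horizon_days=spec.horizon_days,
        hospitals=hospitals,
        doctors=tuple(doctors),
        patients=patients,
        specialty=spec.name,
    )


# ---------------------------------------------------------------------------
# Perturbations (sensitivity analysis)

def perturb_offices(
    instance: Instance,
    mean_reduction_fraction: float,
    heterogeneity: str = EVEN,
    seed: int = 0,
) -> Instance:
    """Reduce the mean office count by the given fraction.

    The total reduction is spread over hospitals — evenly (repeatedly
    decrementing the currently best-equipped hospital) or by a seeded uneven
    split — and no hospital's count ever increases while the mean drops, so
    the optimal objective cannot increase. With a zero reduction and
    ``heterogeneous`` mode, the same total is redistributed unevenly (this
    variant can shift capacity between hospitals and is the one sensitivity
    case without a monotonicity guarantee).
    """
    if not 0 <= mean_reduction_fraction < 1:
        raise ValueError("mean_reduction_fraction must be in [0, 1)")
    if heterogeneity not in (EVEN, HETEROGENEOUS):
        raise ValueError(f"unknown heterogeneity {heterogeneity!r}")
    offices = [h.offices for h in instance.hospitals]
    total = sum(offices)
    target_total = int(round(total * (1 - mean_reduction_fraction)))
    to_remove = total - target_total
    rng = np.random.default_rng(seed)

    if to_remove == 0:
        if heterogeneity == HETEROGENEOUS and total > 0 and len(offices) > 1:
            probs = rng.dirichlet(np.ones(len(offices)))
            offices = [int(c) for c in rng.multinomial(total, probs)]
    elif heterogeneity == EVEN:
        for _ in range(to_remove):
            i = int(np.argmax(offices))
            offices[i] -= 1
    else:
        for _ in range(to_remove):
            nonzero = [i for i, g in enumerate(offices) if g > 0]
            weights = np.array([offices[i] for i in nonzero], float)
            i = int(rng.choice(nonzero, p=weights / weights.sum()))
            offices[i] -= 1

    hospitals = tuple(
        replace(h, offices=offices[i]) for i, h in enumerate(instance.hospitals)
    )
    return replace(instance, hospitals=hospitals)


def perturb_duty(
    instance: Instance, reduction_fraction: float, seed: int = 0
) -> Instance:
    """Shrink every doctor's duty set by dropping ``round(f * |duty|)``
    uniformly chosen periods (round half up)."""
    if not 0 <= reduction_fraction < 1:
        raise ValueError("reduction_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)
    doctors = []
    for m in instance.doctors:
        duty = sorted(m.duty_periods)
        k = int(math.floor(reduction_fraction * len(duty) + 0.5))
        if k > 0:
            dropped = set(
                int(d) for d in rng.choice(duty, size=k, replace=False)
            )
            duty = [d for d in duty if d not in dropped]
        doctors.append(replace(m, duty_periods=frozenset(duty)))
    return replace(instance, doctors=tuple(doctors))


def perturb_quota(instance: Instance, reduction_fraction: float) -> Instance:
    """Cut every per-period appointment quota: ``nc <- floor(nc * (1 - f))``."""
    if not 0 <= reduction_fraction < 1:
        raise ValueError("reduction_fraction must be in [0, 1)")
    doctors = tuple(
        replace(
            m,
            appointments_per_period=int(
                math.floor(m.appointments_per_period * (1 - reduction_fraction))
            ),
        )
        for m in instance.doctors
    )
    return replace(instance, doctors=doctors)


# ---------------------------------------------------------------------------
# Builtin sensitivity classes (I3 / I4)

_SENSITIVITY_CLASSES: dict[str, ClassSpec] = {
    # otolaryngology: 4 hospitals, 5-day horizon, average wait 196 days;
    # 18-22 doctors and 700-1000 patients across the three types
    "I31": ClassSpec("I31", 4, 5, 196, 18, 700, 4.5, EVEN,
                     duty_periods_range=(1, 10), appointments_per_duty_day=(2, 8)),
    "I32": ClassSpec("I32", 4, 5, 196, 22, 1000, 4.5, EVEN,
                     duty_periods_range=(1, 10), appointments_per_duty_day=(2, 8)),
    "I33": ClassSpec("I33", 4, 5, 196, 20, 850, 2.5, HETEROGENEOUS,
                     duty_periods_range=(1, 10), appointments_per_duty_day=(2, 8)),
    # ophthalmology: 6 hospitals, 10-day horizon, average wait 284 days;
    # 10-16 doctors and 1000-1400 patients across the three types
    "I41": ClassSpec("I41", 6, 10, 284, 10, 1000, 4.5, EVEN,
                     duty_periods_range=(1, 10), appointments_per_duty_day=(2, 8)),
    "I42": ClassSpec("I42", 6, 10, 284, 16, 1400, 4.5, EVEN,
                     duty_periods_range=(1, 10), appointments_per_duty_day=(2, 8)),
    "I43": ClassSpec("I43", 6, 10, 284, 13, 1200, 2.5, HETEROGENEOUS,
                     duty_periods_range=(1, 10), appointments_per_duty_day=(2, 8)),
}

# perturbation targets: offices mean 4.5 -> 3.5 for the even classes
_OFFICE_PERTURBED_MEAN = 3.5
_DUTY_REDUCTION = 0.12
_QUOTA_REDUCTION = 0.20


def builtin_class_names() -> list[str]:
    names = []
    for base in _SENSITIVITY_CLASSES:
        names.append(base)
        names.extend(f"{base}.{k}" for k in (1, 2, 3))
    return names


def builtin_instance(name: str, seed: int = 0) -> Instance:
    """Instantiate a builtin sensitivity class, e.g. ``I31`` or ``I42.3``.

    Suffix ``.1`` perturbs the office allocation (mean cut to 3.5 with a
    heterogeneous spread for the even classes; heterogeneity increased at
    constant mean for I33/I43), ``.2`` cuts duty periods by 12%, ``.3``
    cuts per-period quotas by 20%.
    """
    base, _, suffix = name.partition(".")
    if base not in _SENSITIVITY_CLASSES:
        raise KeyError(f"unknown builtin class {name!r}")
    spec = replace(_SENSITIVITY_CLASSES[base], seed=seed)
    instance = generate_instance(spec)
    if not suffix:
        return instance
    if suffix == "1":
        if spec.offices_distribution == EVEN:
            reduction = 1.0 - _OFFICE_PERTURBED_MEAN / spec.offices_mean
            out = perturb_offices(instance, reduction, HETEROGENEOUS, seed=seed + 1)
        else:
            out = perturb_offices(instance, 0.0, HETEROGENEOUS, seed=seed + 1)
    elif suffix == "2":
        out = perturb_duty(instance, _DUTY_REDUCTION, seed=seed + 1)
    elif suffix == "3":
        out = perturb_quota(instance, _QUOTA_REDUCTION)
    else:
        raise KeyError(f"unknown perturbation suffix in {name!r}")
    return replace(out, specialty=name)


# ---------------------------------------------------------------------------
# Builtin regional groups (I1 / I2): 4 hospitals, 22-day horizon, 6 specialties

_GROUP_SPECIALTIES = (
    "neurosurgery", "orthopedics", "ophthalmology",
    "pneumology", "otolaryngology", "dermato-venereology",
)

_GROUPS: dict[str, dict[str, tuple[int, ...]]] = {
    "I1": {
        "avg_wait_days": (202, 306, 242, 264, 313, 319),
        "n_doctors": (16, 25, 19, 11, 15, 4),
        "n_patients": (639, 3017, 4202, 803, 2128, 1780),
    },
    "I2": {
        "avg_wait_days": (196, 212, 285, 245, 267, 275),
        "n_doctors": (24, 49, 46, 23, 55, 41),
        "n_patients": (3534, 10886, 3738, 3738, 8304, 7090),
    },
}

GROUP_N_HOSPITALS = 4
GROUP_HORIZON_DAYS = 22


def group_parameters(group: str, specialty_index: int) -> dict[str, int]:
    """Published parameters of one group instance (``specialty_index`` is
    1-based, 1..6)."""
    if group not in _GROUPS:
        raise KeyError(f"unknown group {group!r}")
    if not 1 <= specialty_index <= 6:
        raise ValueError("specialty_index must be in 1..6")
    g = _GROUPS[group]
    i = specialty_index - 1
    return {
        "avg_wait_days": g["avg_wait_days"][i],
        "n_doctors": g["n_doctors"][i],
        "n_patients": g["n_patients"][i],
    }


def generate_group_instance(
    group: str,
    specialty_index: int,
    seed: int = 0,
    n_patients: int | None = None,
    n_doctors: int | None = None,
) -> Instance:
    """Generate one regional group instance (``I1``/``I2``, specialty 1..6).

    Construction assumptions: offices per hospital equal its doctor
    head-count; every day, ceil(half) of each hospital's doctors are on duty
    for one seeded half-day period; each duty period carries eight
    20-minute appointments. ``n_patients``/``n_doctors`` override the
    published counts for scaled-down runs; waits stay uniform on
    1..average.
    """
    params = group_parameters(group, specialty_index)
    n_doc = n_doctors if n_doctors is not None else params["n_doctors"]
    n_pat = n_patients if n_patients is not None else params["n_patients"]
    if n_doc < 1 or n_pat < 0:
        raise ValueError("doctor/patient counts out of range")

    ss = np.random.SeedSequence([seed, specialty_index, 0 if group == "I1" else 1])
    rng_struct, rng_wait = (np.random.default_rng(s) for s in ss.spawn(2))

    n_periods = 2 * GROUP_HORIZON_DAYS
    doc_hospital = [i % GROUP_N_HOSPITALS for i in range(n_doc)]
    per_hospital = [doc_hospital.count(k) for k in range(GROUP_N_HOSPITALS)]
    hospitals = tuple(
        HospitalSpec(id=f"H{k + 1}", offices=per_hospital[k])
        for k in range(GROUP_N_HOSPITALS)
    )

    duty: dict[int, set[int]] = {i: set() for i in range(n_doc)}
    by_hospital = {
        k: [i for i in range(n_doc) if doc_hospital[i] == k]
        for k in range(GROUP_N_HOSPITALS)
    }
    for day in range(1, GROUP_HORIZON_DAYS + 1):
        for k in range(GROUP_N_HOSPITALS):
            docs = by_hospital[k]
            if not docs:
                continue
            n_on_duty = math.ceil(len(docs) / 2)
            chosen = rng_struct.choice(docs, size=n_on_duty, replace=False)
            halves = rng_struct.integers(0, 2, size=n_on_duty)  # 0 morning, 1 afternoon
            for i, half in zip(chosen, halves):
                duty[int(i)].add(2 * day - 1 + int(half))

    doctors = tuple(
        DoctorSpec(
            id=f"M{i + 1}",
            appointments_per_period=APPOINTMENTS_PER_HALF_DAY,
            works_at=frozenset({f"H{doc_hospital[i] + 1}"}),
            duty_periods=frozenset(duty[i]),
        )
        for i in range(n_doc)
    )

    wait_seed = int(rng_wait.integers(0, 2**31 - 1))
    waits = generate_waiting_times(n_pat, params["avg_wait_days"], wait_seed)
    patients = tuple(
        PatientSpec(id=f"P{i + 1}", waiting_days=waits[i]) for i in range(n_pat)
    )
    return Instance(
        horizon_days=GROUP_HORIZON_DAYS,
        hospitals=hospitals,
        doctors=doctors,
        patients=patients,
        specialty=f"{group}{specialty_index} ({_GROUP_SPECIALTIES[specialty_index - 1]})",
    )
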