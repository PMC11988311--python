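"""Solver-independent ground truth for the scheduling ILP.

The scheduling model has a special structure: patients are interchangeable
given their priority weights (no patient-specific eligibility), so once the
set of active doctors is fixed the problem reduces to filling the available
appointment slots with the highest-weight patients — a pure top-K selection.

Two oracles exploit this:

* :func:`greedy_objective` — closed form for instances where every doctor
  works at exactly one hospital (the common case, and what the synthetic
  generator produces). Hospital capacities then decompose: hospital ``h``
  can activate at most ``g_h`` doctors, and activating the doctors with the
  largest individual capacities ``|duty_periods| * nc_m`` is optimal because
  slot counts simply add up.
* :func:`exhaustive_optimum` — enumeration of all doctor-activation subsets
  (any contract structure, including doctors at several hospitals), with the
  inner top-K fill; exact but only for tiny instances.

These are test oracles; production scheduling uses the ILP.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import chain, combinations

from .instances import Instance

MAX_EXHAUSTIVE_SPACE = 10**6


class UnsupportedStructureError(ValueError):
    """Raised when the greedy oracle's single-hospital premise fails."""


@dataclass(frozen=True)
class CapacityBreakdown:
    per_hospital: dict[str, int]
    total: int


def doctor_capacity(duty_periods_count: int, appointments_per_period: int) -> int:
    return duty_periods_count * appointments_per_period


def hospital_capacity(instance: Instance, hospital_id: str) -> int:
    """Achievable appointment count at one hospital: the ``g_h`` largest
    individual doctor capacities among the hospital's doctors, summed."""
    h = instance.hospital(hospital_id)
    caps = sorted(
        (
            doctor_capacity(len(m.duty_periods), m.appointments_per_period)
            for m in instance.doctors_at(hospital_id)
        ),
        reverse=True,
    )
    return sum(caps[: h.offices])


def capacity_upper_bound(instance: Instance) -> CapacityBreakdown:
    """Per-hospital achievable appointment counts under single-hospital
    doctors; raises :class:`UnsupportedStructureError` otherwise (use
    :func:`exhaustive_optimum` for general contract structures)."""
    for m in instance.doctors:
        if len(m.works_at) != 1:
            raise UnsupportedStructureError(
                f"doctor {m.id} works at {len(m.works_at)} hospitals; "
                "greedy capacity decomposition requires exactly one"
            )
    per_hospital = {
        h.id: hospital_capacity(instance, h.id) for h in instance.hospitals
    }
    return CapacityBreakdown(per_hospital=per_hospital, total=sum(per_hospital.values()))


def _top_k_weight_sum(instance: Instance, k: int) -> int:
    weights = sorted((p.waiting_days for p in instance.patients), reverse=True)
    return sum(weights[:k])


def greedy_objective(instance: Instance) -> int:
    """Optimal objective in closed form: the sum of the ``min(C, |P|)``
    largest waiting times, where ``C`` is the total achievable capacity."""
    cap = capacity_upper_bound(instance)
    return _top_k_weight_sum(instance, cap.total)


def _subsets_up_to(items: list[str], k: int):
    return chain.from_iterable(
        combinations(items, r) for r in range(min(k, len(items)) + 1)
    )


def exhaustive_optimum(instance: Instance) -> int:
    """Exact optimum by enumerating, per hospital, every subset of its
    contracted doctors of size at most ``g_h``; given the activations the
    inner problem is a top-K selection over the activated doctors' slots.

    A doctor active at several hospitals contributes their full per-period
    quota once (the quota is shared across hospitals), so total capacity is
    summed over the set of doctors active anywhere.
    """
    doctors = {m.id: m for m in instance.doctors}
    per_hospital_choices: list[list[tuple[str, ...]]] = []
    space = 1
    for h in instance.hospitals:
        ids = sorted(m.id for m in instance.doctors_at(h.id))
        choices = list(_subsets_up_to(ids, h.offices))
        per_hospital_choices.append(choices)
        space *= max(len(choices), 1)
        if space > MAX_EXHAUSTIVE_SPACE:
            raise ValueError(
                f"activation search space exceeds {MAX_EXHAUSTIVE_SPACE}; "
                "instance too large for exhaustive enumeration"
            )

    best = 0
    stack: list[tuple[int, frozenset[str]]] = [(0, frozenset())]
    while stack:
        idx, active = stack.pop()
        if idx == len(per_hospital_choices):
            cap = sum(
                doctor_capacity(
                    len(doctors[mid].duty_periods),
                    doctors[mid].appointments_per_period,
                )
                for mid in active
            )
            best = max(best, _top_k_weight_sum(instance, cap))
            continue
        for subset in per_hospital_choices[idx]:
            stack.append((idx + 1, active | frozenset(subset)))
    return best
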