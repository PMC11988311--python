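# Methods

## Problem and model

`waitsched` plans first outpatient consultations for one clinical specialty
over a short horizon of working days, each split into a morning and an
afternoon period (`|D| = 2 × horizon_days`; period `d` belongs to day
`ceil(d/2)`, odd periods are mornings). The objective maximizes the total
waiting time of the scheduled patients, which is equivalent to filling all
available slots with the longest-waiting patients first: leftover capacity
is never wasted while a longer-waiting patient is left out, and among full
plans the longest waits are served.

The ILP is stated in the README. Two readings of the printed formulation
deserve note, because both are implemented exactly as written:

* **Office cap is horizon-wide.** `Σ_m y_mh ≤ g_h` uses a single activation
  variable per doctor-hospital pair, so it caps the number of *distinct*
  doctors a hospital may activate over the whole horizon, not per period.
  The validator, the oracles and the solver all adopt this same reading, so
  the package is internally consistent.
* **Quotas are shared across hospitals.** The quota constraint sums over
  hospitals, so a doctor contracted at several hospitals may in principle
  split one period's `nc_m` consultations across sites. The synthetic
  generator assigns each doctor to exactly one hospital, so this corner only
  matters for hand-built instances; the exhaustive oracle handles it.

Variables are constructed sparsely: `x_pmdh` exists only where the doctor
works at the hospital and is on duty in the period, which enforces the
contract/duty constraints structurally (for materialized variables the
printed rows reduce to the binary bounds). The linking constraints are kept
in per-tuple form `x ≤ y`, `x ≤ z`; the aggregated big-M form would weaken
the LP relaxation.

## Solving and verification

`scipy.optimize.milp` (HiGHS branch-and-bound) solves the model. Defaults:
relative gap tolerance `1e-9` (proven optimality), time limit 600 s. The
reported objective is always recomputed in exact integer arithmetic from the
decoded assignment set, never read back from solver floating point, and
`check_solution` re-verifies every constraint on the decoded solution
independently of the solver. HiGHS has no randomized component here; the
`seed` argument is part of the call contract for backends that do.

Ties between patients with equal waits are broken by the solver; all outputs
(schedule CSVs, unscheduled lists) are then ordered deterministically by
(waiting days desc, patient id), so a given solution always prints the same
way.

`extract_schedule` adds the presentation layer the model does not decide:
within each (hospital, period) the active doctors occupy offices `1..g_h`
in doctor-id order, and each doctor's patients get consecutive 20-minute
slots (mornings from 09:00, afternoons from 14:00), longest wait first.

## Oracles

Because patients are interchangeable given their weights — any patient may
occupy any materialized slot — the optimum has a closed form once the doctor
activations are fixed: fill the `min(capacity, |P|)` slots with the largest
weights. Two oracles exploit this:

* **Greedy** (`greedy_objective`): when every doctor works at exactly one
  hospital, capacity decomposes per hospital as the sum of the `g_h` largest
  doctor capacities `|duty_periods| × nc_m`, and the optimum is the top-K
  weight sum for `K = total capacity`. The premise is checked and a
  structure error raised otherwise.
* **Exhaustive** (`exhaustive_optimum`): for arbitrary contract structures,
  enumerate per hospital every activation subset of size ≤ `g_h`; given the
  activations the inner problem is again a top-K selection (a doctor active
  at several hospitals contributes their quota once). Bounded to ~10^6
  activation combinations.

The greedy argument is not assumed: the test suite cross-checks greedy
against exhaustive on hundreds of random instances, and the ILP against both.

## Hybrid loop

`run_hybrid` schedules the host hospital first on the full waiting list,
then offers each subsequent hospital the residual list, stopping when the
list empties, the offered hospitals are exhausted, or (interactive mode)
the decision maker declines. Each stage solves a *single-hospital* ILP —
this mirrors the sequential decision process and keeps stage models small,
at the cost of not re-optimizing earlier stages (the host's schedule is, by
construction, what solving the host alone would give; tests assert this).
A stage with zero capacity, or a valid solve that adds no appointment, falls
through to the next hospital. Waitlist state lives in memory for one run;
carrying unscheduled patients into the next horizon is the caller's job.

## Synthetic generator

Only aggregate waiting-list figures are published (list size, average wait,
doctor head-counts); individual waits, rosters and office counts are
confidential. The generator fills the gaps with the field's standard
assumptions, all draws flowing from one integer seed (numpy `SeedSequence`,
bit-reproducible across platforms):

* appointments last 20 minutes; a half-day clinic holds eight;
* each patient's wait is uniform on `{1, ..., average wait}` — the sources
  state only the support and the average, and the uniform is the simplest
  distribution consistent with both;
* doctors are split round-robin across hospitals (one hospital each, so the
  greedy oracle applies to every generated instance).

Two builtin families:

* **Sensitivity classes** `I31/I32/I33` (4 hospitals, 5-day horizon,
  196-day average wait, 18–22 doctors, 700–1000 patients) and `I41/I42/I43`
  (6 hospitals, 10-day horizon, 284-day average, 10–16 doctors, 1000–1400
  patients). Office means are 4.5 evenly spread (types 1–2) or 2.5
  heterogeneous (type 3); duty-period counts are uniform on 1..10 and
  per-period quotas uniform on 2..8. Perturbation suffixes: `.1` cuts the
  office mean to 3.5 with a heterogeneous spread (types 1–2) or re-spreads
  the 2.5 mean more unevenly (type 3); `.2` drops 12% of each doctor's duty
  periods (count rounded half-up); `.3` floors quotas to 80%.
* **Regional groups** `I1`/`I2`: 4 hospitals, 22-day horizon, six
  specialties with the published per-specialty averages, doctor counts and
  list sizes (e.g. 639–4202 patients for `I1`, up to 10,886 for `I2`).
  Offices equal the hospital's doctor head-count; each day, `ceil(n/2)` of a
  hospital's `n` doctors are on duty ("at least half", read as its
  deterministic lower bound) for one seeded half-day of eight appointments.
  The round-robin split of the published doctor totals across the four
  hospitals is an assumption — the true split is not published — so
  per-instance "patients not attended at the host" percentages are
  structural illustrations, not reproductions.

Office perturbations never increase any single hospital's count while the
mean drops; this is what guarantees the perturbed optimum cannot exceed the
original (a free redistribution at a lower mean could shift offices toward a
hospital with high-capacity doctors and raise it). The one exception is the
constant-mean "more heterogeneous" variant, which necessarily moves offices
between hospitals and carries no monotonicity guarantee.

What the generator does **not** emulate: arrival of new referrals during
the horizon, specialty-dependent appointment lengths, doctor preferences or
leave, travel distance between hospitals, and any correlation between a
patient's wait and their clinical urgency. Passing tests on generated
instances therefore demonstrate the optimizer's correctness and the
approach's structural behaviour, not calibrated performance on any real
hospital's data.

## Problem sizes and test design

The test suite solves hundreds of small ILPs: 200 random instances (≤30
patients, ≤6 doctors, ≤10 periods, ≤3 hospitals) checked exactly against the
greedy oracle, 500 tiny instances (≤6 patients, ≤2 doctors, ≤4 periods, ≤2
hospitals, arbitrary contracts) against exhaustive enumeration, and regional
group runs scaled to 250 patients and a quarter of the published doctor
counts — sizes chosen so the whole suite runs in well under a minute while
still exercising oversubscription, spillover and all termination branches.
The acceptance script uses a larger host instance (~800 patients, 12
doctors, 22-day horizon) and solves it to a proven 0% gap in a few seconds.

## Known limitations

* The horizon-wide office cap means a hospital with `g_h` offices can use at
  most `g_h` distinct doctors across the whole horizon even if different
  doctors could rotate through the same office on different days; with the
  per-period reading capacity would be larger. Both the optimizer and the
  oracles apply the same reading, so comparisons are consistent.
* Sequential hybrid stages do not share a doctor's quota across hospitals;
  for the generated single-hospital-contract instances this is vacuous.
* The severity-score objective has no greedy oracle (weights are still
  interchangeable, but the variant is exercised against the exhaustive
  oracle and direct checks only).
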