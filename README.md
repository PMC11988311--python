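# waitsched

Prioritized scheduling of outpatient specialist appointments across the
pooled capacity of a region's public hospitals.

Public health systems carry long waiting lists for first specialist
consultations, and the wait a patient faces often depends on which hospital
their referral happens to land in — while a neighbouring hospital with the
same specialty has idle clinic capacity. `waitsched` is a decision-support
tool for the planner who must turn a specialty's waiting list into a
concrete appointment plan for the next few weeks: which patient sees which
doctor, on which day and half-day period, in which consulting office, and —
when the home hospital's capacity runs out — at which other hospital in the
region.

It is aimed at health-services operations researchers and hospital planning
staff; all inputs are plain JSON/CSV documents, and a seeded synthetic
generator reproduces realistic instance families so the whole pipeline runs
without any confidential patient data.

## The model

One instance covers one clinical specialty. The planning horizon has `|D| =
days × 2` half-day periods (morning/afternoon). Hospital `h` has `g_h`
consulting offices per period; doctor `m` works at the hospitals flagged in
the Boolean matrix `lt_mh`, is on duty in the periods flagged in `hm_md`,
and can hold at most `nc_m` consultations per duty period. Patient `p` has
waited `wt_p` days; the longer the wait, the higher the scheduling priority.

With binary variables `x_pmdh` (patient `p` sees doctor `m` in period `d` at
hospital `h`), `y_mh` (doctor `m` activated at hospital `h`) and `z_md`
(doctor `m` holds consultations in period `d`), the integer linear program is

```
max  Z = Σ_p Σ_m Σ_d Σ_h  wt_p · x_pmdh

s.t. Σ_m Σ_d Σ_h x_pmdh ≤ 1          ∀p        (each patient at most once)
     y_mh ≤ lt_mh,  z_md ≤ hm_md     ∀m,h,d    (contracts and duty rosters)
     Σ_h Σ_p x_pmdh ≤ nc_m           ∀m,d      (per-period quota)
     Σ_m y_mh ≤ g_h                  ∀h        (office cap)
     x_pmdh ≤ y_mh,  x_pmdh ≤ z_md   ∀p,m,d,h  (linking)
     x, y, z ∈ {0,1}
```

Maximizing total scheduled waiting days fills every available slot with the
longest-waiting patients first. An optional variant replaces `wt_p` with a
clinical severity score `Ps_p`. The solver is HiGHS branch-and-bound via
`scipy.optimize.milp`, run to proven optimality by default.

The **hybrid loop** mirrors how a planner actually works: solve the host
hospital first on the full list, then — if patients remain — offer the next
hospital in the region, re-solving on the residual list, until the list is
empty, capacity is exhausted, or the decision maker stops. Solver-independent
**oracles** (a closed-form greedy optimum and brute-force enumeration)
provide exact ground truth for testing.

## Worked example

Generate a regional instance (4 hospitals, 22-day horizon, 400 patients on
an ophthalmology-style list, 8 doctors split round-robin), run the
host-first hybrid plan, and print the report:

```
$ waitsched generate --group I1 --specialty 3 --patients 400 --doctors 8 --seed 7 -o i13.json
INFO waitsched: wrote i13.json: 4 hospitals, 8 doctors, 400 patients, 44 periods, seed 7

$ waitsched hybrid i13.json --host H1 -o out
INFO waitsched: stage H1: capacity=176 status=optimal scheduled=176
INFO waitsched: stage H2: capacity=176 status=optimal scheduled=176
INFO waitsched: stage H3: capacity=176 status=optimal scheduled=48
INFO waitsched: host unattended 56.0%, 2 support hospital(s), max gap 0%, latest appointment day 22, termination: waitlist_empty

$ waitsched report out/hybrid_report.json
specialty:              I13 (ophthalmology)
waiting list:           400
scheduled:              400
remaining:              0
host unattended (%):    56.0
support hospitals:      H2, H3
max gap (%):            0
max additional wait (d):  22
termination:            waitlist_empty
```

The host H1 can absorb 176 of the 400 patients (2 of its 2 doctors on duty
each day, one half-day of eight 20-minute slots each, over 22 days); the
56% it cannot attend spill to H2 and then H3, every stage solves to a proven
0% optimality gap, and everyone gets an appointment within the 22-day
horizon. The per-patient plan lands in `out/schedule.csv`:

```
patient_id,waiting_days,hospital_id,doctor_id,day,period,slot_time,office_number
P332,226,H1,M5,1,morning,09:00,1
P34,217,H1,M5,1,morning,09:20,1
P346,205,H1,M5,1,morning,09:40,1
```

The same objects are available as a library (`waitsched.build_model`,
`solve`, `run_hybrid`, `generate_group_instance`, ...).

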