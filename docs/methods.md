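# Methods

## The system being modeled

The simulated theater is a large university-hospital operating suite: 18
operating rooms shared by nine surgical departments (GVT, VS, GYN, CAR,
PED, OMS, NS, TS, URO). One room (R01 in the bundled layout) is reserved
for emergencies and staffed around the clock; two rooms (R02, R03) also run
through the night for very-urgent cases; 13 separate induction rooms bound
how many anesthesia inductions can run in parallel. A cyclic master surgery
schedule (MSS) assigns every room-day to one department. Regular staffed
hours are 08:30–15:45 (435 min); extended hours up to 20:00 exist only in
buffer scenarios and are never booked, only used to absorb delays.

Patients carry one of four acuity levels with different management: elective
cases are booked from a department waiting list the evening before; semi-
urgent cases (24 h target) enter the next day's program at its head and are
never treated at night; very-urgent cases (6 h target) are inserted intraday
into a room of their own specialty when possible, otherwise any insertable
room; emergencies break into the dedicated emergency room or the room that
frees earliest, regardless of specialty, and are never deferred.

## Per-case process semantics

A case consists of anesthesia induction, in-room occupation (entry to
exit; the procedure itself sits inside this interval) and cleaning. Under
sequential induction the room (and its anesthesia team) is blocked for
induction + occupation + cleaning — the "presence of anesthesiologist" is
the scheduling-relevant duration. Under parallel induction the successor's
induction may run in an induction room while the predecessor still occupies
the OR, provided a team from the extra pool is free; the OR is then blocked
only for occupation + cleaning, and day schedules are booked with
occupation-based slot lengths. The first case of a room's day has no
predecessor and never overlaps. The engine times a pre-induction so that it
is expected to finish when the room is expected to be cleaned; if the room
frees early the case waits for its induction to end, and if no team was
available the case falls back to sequential in-room induction. The idle
emergency-room team acts as one recallable backup team whenever the
dedicated emergency room is open, idle and has no inbound emergency; recall
is modeled as instantaneous (an emergency never waits for a lent team, and
an induction already underway completes).

## Synthetic input model and default calibration

No patient-level data ship with the package; every input is generated.

* **Arrivals.** Counts per window are Poisson (a negative-binomial switch
  matched to the configured SDs exists for over-dispersion; default off).
  Daytime (06:00–22:00) urgent rates per weekday by specialty: TS 4.7,
  GVT 2.4, CAR 1.8, PED 1.0, GYN 0.6, VS 1.3, NS 0.5, OMS 0.2, URO 0.1
  (total 12.6); nightly urgents 0.48 pooled across specialties (attributed
  proportionally to the daytime rates); emergencies 2.8 per day window and
  0.8 per night, every day of the week. Daytime urgents arrive on weekdays
  only (configurable); arrival instants are uniform within their window —
  only the day/night split of the counting process is constrained by the
  source rates. Urgent cases split 50/50 into semi- and very-urgent.
* **Durations.** The anchor is the table of mean elective presence times
  per (specialty, class ∈ {short, medium, long}), e.g. GVT 74/166/371 min.
  Presence is decomposed as induction = 20% and occupation = 80% of the
  class mean (configurable `induction_fraction`); both parts are log-normal
  with coefficient of variation 0.5. Cleaning is log-normal, mean 15 min,
  CV 0.3. Cardiac surgery (CAR) draws a two-component mixture factor
  (0.65× / 1.35× the class mean, weight ½/½, per-component CV 0.25) that
  preserves the class mean while producing the two density modes its
  empirical histogram shows. Emergencies multiply the mean by 1.2 and the
  CV by 1.3; urgent and emergency cases use the medium-class means of their
  specialty. Class thresholds are the terciles of the per-specialty
  elective presence mixture, computed from the closed-form mixture CDF; the
  default class mix is therefore equal thirds.
* **Weekly volume and case mix.** Weekly elective demand per department is
  Poisson, with means proportional to each department's bookable capacity
  share and scaled so that *total* expected weekly demand (electives +
  urgents + emergencies) is 345. With the arrival rates above this leaves
  253.4 electives/week — about 73.5% of all generated patients. The nominal
  72/21/7 case mix, the arrival rates, and the weekly total of 345 are
  mutually inconsistent at the 1.5-percentage-point level (the non-elective
  rates sum to 91.6/week = 26.5%, not 28%); the calibration privileges the
  weekly total, and the residual sits in the elective share. Because the
  generated elective demand exceeds bookable elective capacity under the
  default duration calibration, day schedules always fill, as intended —
  the theater operates demand-saturated.

## Scheduling and disruption rules

* Departments fill each of their rooms greedily (priority tiers semi-urgent
  → previously deferred → elective, FIFO within a tier) back-to-back from
  08:30 while the *planned* slot (expected presence + cleaning; expected
  occupation + cleaning under parallel induction) fits before 15:45. The
  first non-fitting patient stops the fill for that room and is offered to
  the department's next room. Schedules are frozen the evening before
  (18:00) and then re-sequenced: FIFO keeps the order, SF/LF sort by
  planned length ascending/descending with FIFO tie-breaks.
* At execution, a room that frees takes its next scheduled case whenever
  the current time is at or before the effective close (regular close +
  buffer hours, capped at 20:00); there is no look-ahead on the projected
  end, so a case started just before close runs into overtime. Cases still
  pending at the effective close are deferred to the head of the next day's
  elective program (semi-urgents return to the top of their tier), keeping
  their relative order. Started cases always complete. A case whose
  overlapped induction has already begun is committed and is finished the
  same day.
* Emergency break-in: the coordinator learns of an emergency 30 min before
  the patient is ready for surgery (configurable `emergency_notice_min`)
  and selects the room at notice time — the dedicated emergency room if it
  will be free by the ready time, otherwise the insertable room whose
  current commitment (realized end of the running case, cleaning included,
  plus expected lengths of already-queued insertions) ends earliest. The
  chosen room's pending scheduled cases are postponed and may cascade into
  deferrals. Elective rooms are insertable while staffed; the emergency
  room and the two night rooms are insertable around the clock. Emergency
  waiting is measured from ready-for-surgery to treatment start, clamped at
  zero; very-urgent waiting from arrival; elective/semi-urgent waiting from
  the frozen planned start of the day actually treated (a deferral resets
  the reference to the next day's plan, so deferral is counted separately,
  not as waiting).
* In buffer scenarios, a room that runs out of own work during the
  extended window takes on pending cases from any other room (earliest
  planned start first) regardless of department — a deliberate
  simplification that assumes the owning department's surgeon is available.

## Indicators

Treated cases and deferrals are normalized per week. Overtime/undertime
compare each open elective room-day's last activity end (cleaning included)
to the regular close; an empty room-day counts the full 435 min as
undertime; the dedicated emergency room is excluded from room-day
aggregates. Utilization is busy minutes over window length for the regular
(08:30–15:45) and extended (15:45–20:00) windows: room utilization counts
occupation + cleaning, system utilization adds the induction time
attributable to the room's cases (wherever the induction physically ran).
Anesthesia turnover is the mean gap from a patient's room exit to the next
patient's room entry within a room-day; single-case days contribute no
pair. Replication KPIs aggregate to means with two-sided 95% t-intervals;
policy contrasts additionally use paired-difference intervals over
common-seeded replications (common random numbers), which is what the
directional tests assert.

## Numerical and design choices

* The event core is a hand-written heap-ordered event queue (global clock
  in minutes); ties resolve by insertion order, so runs are exactly
  reproducible per (scenario, calibration, MSS, seed).
* Default run size: 30 replications × 52 post-warm-up weeks with 4 warm-up
  weeks discarded so the waiting-list state reaches its operating regime; a
  full 12-scenario battery takes a few minutes on one CPU.
* Seeds: replication *i* uses `(base_seed + i) mod 2^31`; scenarios share
  seeds for variance reduction.
* The bundled MSS assigns 17 elective room-days per weekday as GVT 3, TS 3,
  VS 2, GYN 2, CAR 2, NS 2, PED 1, OMS 1, URO 1 — more rooms for the
  departments with the largest urgent and elective volume. Any layout can
  be substituted via CSV (`weekday, room_id, department_code`), validated
  against the 18-room / one-emergency-room / two-night-room invariants.
* Degenerate inputs are honored exactly: zero CV makes every draw equal its
  mean; with zero-length inductions parallel and sequential modes produce
  identical timelines; with no disruptions the realized timeline equals the
  frozen plan to the minute (these are asserted in the test suite).

## What the synthetic model does and does not show

The generator reproduces the calibrated first moments (arrival rates,
presence means, weekly volume) and the qualitative duration shapes
(right-skew, CAR bimodality, longer and more variable emergencies). It does
not model seasonality, weekday heterogeneity beyond the day/night split,
no-shows, transport failures, staff absence, or downstream ICU/PACU/ward
blocking — so absolute throughput and deferral levels are optimistic
relative to a real theater, and passing tests certify the *mechanics and
directions* of the policy effects, not point forecasts for any specific
hospital. Two further consequences of the documented defaults are worth
knowing: with equal class thirds the mean case is long (≈182 min presence),
so the theater fits fewer, longer cases per room-day than a typical
empirical mix would give; and because elective demand saturates capacity,
booking-side capacity gains (as under parallel induction) translate almost
fully into throughput, i.e. the simulated parallel-induction gain (~20%
with one extra team) is an upper bound tied to the 20% induction-fraction
default. Emergency-waiting levels depend on crediting the 30-min notice
against waiting; the defaults land mean waits of ≈3.6 min with the
dedicated emergency room open and ≈18 min with it closed.

## Limitations

Surgeon- and staff-level rosters are out of scope (departments, not
surgeons, own the schedules); there is no intraday elective cancellation,
no weekend elective program, and no optimization-based scheduling — the
package compares rule-based policies only. The anesthesia-team backup rule
lends the emergency room's team but never its room; very-urgent cases that
cannot get a same-specialty room within their window escalate to any room
rather than violating the window silently.
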