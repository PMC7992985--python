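"""Discrete-event core: executes frozen day schedules against stochastic reality.

The engine advances a single global clock (minutes since the start of the
replication, day 0 being a Monday) through a heap-ordered event queue.  Each
day it

* generates urgent and emergency arrivals for the daytime (06:00-22:00) and
  night (22:00-06:00) windows,
* freezes the next day's department schedules the evening before,
* runs every staffed room through its schedule, inserting emergency and
  very-urgent break-ins, postponing displaced cases and deferring to the
  next day whatever no longer fits before the effective close.

Anesthesia semantics: under sequential induction a case blocks its room for
induction + occupation + cleaning.  Under parallel induction the next
scheduled patient's induction may run in one of the 13 induction rooms while
the predecessor still occupies the OR, provided an anesthesia team from the
extra pool (or the idle emergency-room team, which acts as a recallable
backup) is free; the room is then blocked only for occupation + cleaning.
The first case of a room's day never overlaps - it has no predecessor.
"""

from __future__ import annotations

import heapq
import itertools
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Deque, Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import REGULAR_CLOSE, REGULAR_OPEN, ScenarioConfig, ScenarioError
from .patient_generation import (
    ELECTIVE,
    EMERGENCY,
    SEMI_URGENT,
    SPECIALTIES,
    VERY_URGENT,
    Calibration,
    Patient,
    make_patient,
    sample_arrival_counts,
    sample_arrival_times,
    assign_urgency_split,
)
from .scheduling import (
    EMERGENCY_DEPT,
    MasterSurgerySchedule,
    RoomView,
    WaitingList,
    build_day_schedules,
    select_room_for_emergency,
)

__all__ = ["CaseRecord", "DeferralEvent", "CaseLog", "run_replication"]

MINUTES_PER_DAY = 1440.0
VERY_URGENT_WINDOW = 360.0  # six hours

# event kinds, in tie-breaking priority order of insertion sequence only
_DAY_START = "day_start"
_PLAN = "plan"
_OPEN = "open"
_CLOSE = "close"
_ROOM_FREE = "room_free"
_WAKE = "wake"
_EMERG = "emergency"
_VU = "very_urgent"
_SU = "semi_urgent"
_PREIND = "preinduction"
_PREIND_DONE = "preinduction_done"


@dataclass
class CaseRecord:
    """Realized sub-process timestamps of one treated case."""

    pid: int
    specialty: str
    acuity: str
    duration_class: str
    day: int
    room: str
    planned_start: float
    ready: float
    induction_start: float
    induction_end: float
    room_entry: float
    room_exit: float
    cleaning_end: float
    wait: float
    deferrals: int
    preinducted: bool


@dataclass
class DeferralEvent:
    day: int
    pid: int
    acuity: str
    specialty: str


@dataclass
class CaseLog:
    """Per-replication record of every treated case plus deferral events."""

    records: List[CaseRecord]
    deferral_events: List[DeferralEvent]
    scenario: ScenarioConfig
    mss: MasterSurgerySchedule
    warmup_days: int
    total_days: int
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        cols = CaseRecord.__dataclass_fields__.keys()
        return pd.DataFrame([r.__dict__ for r in self.records], columns=list(cols))

    def deferrals_dataframe(self) -> pd.DataFrame:
        cols = DeferralEvent.__dataclass_fields__.keys()
        return pd.DataFrame([d.__dict__ for d in self.deferral_events], columns=list(cols))

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


class _Room:
    __slots__ = (
        "id", "is_night", "is_er", "avail", "in_case", "sched", "insert_q",
        "dept", "open_t", "close_t", "reg_close_t",
    )

    def __init__(self, rid: str, is_night: bool, is_er: bool):
        self.id = rid
        self.is_night = is_night
        self.is_er = is_er
        self.avail = 0.0          # time the room is free and cleaned
        self.in_case = False
        self.sched: Deque[Patient] = deque()
        self.insert_q: List[Patient] = []
        self.dept: Optional[str] = None
        self.open_t = -math.inf   # absolute staffed window of the current day
        self.close_t = -math.inf
        self.reg_close_t = -math.inf

    def insert_avail(self, t: float) -> float:
        """Earliest moment a newly inserted case could start here."""
        base = max(self.avail, t)
        for q in self.insert_q:
            base = max(base, q.ready) + q.exp_chain
        return base


class _Engine:
    def __init__(
        self,
        scenario: ScenarioConfig,
        calibration: Calibration,
        mss: MasterSurgerySchedule,
        seed: int,
        elective_pool: Optional[Callable[[int], List[Patient]]] = None,
    ):
        self.scenario = scenario
        self.calib = calibration
        self.mss = mss
        self.seed = int(seed)
        self.rng = np.random.default_rng(self.seed)
        self.elective_pool = elective_pool

        self.total_days = 7 * (scenario.warmup_weeks + scenario.horizon_weeks)
        self.rooms: Dict[str, _Room] = {}
        er_id = mss.emergency_room(0)
        for rid in mss.rooms:
            self.rooms[rid] = _Room(rid, rid in mss.night_rooms, rid == er_id)
        self.er_room = self.rooms.get(er_id) if (er_id and scenario.dedicated_emergency_or) else None

        self.wl = WaitingList(mss.departments)
        self.day_plans: Dict[Tuple[int, str], List[Patient]] = {}
        self.records: List[CaseRecord] = []
        self.deferral_events: List[DeferralEvent] = []
        self.next_id = 0

        self.teams_busy = 0
        self.inductions_active = 0
        self.team_queue: Deque[Tuple[_Room, Patient]] = deque()

        dept_weights = np.array([mss.weekly_room_days(d) for d in mss.departments], dtype=float)
        self._dept_names = list(mss.departments)
        self._dept_weights = (
            dept_weights / dept_weights.sum()
            if dept_weights.sum() > 0
            else np.full(len(dept_weights), 1.0 / max(len(dept_weights), 1))
        )

        self._heap: List[Tuple[float, int, str, object]] = []
        self._seq = itertools.count()

    # -- event plumbing -----------------------------------------------------------

    def _push(self, t: float, kind: str, payload) -> None:
        heapq.heappush(self._heap, (t, next(self._seq), kind, payload))

    def run(self) -> CaseLog:
        for d in range(self.total_days):
            self._push(d * MINUTES_PER_DAY, _DAY_START, d)
            if d % 7 < 5:
                plan_at = 0.0 if d == 0 else (d - 1) * MINUTES_PER_DAY + 1080.0
                self._push(plan_at, _PLAN, d)
        end_t = self.total_days * MINUTES_PER_DAY + 2 * MINUTES_PER_DAY
        while self._heap:
            t, _, kind, payload = heapq.heappop(self._heap)
            if t > end_t:
                break
            getattr(self, "_on_" + kind)(t, payload)
        return CaseLog(
            records=self.records,
            deferral_events=self.deferral_events,
            scenario=self.scenario,
            mss=self.mss,
            warmup_days=7 * self.scenario.warmup_weeks,
            total_days=self.total_days,
            seed=self.seed,
        )

    # -- daily generation ---------------------------------------------------------

    def _new_patient(self, specialty: str, acuity: str, arrival: float, cls: str) -> Patient:
        p = make_patient(self.next_id, specialty, acuity, arrival, cls, self.calib.duration, self.rng)
        self.next_id += 1
        return p

    def _on_day_start(self, t: float, day: int) -> None:
        wd = day % 7
        arr = self.calib.arrival
        dur = self.calib.duration
        for window in ("day", "night"):
            counts = sample_arrival_counts(window, wd, arr, self.rng)
            for spec in SPECIALTIES:
                n = counts.get((spec, "urgent"), 0)
                if n == 0:
                    continue
                times = sample_arrival_times(n, window, self.rng) + day * MINUTES_PER_DAY
                for at in times:
                    acuity = assign_urgency_split(arr, self.rng)
                    p = self._new_patient(spec, acuity, float(at), dur.urgent_class)
                    p.ready = float(at)
                    self._push(float(at), _VU if acuity == VERY_URGENT else _SU, p)
            n_em = counts.get(("ANY", "emergency"), 0)
            if n_em:
                times = sample_arrival_times(n_em, window, self.rng) + day * MINUTES_PER_DAY
                specs = self.rng.choice(len(self._dept_names), size=n_em, p=self._dept_weights)
                for at, si in zip(times, specs):
                    p = self._new_patient(self._dept_names[int(si)], EMERGENCY, float(at), dur.emergency_class)
                    self._push(float(at), _EMERG, p)
        # room staffing events
        if wd < 5:
            for room in self.rooms.values():
                if room.is_er:
                    continue
                if self.mss.department_of(wd, room.id) is None:
                    continue
                self._push(day * MINUTES_PER_DAY + self.mss.regular_open, _OPEN, (room.id, day))
                self._push(day * MINUTES_PER_DAY + self.scenario.effective_close, _CLOSE, (room.id, day))

    def _on_plan(self, t: float, day: int) -> None:
        if day % 7 == 0:
            week = day // 7
            if self.elective_pool is not None:
                pool = self.elective_pool(week)
            else:
                pool = self._default_pool(week, t)
            for p in pool:
                self.wl.add_elective(p)
        schedules = build_day_schedules(self.wl, self.mss, day, self.scenario)
        for room_id, rs in schedules.items():
            self.day_plans[(day, room_id)] = [e.patient for e in rs.entries]

    def _default_pool(self, week: int, now: float) -> List[Patient]:
        from .patient_generation import generate_weekly_elective_pool

        pool = generate_weekly_elective_pool(
            self.calib, self.mss, self.rng, week, id_start=self.next_id, arrival_time=now
        )
        self.next_id += len(pool)
        return pool

    # -- room lifecycle -----------------------------------------------------------

    def _on_open(self, t: float, payload) -> None:
        room_id, day = payload
        room = self.rooms[room_id]
        room.dept = self.mss.department_of(day % 7, room_id)
        room.open_t = day * MINUTES_PER_DAY + self.mss.regular_open
        room.close_t = day * MINUTES_PER_DAY + self.scenario.effective_close
        room.reg_close_t = day * MINUTES_PER_DAY + self.mss.regular_close
        room.sched = deque(self.day_plans.pop((day, room_id), []))
        self._try_start(room, t)

    def _on_close(self, t: float, payload) -> None:
        room_id, day = payload
        room = self.rooms[room_id]
        keep: Deque[Patient] = deque()
        deferred_semis: List[Patient] = []
        while room.sched:
            p = room.sched.popleft()
            if p.pre_ind_end is not None:
                keep.append(p)  # induction already committed: finished today
            elif p.acuity == SEMI_URGENT:
                deferred_semis.append(p)
                self._record_deferral(p, day)
            else:
                self._record_deferral(p, day)
                self.wl.add_deferred(p)
        for p in reversed(deferred_semis):
            self.wl.add_semi_urgent(p, front=True)
        room.sched = keep

    def _record_deferral(self, p: Patient, day: int) -> None:
        if p.acuity == EMERGENCY:
            raise RuntimeError("emergency patients are never deferred")
        p.deferrals += 1
        p.pre_ind_start = None
        p.pre_ind_end = None
        self.deferral_events.append(DeferralEvent(day, p.id, p.acuity, p.specialty))

    # -- arrivals -----------------------------------------------------------------

    def _insertable(self, room: _Room, when: float) -> bool:
        if room.is_er:
            return self.scenario.dedicated_emergency_or
        if room.is_night:
            return True
        return room.open_t <= when <= room.close_t

    def _queue_insertion(self, room: _Room, p: Patient, t: float) -> None:
        if p.acuity == EMERGENCY:
            idx = 0
            while idx < len(room.insert_q) and room.insert_q[idx].acuity == EMERGENCY:
                idx += 1
            room.insert_q.insert(idx, p)
        else:
            room.insert_q.append(p)
        if not room.in_case:
            self._try_start(room, t)

    def _on_emergency(self, t: float, p: Patient) -> None:
        p.ready = t + self.scenario.emergency_notice_min
        views = [
            RoomView(
                room=r.id,
                insertable=self._insertable(r, p.ready),
                next_free=r.insert_avail(t),
                is_emergency_room=r.is_er,
            )
            for r in self.rooms.values()
        ]
        choice = select_room_for_emergency(views, p.ready)
        if choice is None:  # cannot happen with night rooms staffed, kept defensive
            choice = min(self.rooms.values(), key=lambda r: r.insert_avail(t)).id
        self._queue_insertion(self.rooms[choice], p, t)

    def _on_very_urgent(self, t: float, p: Patient) -> None:
        p.ready = t
        own = [
            r
            for r in self.rooms.values()
            if not r.is_er and self._insertable(r, t) and r.dept == p.specialty
        ]
        room = None
        if own:
            best = min(own, key=lambda r: (r.insert_avail(t), r.id))
            if best.insert_avail(t) <= t + VERY_URGENT_WINDOW:
                room = best
        if room is None:
            cands = [r for r in self.rooms.values() if self._insertable(r, t) and not r.is_er]
            if self.er_room is not None and not self.er_room.in_case and not self.er_room.insert_q:
                cands.append(self.er_room)  # idle emergency room may take very-urgent cases
            room = min(cands, key=lambda r: (r.insert_avail(t), r.id))
        self._queue_insertion(room, p, t)

    def _on_semi_urgent(self, t: float, p: Patient) -> None:
        # booked into the next frozen schedule at the head of the department's
        # program; never treated at night
        self.wl.add_semi_urgent(p)

    # -- case execution -----------------------------------------------------------

    def _try_start(self, room: _Room, t: float) -> None:
        if room.in_case:
            return
        now = max(t, room.avail)
        if now > t:
            return  # a room_free event is pending at room.avail
        if room.insert_q:
            p = room.insert_q[0]
            s = max(now, p.ready)
            if s > now:
                self._push(s, _WAKE, room.id)
                return
            room.insert_q.pop(0)
            self._start_case(room, p, s)
            return
        if room.sched:
            p = room.sched[0]
            if now <= room.close_t or p.pre_ind_end is not None:
                room.sched.popleft()
                self._start_case(room, p, now)
            # past close without a committed induction: the close sweep defers
            return
        self._maybe_steal(room, now)

    def _maybe_steal(self, room: _Room, now: float) -> None:
        """End-of-day buffer capacity takes on pending cases from other rooms."""
        if self.scenario.buffer_hours <= 0 or room.is_er:
            return
        if not (room.reg_close_t <= now <= room.close_t):
            return
        donors = [
            r
            for r in self.rooms.values()
            if r is not room and r.sched and r.sched[0].pre_ind_end is None
        ]
        if not donors:
            return
        donor = min(donors, key=lambda r: (r.sched[0].planned_start, r.id))
        p = donor.sched.popleft()
        self._start_case(room, p, now)

    def _on_room_free(self, t: float, room_id: str) -> None:
        room = self.rooms[room_id]
        room.in_case = False
        self._try_start(room, t)

    def _on_wake(self, t: float, room_id: str) -> None:
        self._try_start(self.rooms[room_id], t)

    def _start_case(self, room: _Room, p: Patient, s: float) -> None:
        scen = self.scenario
        preinducted = scen.parallel_induction and p.pre_ind_end is not None
        if preinducted:
            ind_s, ind_e = p.pre_ind_start, p.pre_ind_end
            entry = max(s, ind_e)
        else:
            ind_s, ind_e = s, s + p.ind
            entry = ind_e
        exit_t = entry + p.occ
        clean_e = exit_t + p.clean
        room.avail = clean_e
        room.in_case = True
        self._push(clean_e, _ROOM_FREE, room.id)

        if p.acuity == EMERGENCY:
            wait = max(0.0, s - p.ready)
        elif p.acuity == VERY_URGENT:
            wait = max(0.0, s - p.arrival)
        else:
            actual = entry if scen.parallel_induction else s
            ref = p.planned_start if not math.isnan(p.planned_start) else s
            wait = max(0.0, actual - ref)

        p.disposition = "treated"
        self.records.append(
            CaseRecord(
                pid=p.id,
                specialty=p.specialty,
                acuity=p.acuity,
                duration_class=p.duration_class,
                day=int(s // MINUTES_PER_DAY),
                room=room.id,
                planned_start=p.planned_start,
                ready=p.ready,
                induction_start=ind_s,
                induction_end=ind_e,
                room_entry=entry,
                room_exit=exit_t,
                cleaning_end=clean_e,
                wait=wait,
                deferrals=p.deferrals,
                preinducted=preinducted,
            )
        )

        # overlapped induction of the successor, timed to finish when the room
        # is expected to be cleaned
        if scen.parallel_induction and room.sched and not room.is_er:
            nxt = room.sched[0]
            if nxt.pre_ind_end is None:
                t_req = max(entry, entry + p.exp_occ + p.exp_clean - nxt.exp_ind)
                if t_req + nxt.exp_ind <= room.close_t:
                    self._push(t_req, _PREIND, (room.id, nxt))

    # -- parallel induction resourcing -------------------------------------------

    def _pool_capacity(self) -> int:
        cap = self.scenario.extra_teams
        if (
            self.er_room is not None
            and not self.er_room.in_case
            and not self.er_room.insert_q
        ):
            cap += 1  # idle emergency-room team lent as recallable backup
        return cap

    def _preind_valid(self, room: _Room, p: Patient) -> bool:
        return (
            p.pre_ind_end is None
            and p.disposition == "waiting"
            and bool(room.sched)
            and room.sched[0] is p
            and not room.insert_q
        )

    def _on_preinduction(self, t: float, payload) -> None:
        room_id, p = payload
        room = self.rooms[room_id]
        if not self._preind_valid(room, p):
            return
        self._request_team(room, p, t)

    def _request_team(self, room: _Room, p: Patient, t: float) -> None:
        if self.teams_busy < self._pool_capacity() and self.inductions_active < self.mss.induction_room_count:
            self.teams_busy += 1
            self.inductions_active += 1
            p.pre_ind_start = t
            p.pre_ind_end = t + p.ind
            self._push(p.pre_ind_end, _PREIND_DONE, (room.id, p))
        else:
            self.team_queue.append((room, p))

    def _on_preinduction_done(self, t: float, payload) -> None:
        room_id, p = payload
        room = self.rooms[room_id]
        self.teams_busy -= 1
        self.inductions_active -= 1
        while self.team_queue:
            r2, p2 = self.team_queue.popleft()
            if self._preind_valid(r2, p2):
                self._request_team(r2, p2, t)
                break
        if not room.in_case and room.sched and room.sched[0] is p:
            self._try_start(room, t)


def run_replication(
    scenario: ScenarioConfig,
    calibration: Calibration,
    mss: MasterSurgerySchedule,
    seed: int,
    elective_pool: Optional[Callable[[int], List[Patient]]] = None,
) -> CaseLog:
    """Run one seeded replication and return its case log.

    Identical (scenario, calibration, mss, seed) inputs produce identical
    logs.  ``elective_pool`` optionally replaces the synthetic weekly
    elective generator (used for deterministic toy instances in tests).
    """
    if not isinstance(scenario, ScenarioConfig):
        raise ScenarioError("scenario must be a ScenarioConfig")
    return _Engine(scenario, calibration, mss, seed, elective_pool).run()
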