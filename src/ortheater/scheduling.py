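"""Master surgery schedule, waiting list and day-schedule construction.

Departments build preliminary day schedules from a prioritized waiting list
the evening before execution.  Scheduling only books the regular opening
window (08:30-15:45); extended hours, where enabled, act purely as an
end-of-day buffer.  The OR coordinator's intraday disruption handling
(emergency break-ins, postponements, deferrals) is driven by the engine but
the individual rules live here so they can be tested in isolation.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Deque, Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .config import REGULAR_CLOSE, REGULAR_OPEN, ScenarioConfig
from .patient_generation import (
    ELECTIVE,
    EMERGENCY,
    SEMI_URGENT,
    SPECIALTIES,
    VERY_URGENT,
    Calibration,
    Patient,
)

__all__ = [
    "MSSError",
    "MasterSurgerySchedule",
    "default_mss",
    "WaitingList",
    "ScheduledCase",
    "RoomSchedule",
    "planned_slot_length",
    "build_day_schedules",
    "apply_sequencing",
    "postpone_following",
    "select_room_for_emergency",
    "RoomView",
]

EMERGENCY_DEPT = "EMERGENCY"
MINUTES_PER_DAY = 1440.0


class MSSError(ValueError):
    """Raised when a master surgery schedule violates the theater's layout."""


@dataclass
class MasterSurgerySchedule:
    """(weekday, room) -> department assignment for the cyclic week.

    The theater has 18 rooms; each weekday one of them is reserved for
    emergencies, two designated rooms additionally run through the night for
    very-urgent and emergency cases, and 13 separate induction rooms bound
    the number of concurrent parallel inductions.
    """

    assignment: Dict[Tuple[int, str], str]
    rooms: Tuple[str, ...]
    night_rooms: frozenset
    regular_open: float = REGULAR_OPEN
    regular_close: float = REGULAR_CLOSE
    induction_room_count: int = 13
    validate: bool = True

    def __post_init__(self) -> None:
        if self.validate:
            self._validate()

    def _validate(self) -> None:
        if len(self.rooms) != 18:
            raise MSSError(f"the operating theater has 18 rooms, got {len(self.rooms)}")
        if len(self.night_rooms) != 2:
            raise MSSError("exactly two rooms run through the night")
        if not self.night_rooms <= set(self.rooms):
            raise MSSError("night rooms must be among the theater's rooms")
        for wd in range(5):
            ers = [r for r in self.rooms if self.assignment.get((wd, r)) == EMERGENCY_DEPT]
            if len(ers) != 1:
                raise MSSError(f"weekday {wd} needs exactly one dedicated emergency room, got {len(ers)}")
        if self.regular_open >= self.regular_close:
            raise MSSError("regular_open must precede regular_close")

    # -- queries ------------------------------------------------------------------

    @property
    def departments(self) -> Tuple[str, ...]:
        seen = []
        for (_, _), dept in sorted(self.assignment.items()):
            if dept != EMERGENCY_DEPT and dept not in seen:
                seen.append(dept)
        return tuple(seen)

    def department_of(self, weekday: int, room: str) -> Optional[str]:
        return self.assignment.get((weekday, room))

    def emergency_room(self, weekday: int) -> Optional[str]:
        for r in self.rooms:
            if self.assignment.get((weekday, r)) == EMERGENCY_DEPT:
                return r
        return None

    def elective_rooms(self, weekday: int) -> List[str]:
        return [
            r
            for r in self.rooms
            if (weekday, r) in self.assignment and self.assignment[(weekday, r)] != EMERGENCY_DEPT
        ]

    def weekly_room_days(self, dept: str) -> int:
        return sum(1 for (_, _), d in self.assignment.items() if d == dept)

    # -- IO -----------------------------------------------------------------------

    def to_csv(self, path) -> None:
        rows = [
            {"weekday": wd, "room_id": room, "department_code": dept}
            for (wd, room), dept in sorted(self.assignment.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, night_rooms: Iterable[str] = ("R02", "R03"), **kwargs) -> "MasterSurgerySchedule":
        df = pd.read_csv(path)
        required = {"weekday", "room_id", "department_code"}
        if not required <= set(df.columns):
            raise MSSError(f"MSS file needs columns {sorted(required)}")
        assignment = {
            (int(r.weekday), str(r.room_id)): str(r.department_code) for r in df.itertuples()
        }
        rooms = tuple(sorted({room for (_, room) in assignment}))
        return cls(assignment=assignment, rooms=rooms, night_rooms=frozenset(night_rooms), **kwargs)


#: Elective room counts per weekday in the default layout; departments with
#: high urgent and elective volume receive more room-days.
_DEFAULT_ROOM_COUNTS = (
    ("GVT", 3), ("TS", 3), ("VS", 2), ("GYN", 2), ("CAR", 2),
    ("NS", 2), ("PED", 1), ("OMS", 1), ("URO", 1),
)


def default_mss() -> MasterSurgerySchedule:
    """The bundled 18-room x 5-weekday layout: R01 is the dedicated emergency
    room every day; R02/R03 are the night rooms; the remaining 17 rooms are
    split among the nine departments in the same way each weekday."""
    rooms = tuple(f"R{i:02d}" for i in range(1, 19))
    depts: List[str] = []
    for dept, n in _DEFAULT_ROOM_COUNTS:
        depts.extend([dept] * n)
    assignment: Dict[Tuple[int, str], str] = {}
    for wd in range(5):
        assignment[(wd, "R01")] = EMERGENCY_DEPT
        for room, dept in zip(rooms[1:], depts):
            assignment[(wd, room)] = dept
    return MasterSurgerySchedule(
        assignment=assignment, rooms=rooms, night_rooms=frozenset({"R02", "R03"})
    )


# --- waiting list -----------------------------------------------------------------


class WaitingList:
    """Department-pooled waiting list with three priority tiers.

    Booking order within a department is semi-urgent patients first (their
    24-hour window dominates), then previously deferred patients, then fresh
    electives; each tier is FIFO so deferred patients keep their relative
    order.
    """

    def __init__(self, departments: Iterable[str]):
        self.tiers: Dict[str, Dict[str, Deque[Patient]]] = {
            d: {"semi": deque(), "deferred": deque(), "elective": deque()} for d in departments
        }

    def _dept(self, dept: str) -> Dict[str, Deque[Patient]]:
        if dept not in self.tiers:
            self.tiers[dept] = {"semi": deque(), "deferred": deque(), "elective": deque()}
        return self.tiers[dept]

    def add_semi_urgent(self, p: Patient, front: bool = False) -> None:
        q = self._dept(p.specialty)["semi"]
        q.appendleft(p) if front else q.append(p)

    def add_deferred(self, p: Patient) -> None:
        self._dept(p.specialty)["deferred"].append(p)

    def add_elective(self, p: Patient) -> None:
        self._dept(p.specialty)["elective"].append(p)

    def booking_order(self, dept: str) -> Iterable[Deque[Patient]]:
        t = self._dept(dept)
        return (t["semi"], t["deferred"], t["elective"])

    def size(self, dept: Optional[str] = None) -> int:
        depts = [dept] if dept else list(self.tiers)
        return sum(len(q) for d in depts for q in self.tiers[d].values())


# --- day schedules ----------------------------------------------------------------


@dataclass
class ScheduledCase:
    patient: Patient
    planned_start: float
    planned_len: float


@dataclass
class RoomSchedule:
    room: str
    day: int
    entries: List[ScheduledCase] = field(default_factory=list)

    def recompute_starts(self, open_abs: float) -> None:
        cursor = open_abs
        for e in self.entries:
            e.planned_start = cursor
            e.patient.planned_start = cursor
            cursor += e.planned_len


def planned_slot_length(patient: Patient, scenario: ScenarioConfig) -> float:
    """Planned bookable length of one case.

    Sequential induction blocks the room for the full presence-of-
    anesthesiologist duration, so the slot is expected presence plus expected
    cleaning.  Under parallel induction the room is only blocked for the
    in-room occupation, so slots shrink to expected occupation plus cleaning
    and more cases fit into the same regular window.
    """
    if patient.duration_class not in ("short", "medium", "long"):
        raise ValueError(f"unknown duration class {patient.duration_class!r}")
    if scenario.parallel_induction:
        return patient.exp_occ + patient.exp_clean
    return patient.exp_presence + patient.exp_clean


def build_day_schedules(
    waiting_list: WaitingList,
    mss: MasterSurgerySchedule,
    day: int,
    scenario: ScenarioConfig,
) -> Dict[str, RoomSchedule]:
    """Greedy preliminary schedules for one execution day.

    For every room of the day's MSS, patients of the room's department are
    appended in priority-then-FIFO order while their cumulative planned
    length fits inside the regular window; the first patient that does not
    fit stops the fill for that room (it is offered to the department's next
    room, if any).  Schedules are then re-sequenced per policy and frozen.
    """
    weekday = day % 7
    if weekday >= 5:
        return {}
    open_abs = day * MINUTES_PER_DAY + mss.regular_open
    close_abs = day * MINUTES_PER_DAY + mss.regular_close
    schedules: Dict[str, RoomSchedule] = {}
    for room in mss.elective_rooms(weekday):
        dept = mss.department_of(weekday, room)
        rs = RoomSchedule(room=room, day=day)
        cursor = open_abs
        for tier in waiting_list.booking_order(dept):
            stopped = False
            while tier:
                p = tier[0]
                length = planned_slot_length(p, scenario)
                if cursor + length > close_abs:
                    stopped = True
                    break
                tier.popleft()
                p.slot_len = length
                p.planned_start = cursor
                rs.entries.append(ScheduledCase(p, cursor, length))
                cursor += length
            if stopped:
                break
        schedules[room] = apply_sequencing(rs, scenario.sequencing, open_abs)
    return schedules


def apply_sequencing(schedule: RoomSchedule, policy: str, open_abs: Optional[float] = None) -> RoomSchedule:
    """Re-sequence a built schedule: FIFO keeps it, SF sorts planned lengths
    ascending, LF descending; ties keep the original FIFO position.  Planned
    starts are recomputed back-to-back from the room's opening time."""
    if policy not in ("FIFO", "SF", "LF"):
        raise ValueError(f"unknown sequencing policy {policy!r}")
    if open_abs is None:
        open_abs = schedule.entries[0].planned_start if schedule.entries else 0.0
    if policy == "SF":
        schedule.entries.sort(key=lambda e: e.planned_len)  # stable: FIFO tie-break
    elif policy == "LF":
        schedule.entries.sort(key=lambda e: -e.planned_len)
    schedule.recompute_starts(open_abs)
    return schedule


def postpone_following(
    schedule: RoomSchedule, insertion_start: float, insertion_duration: float
) -> RoomSchedule:
    """Shift planned cases after an emergency break-in.

    Every not-yet-started entry (planned start at or after the insertion
    moment) moves back by the insertion's realized length; entries already
    finished are untouched.  The patients' frozen planned starts are kept as
    the reference for intraday waiting - postponement is exactly what the
    waiting-time indicator measures."""
    for e in schedule.entries:
        if e.planned_start >= insertion_start:
            e.planned_start += insertion_duration
    return schedule


# --- emergency room selection -----------------------------------------------------


@dataclass
class RoomView:
    """Minimal snapshot the coordinator needs for break-in decisions."""

    room: str
    insertable: bool
    next_free: float  # earliest time a newly inserted case could begin
    is_emergency_room: bool = False


def select_room_for_emergency(views: Sequence[RoomView], ready: float) -> Optional[str]:
    """Pick the room for an incoming emergency.

    The dedicated emergency room takes the case whenever it will be free by
    the patient's ready time; otherwise the case goes to the insertable room
    that frees earliest (idle rooms count as free now).  Pending elective
    cases of the chosen room are postponed by the engine."""
    candidates = [v for v in views if v.insertable]
    if not candidates:
        return None
    for v in candidates:
        if v.is_emergency_room and v.next_free <= ready:
            return v.room
    best = min(candidates, key=lambda v: (max(v.next_free, ready), v.room))
    return best.room
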