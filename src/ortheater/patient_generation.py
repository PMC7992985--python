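"""Synthetic patient streams and case-duration sampling.

The operating theater studied here serves nine surgical departments in a
large university hospital.  No patient-level dataset is available, so every
input to the simulation is generated from a compact calibration:

* urgent arrivals per specialty per weekday daytime window (06:00-22:00),
  plus a pooled nightly urgent rate,
* emergency arrivals day/night, independent of specialty,
* right-skewed per-specialty surgery durations anchored on the published
  short/medium/long mean "presence of anesthesiologist" times of elective
  patients (log-normal components; a two-component mixture for cardiac
  surgery, whose empirical duration histogram is bimodal),
* a 72/21/7 elective/urgent/emergency case mix with total weekly surgical
  demand calibrated to ~345 cases.

All times are minutes.  Within a day, minute 0 is midnight; the daytime
window is [360, 1320) and the night window [1320, 1800) (22:00 to 06:00 of
the next day).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

__all__ = [
    "SPECIALTIES",
    "ACUITIES",
    "CLASSES",
    "DAY_WINDOW",
    "NIGHT_WINDOW",
    "CalibrationError",
    "ArrivalModel",
    "DurationModel",
    "Calibration",
    "Patient",
    "default_calibration",
    "load_calibration",
    "sample_arrival_counts",
    "sample_arrival_times",
    "assign_urgency_split",
    "sample_case_durations",
    "classify_duration_class",
    "generate_weekly_elective_pool",
    "sample_weekly_demand",
]

SPECIALTIES: Tuple[str, ...] = ("GVT", "VS", "GYN", "CAR", "PED", "OMS", "NS", "TS", "URO")

ELECTIVE = "elective"
SEMI_URGENT = "semi_urgent"
VERY_URGENT = "very_urgent"
EMERGENCY = "emergency"
ACUITIES: Tuple[str, ...] = (ELECTIVE, SEMI_URGENT, VERY_URGENT, EMERGENCY)

SHORT, MEDIUM, LONG = "short", "medium", "long"
CLASSES: Tuple[str, ...] = (SHORT, MEDIUM, LONG)

#: Daytime window 06:00-22:00 and night window 22:00-06:00, minutes from midnight.
DAY_WINDOW: Tuple[float, float] = (360.0, 1320.0)
NIGHT_WINDOW: Tuple[float, float] = (1320.0, 1800.0)

MINUTES_PER_DAY = 1440.0
MINUTES_PER_WEEK = 7 * MINUTES_PER_DAY

# --- default calibration constants ------------------------------------------------

#: Mean daytime urgent arrivals per weekday, by specialty.
URGENT_DAY_MEAN: Dict[str, float] = {
    "TS": 4.7, "GVT": 2.4, "CAR": 1.8, "GYN": 0.6, "VS": 1.3,
    "NS": 0.5, "PED": 1.0, "URO": 0.1, "OMS": 0.2,
}
#: Empirical standard deviations of the daytime urgent counts (used by the
#: optional negative-binomial arrival family).
URGENT_DAY_SD: Dict[str, float] = {
    "TS": 2.3, "GVT": 1.4, "CAR": 1.5, "GYN": 0.8, "VS": 1.2,
    "NS": 0.7, "PED": 1.0, "URO": 0.4, "OMS": 0.5,
}
URGENT_NIGHT_TOTAL_MEAN = 0.48
EMERGENCY_DAY_MEAN, EMERGENCY_DAY_SD = 2.8, 1.9
EMERGENCY_NIGHT_MEAN, EMERGENCY_NIGHT_SD = 0.8, 1.1

#: Mean elective "presence of anesthesiologist" durations (minutes) by
#: specialty and forecast duration class (short, medium, long).
PRESENCE_MEANS: Dict[str, Tuple[float, float, float]] = {
    "GVT": (74.0, 166.0, 371.0),
    "VS": (46.0, 135.0, 334.0),
    "GYN": (44.0, 101.0, 322.0),
    "CAR": (63.0, 204.0, 324.0),
    "PED": (40.0, 97.0, 256.0),
    "OMS": (55.0, 137.0, 307.0),
    "NS": (81.0, 194.0, 406.0),
    "TS": (63.0, 134.0, 288.0),
    "URO": (94.0, 210.0, 375.0),
}

WEEKLY_VOLUME_TARGET = 345.0


class CalibrationError(ValueError):
    """Raised for inconsistent calibration input (negative rates, bad thresholds...)."""


# --- arrival model ----------------------------------------------------------------


@dataclass
class ArrivalModel:
    """Counting processes for urgent and emergency arrivals.

    Counts per window are Poisson by default; ``family="negbin"`` switches to a
    negative binomial matched to the configured standard deviations (used to
    represent the over-dispersion visible in the empirical emergency counts).
    """

    urgent_day_rate: Dict[str, float] = field(default_factory=lambda: dict(URGENT_DAY_MEAN))
    urgent_day_sd: Dict[str, float] = field(default_factory=lambda: dict(URGENT_DAY_SD))
    urgent_night_rate_total: float = URGENT_NIGHT_TOTAL_MEAN
    emergency_day_rate: float = EMERGENCY_DAY_MEAN
    emergency_day_sd: float = EMERGENCY_DAY_SD
    emergency_night_rate: float = EMERGENCY_NIGHT_MEAN
    emergency_night_sd: float = EMERGENCY_NIGHT_SD
    very_urgent_fraction: float = 0.5
    family: str = "poisson"
    weekend_daytime_urgents: bool = False

    def __post_init__(self) -> None:
        for spec, r in self.urgent_day_rate.items():
            if r < 0:
                raise CalibrationError(f"negative urgent rate for {spec}: {r}")
        for r in (self.urgent_night_rate_total, self.emergency_day_rate, self.emergency_night_rate):
            if r < 0:
                raise CalibrationError(f"negative arrival rate: {r}")
        if not 0.0 <= self.very_urgent_fraction <= 1.0:
            raise CalibrationError(f"very_urgent_fraction must be in [0,1]: {self.very_urgent_fraction}")
        if self.family not in ("poisson", "negbin"):
            raise CalibrationError(f"unknown arrival family: {self.family}")

    def _draw(self, rng: np.random.Generator, mean: float, sd: float, size=None):
        if mean <= 0:
            return 0 if size is None else np.zeros(size, dtype=np.int64)
        if self.family == "negbin" and sd * sd > mean:
            # mean = r(1-p)/p, var = r(1-p)/p^2
            p = mean / (sd * sd)
            r = mean * p / (1.0 - p)
            return rng.negative_binomial(r, p, size)
        return rng.poisson(mean, size)


def sample_arrival_counts(
    window: str, weekday: int, model: ArrivalModel, rng: np.random.Generator
) -> Dict[Tuple[str, str], int]:
    """Draw one window's arrival counts.

    Returns a mapping ``(specialty, "urgent") -> count`` for urgent patients
    (drawn per specialty, daytime on weekdays only unless configured
    otherwise) and ``("ANY", "emergency") -> count`` for emergencies, which
    are specialty-agnostic: they go to the next available room regardless of
    the room's department.
    """
    if window not in ("day", "night"):
        raise ValueError(f"window must be 'day' or 'night': {window}")
    counts: Dict[Tuple[str, str], int] = {}
    if window == "day":
        urgent_active = weekday < 5 or model.weekend_daytime_urgents
        for spec in SPECIALTIES:
            rate = model.urgent_day_rate.get(spec, 0.0) if urgent_active else 0.0
            sd = model.urgent_day_sd.get(spec, 0.0)
            counts[(spec, "urgent")] = int(model._draw(rng, rate, sd)) if rate > 0 else 0
        counts[("ANY", "emergency")] = int(
            model._draw(rng, model.emergency_day_rate, model.emergency_day_sd)
        )
    else:
        # Nightly urgents are pooled; attribute them to specialties in
        # proportion to the daytime rates when individual patients are built.
        total = int(model._draw(rng, model.urgent_night_rate_total, 0.0))
        for spec in SPECIALTIES:
            counts[(spec, "urgent")] = 0
        if total > 0:
            weights = np.array([model.urgent_day_rate.get(s, 0.0) for s in SPECIALTIES])
            weights = weights / weights.sum() if weights.sum() > 0 else np.full(len(SPECIALTIES), 1 / len(SPECIALTIES))
            picks = rng.choice(len(SPECIALTIES), size=total, p=weights)
            for i in picks:
                counts[(SPECIALTIES[i], "urgent")] += 1
        counts[("ANY", "emergency")] = int(
            model._draw(rng, model.emergency_night_rate, model.emergency_night_sd)
        )
    return counts


def sample_arrival_times(count: int, window: str, rng: np.random.Generator) -> np.ndarray:
    """Place ``count`` arrivals uniformly inside the window, sorted ascending.

    Times are minutes from the owning day's midnight; night times may exceed
    1440 (the night window runs into the following morning).
    """
    if count < 0:
        raise ValueError("count must be >= 0")
    lo, hi = DAY_WINDOW if window == "day" else NIGHT_WINDOW
    if window not in ("day", "night"):
        raise ValueError(f"window must be 'day' or 'night': {window}")
    return np.sort(rng.uniform(lo, hi, size=count))


def assign_urgency_split(model: ArrivalModel, rng: np.random.Generator) -> str:
    """Split a generic urgent case into semi-urgent (24 h) or very-urgent (6 h)."""
    return VERY_URGENT if rng.random() < model.very_urgent_fraction else SEMI_URGENT


# --- duration model ---------------------------------------------------------------


@dataclass
class DurationModel:
    """Per-specialty, per-acuity surgery duration sampling.

    The anchor is the table of elective presence-of-anesthesiologist means per
    (specialty, class).  Presence is decomposed into an induction component
    (``induction_fraction`` of the mean) and an in-room occupation component
    (the rest); both are log-normal with coefficient of variation ``cv``.
    Cardiac surgery (CAR) draws a mixture factor first, producing the bimodal
    shape of its empirical histogram while preserving the class mean.
    Emergencies are longer and more variable than electives; urgent cases use
    the medium-class means of their specialty.
    """

    presence_means: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(PRESENCE_MEANS)
    )
    induction_fraction: float = 0.2
    cv: float = 0.5
    cleaning_mean: float = 15.0
    cleaning_cv: float = 0.3
    emergency_mean_factor: float = 1.2
    emergency_cv_factor: float = 1.3
    urgent_class: str = MEDIUM
    emergency_class: str = MEDIUM
    car_mixture_spread: float = 0.35
    car_mixture_weight: float = 0.5
    car_component_cv: float = 0.25
    class_probs: Tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    class_threshold_override: Optional[Dict[str, Tuple[float, float]]] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.induction_fraction < 1.0:
            raise CalibrationError("induction_fraction must be in (0,1)")
        if self.cv < 0 or self.cleaning_cv < 0:
            raise CalibrationError("coefficients of variation must be >= 0")
        for spec, means in self.presence_means.items():
            if not means[0] < means[1] < means[2]:
                raise CalibrationError(f"class means must increase for {spec}: {means}")
        if abs(sum(self.class_probs) - 1.0) > 1e-9 or any(p < 0 for p in self.class_probs):
            raise CalibrationError("class_probs must be a probability vector")
        if self.class_threshold_override:
            for spec, (t1, t2) in self.class_threshold_override.items():
                if t1 >= t2:
                    raise CalibrationError(f"class thresholds must satisfy t1 < t2 for {spec}")
        self._threshold_cache: Dict[str, Tuple[float, float]] = {}

    # -- means --------------------------------------------------------------------

    def presence_mean(self, specialty: str, duration_class: str) -> float:
        try:
            means = self.presence_means[specialty]
        except KeyError as exc:
            raise CalibrationError(f"no duration calibration for specialty {specialty!r}") from exc
        return means[CLASSES.index(duration_class)]

    def expected_parts(
        self, specialty: str, acuity: str, duration_class: str
    ) -> Tuple[float, float, float]:
        """Expected (induction, occupation, cleaning) means in minutes."""
        m = self.presence_mean(specialty, duration_class)
        if acuity == EMERGENCY:
            m *= self.emergency_mean_factor
        return (
            self.induction_fraction * m,
            (1.0 - self.induction_fraction) * m,
            self.cleaning_mean,
        )

    # -- class thresholds ---------------------------------------------------------

    def class_thresholds(self, specialty: str) -> Tuple[float, float]:
        """Terciles of the specialty's elective presence distribution.

        Computed once per specialty from the closed-form CDF of the
        equal-weight log-normal class mixture and cached.
        """
        if self.class_threshold_override and specialty in self.class_threshold_override:
            return self.class_threshold_override[specialty]
        if specialty in self._threshold_cache:
            return self._threshold_cache[specialty]
        means = self.presence_means.get(specialty)
        if means is None:
            raise CalibrationError(f"no duration calibration for specialty {specialty!r}")
        probs = np.asarray(self.class_probs)
        cv = max(self.cv, 1e-6)
        sigma = math.sqrt(math.log1p(cv * cv))
        scales = [m * math.exp(-sigma * sigma / 2.0) for m in means]

        def mix_cdf(x: float) -> float:
            return float(sum(p * stats.lognorm.cdf(x, sigma, scale=s) for p, s in zip(probs, scales)))

        hi = means[2] * 20.0
        t1 = optimize.brentq(lambda x: mix_cdf(x) - 1 / 3, 1e-6, hi)
        t2 = optimize.brentq(lambda x: mix_cdf(x) - 2 / 3, 1e-6, hi)
        self._threshold_cache[specialty] = (t1, t2)
        return (t1, t2)


def _lognormal(rng: np.random.Generator, mean: float, cv: float, size=None):
    """Log-normal sample(s) with the requested mean and coefficient of variation."""
    if mean <= 0:
        raise CalibrationError(f"duration mean must be positive: {mean}")
    if cv <= 0:
        return mean if size is None else np.full(size, mean)
    s2 = math.log1p(cv * cv)
    mu = math.log(mean) - s2 / 2.0
    return rng.lognormal(mu, math.sqrt(s2), size)


def sample_case_durations(
    specialty: str,
    acuity: str,
    duration_class: str,
    model: DurationModel,
    rng: np.random.Generator,
) -> Tuple[float, float, float]:
    """Sample (induction, occupation, cleaning) minutes for one case.

    Induction plus occupation has the configured presence mean for the
    (specialty, class); cardiac cases draw a symmetric two-component mixture
    factor first, which preserves the mean but yields two modes.
    """
    m = model.presence_mean(specialty, duration_class)
    cv = model.cv
    if acuity == EMERGENCY:
        m *= model.emergency_mean_factor
        cv *= model.emergency_cv_factor
    if specialty == "CAR" and model.car_mixture_spread > 0:
        # two components symmetric about the class mean; the narrower
        # per-component dispersion keeps the two modes visible
        if rng.random() < model.car_mixture_weight:
            m *= 1.0 - model.car_mixture_spread
        else:
            m *= 1.0 + model.car_mixture_spread
        cv = model.car_component_cv * (model.emergency_cv_factor if acuity == EMERGENCY else 1.0)
    ind = float(_lognormal(rng, model.induction_fraction * m, cv))
    occ = float(_lognormal(rng, (1.0 - model.induction_fraction) * m, cv))
    clean = float(_lognormal(rng, model.cleaning_mean, model.cleaning_cv))
    return ind, occ, clean


def classify_duration_class(specialty: str, planned_duration: float, model: DurationModel) -> str:
    """Map a forecast presence duration onto short/medium/long.

    The boundary is inclusive on the left: a duration exactly at a threshold
    belongs to the shorter class.
    """
    t1, t2 = model.class_thresholds(specialty)
    if t1 >= t2:
        raise CalibrationError(f"class thresholds must satisfy t1 < t2 for {specialty}")
    if planned_duration <= t1:
        return SHORT
    if planned_duration <= t2:
        return MEDIUM
    return LONG


# --- patients ---------------------------------------------------------------------


@dataclass
class Patient:
    """One surgical case flowing through the theater."""

    id: int
    specialty: str
    acuity: str
    arrival: float  # absolute minutes since simulation start
    duration_class: str
    # realized durations (minutes)
    ind: float = 0.0
    occ: float = 0.0
    clean: float = 0.0
    # expectations used by the scheduler (the planner never sees realizations)
    exp_ind: float = 0.0
    exp_occ: float = 0.0
    exp_clean: float = 0.0
    # engine bookkeeping
    slot_len: float = 0.0
    planned_start: float = math.nan
    ready: float = math.nan
    deferrals: int = 0
    disposition: str = "waiting"
    pre_ind_start: Optional[float] = None
    pre_ind_end: Optional[float] = None

    @property
    def exp_presence(self) -> float:
        return self.exp_ind + self.exp_occ

    @property
    def exp_chain(self) -> float:
        """Expected sequential room blocking: induction + occupation + cleaning."""
        return self.exp_ind + self.exp_occ + self.exp_clean


def make_patient(
    pid: int,
    specialty: str,
    acuity: str,
    arrival: float,
    duration_class: str,
    duration_model: DurationModel,
    rng: np.random.Generator,
) -> Patient:
    """Build a patient with sampled realizations and planner expectations."""
    ind, occ, clean = sample_case_durations(specialty, acuity, duration_class, duration_model, rng)
    e_ind, e_occ, e_clean = duration_model.expected_parts(specialty, acuity, duration_class)
    return Patient(
        id=pid,
        specialty=specialty,
        acuity=acuity,
        arrival=arrival,
        duration_class=duration_class,
        ind=ind,
        occ=occ,
        clean=clean,
        exp_ind=e_ind,
        exp_occ=e_occ,
        exp_clean=e_clean,
    )


# --- calibration bundle -----------------------------------------------------------


@dataclass
class Calibration:
    """Everything the generator needs, bundled for configuration files."""

    arrival: ArrivalModel = field(default_factory=ArrivalModel)
    duration: DurationModel = field(default_factory=DurationModel)
    weekly_volume_target: float = WEEKLY_VOLUME_TARGET
    #: Optional explicit weekly elective department means; if None they are
    #: derived from the weekly volume target and the MSS capacity shares.
    dept_elective_means: Optional[Dict[str, float]] = None

    @property
    def expected_urgent_per_week(self) -> float:
        days = 7 if self.arrival.weekend_daytime_urgents else 5
        return days * sum(self.arrival.urgent_day_rate.values()) + 7 * self.arrival.urgent_night_rate_total

    @property
    def expected_emergency_per_week(self) -> float:
        return 7 * (self.arrival.emergency_day_rate + self.arrival.emergency_night_rate)

    @property
    def elective_weekly_mean(self) -> float:
        """Weekly elective demand making total expected demand hit the target."""
        m = self.weekly_volume_target - self.expected_urgent_per_week - self.expected_emergency_per_week
        if m <= 0:
            raise CalibrationError("weekly volume target leaves no room for electives")
        return m

    def elective_means_for(self, mss) -> Dict[str, float]:
        """Per-department weekly elective means, proportional to bookable capacity.

        Capacity share of a department is its weekly room-minutes divided by
        its mean elective slot length, so departments with many rooms and/or
        short cases receive proportionally more elective demand.
        """
        if self.dept_elective_means is not None:
            return dict(self.dept_elective_means)
        window = mss.regular_close - mss.regular_open
        cases: Dict[str, float] = {}
        for dept in mss.departments:
            room_days = mss.weekly_room_days(dept)
            mean_presence = float(np.mean(self.duration.presence_means[dept]))
            slot = mean_presence + self.duration.cleaning_mean
            cases[dept] = room_days * window / slot
        total = sum(cases.values())
        target = self.elective_weekly_mean
        return {d: target * c / total for d, c in cases.items()}

    @classmethod
    def from_dict(cls, data: Mapping) -> "Calibration":
        arr = dict(data.get("arrival", {}))
        dur = dict(data.get("duration", {}))
        if "presence_means" in dur:
            dur["presence_means"] = {k: tuple(v) for k, v in dur["presence_means"].items()}
        if "class_threshold_override" in dur and dur["class_threshold_override"] is not None:
            dur["class_threshold_override"] = {
                k: tuple(v) for k, v in dur["class_threshold_override"].items()
            }
        if "urgent_day_rate" in arr:
            arr["urgent_day_rate"] = dict(arr["urgent_day_rate"])
        return cls(
            arrival=ArrivalModel(**arr),
            duration=DurationModel(**dur),
            weekly_volume_target=data.get("weekly_volume_target", WEEKLY_VOLUME_TARGET),
            dept_elective_means=data.get("dept_elective_means"),
        )


def default_calibration() -> Calibration:
    return Calibration()


def load_calibration(path) -> Calibration:
    """Read a YAML calibration file (missing keys fall back to defaults)."""
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return Calibration.from_dict(data)


# --- weekly generation ------------------------------------------------------------


def generate_weekly_elective_pool(
    calibration: Calibration,
    mss,
    rng: np.random.Generator,
    week: int,
    id_start: int = 0,
    arrival_time: Optional[float] = None,
) -> List[Patient]:
    """Generate one week's elective referrals for every department.

    Department counts are Poisson around the calibrated weekly means; classes
    are drawn from the configured class mix (equal thirds by default, matching
    tercile-based forecast classes).  Patients enter the waiting list in
    generation order, which defines their FIFO position.
    """
    means = calibration.elective_means_for(mss)
    at = week * MINUTES_PER_WEEK if arrival_time is None else arrival_time
    pool: List[Patient] = []
    pid = id_start
    for dept in mss.departments:
        n = int(rng.poisson(means[dept]))
        if n == 0:
            continue
        classes = rng.choice(3, size=n, p=np.asarray(calibration.duration.class_probs))
        for k in range(n):
            pool.append(
                make_patient(pid, dept, ELECTIVE, at, CLASSES[int(classes[k])], calibration.duration, rng)
            )
            pid += 1
    return pool


def sample_weekly_demand(
    calibration: Calibration, rng: np.random.Generator, weeks: int
) -> Dict[str, np.ndarray]:
    """Draw total weekly surgical demand counts for ``weeks`` weeks.

    Returns per-week arrays of elective, urgent and emergency counts; used for
    calibration checks (case-mix fractions and total weekly volume).
    """
    arr = calibration.arrival
    electives = rng.poisson(calibration.elective_weekly_mean, size=weeks)
    urgent_day_days = 7 if arr.weekend_daytime_urgents else 5
    urgents = np.zeros(weeks, dtype=np.int64)
    for spec, rate in arr.urgent_day_rate.items():
        if rate > 0:
            urgents += arr._draw(rng, rate, arr.urgent_day_sd.get(spec, 0.0), (weeks, urgent_day_days)).sum(axis=1)
    urgents += arr._draw(rng, arr.urgent_night_rate_total, 0.0, (weeks, 7)).sum(axis=1)
    emergencies = arr._draw(rng, arr.emergency_day_rate, arr.emergency_day_sd, (weeks, 7)).sum(axis=1)
    emergencies += arr._draw(rng, arr.emergency_night_rate, arr.emergency_night_sd, (weeks, 7)).sum(axis=1)
    return {"elective": electives, "urgent": urgents, "emergency": emergencies}
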