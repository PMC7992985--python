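import numpy as np
import pytest

from ortheater import ScenarioConfig, default_calibration, default_mss
from ortheater.patient_generation import (
    SPECIALTIES,
    ArrivalModel,
    Calibration,
    DurationModel,
    Patient,
)
from ortheater.scheduling import MasterSurgerySchedule


@pytest.fixture(scope="session")
def calibration():
    return default_calibration()


@pytest.fixture(scope="session")
def mss():
    return default_mss()


@pytest.fixture
def rng():
    return np.random.default_rng(20210324)


def zero_arrival_model() -> ArrivalModel:
    return ArrivalModel(
        urgent_day_rate={s: 0.0 for s in SPECIALTIES},
        urgent_night_rate_total=0.0,
        emergency_day_rate=0.0,
        emergency_night_rate=0.0,
    )


def deterministic_calibration() -> Calibration:
    """All dispersions zero, no urgent/emergency arrivals: realized timelines
    must equal the plan exactly."""
    return Calibration(
        arrival=zero_arrival_model(),
        duration=DurationModel(cv=0.0, cleaning_cv=0.0, car_mixture_spread=0.0),
    )


def toy_mss(n_rooms: int = 1, dept: str = "GVT") -> MasterSurgerySchedule:
    """A reduced theater for hand-traceable instances (validation off)."""
    rooms = tuple(f"T{i}" for i in range(n_rooms))
    assignment = {(wd, r): dept for wd in range(5) for r in rooms}
    return MasterSurgerySchedule(
        assignment=assignment, rooms=rooms, night_rooms=frozenset(), validate=False
    )


def det_patient(
    pid: int,
    ind: float,
    occ: float,
    clean: float,
    specialty: str = "GVT",
    acuity: str = "elective",
    cls: str = "medium",
    arrival: float = 0.0,
) -> Patient:
    """Patient whose realized durations equal the planner's expectations."""
    return Patient(
        id=pid,
        specialty=specialty,
        acuity=acuity,
        arrival=arrival,
        duration_class=cls,
        ind=ind,
        occ=occ,
        clean=clean,
        exp_ind=ind,
        exp_occ=occ,
        exp_clean=clean,
    )


def toy_scenario(**kwargs) -> ScenarioConfig:
    defaults = dict(horizon_weeks=1, warmup_weeks=0, replications=1, base_seed=1)
    defaults.update(kwargs)
    return ScenarioConfig(**defaults)
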