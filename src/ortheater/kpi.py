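"""Performance indicators and cross-replication confidence intervals.

All indicators follow the operating-theater management conventions used
throughout the scenario comparisons:

* *Waiting time* measures intraday delay between the (updated) planned start
  and the actual start of treatment; urgent and emergency cases, which have
  no booked slot, are referenced to their ready-for-surgery time.  Deferrals
  (interday rescheduling) are counted separately.
* *Overtime / undertime* compare a room-day's last activity end (cleaning
  included) against the regular close of the master surgery schedule; buffer
  hours therefore show up as overtime-window activity by construction.
* *Utilization* is reported for the regular (08:30-15:45) and extended
  (15:45-20:00) windows, as room utilization (occupation + cleaning) and as
  system utilization (anesthesia + occupation + cleaning).
* *Anesthesia turnover time* is the mean gap from one patient's room exit to
  the next patient's room entry within a room-day.

The dedicated emergency room is excluded from room-day aggregates (it has no
planned elective program); cases inserted into elective rooms count fully.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields as dc_fields
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .engine import CaseLog
from .patient_generation import ELECTIVE, EMERGENCY, SEMI_URGENT, VERY_URGENT

__all__ = [
    "KPIReport",
    "CIReport",
    "compute_kpis",
    "aggregate_replications",
    "paired_difference_ci",
    "ci_overlap",
]

MINUTES_PER_DAY = 1440.0
EXTENDED_CLOSE = 1200.0  # 20:00


@dataclass
class KPIReport:
    """One replication's indicators (weekly-normalized where applicable)."""

    treated_cases_per_week: float = 0.0
    deferrals_per_week: float = 0.0
    room_utilization_regular: float = 0.0
    room_utilization_extended: float = 0.0
    system_utilization_regular: float = 0.0
    system_utilization_extended: float = 0.0
    overtime_per_room_day: float = 0.0
    undertime_per_room_day: float = 0.0
    waiting_elective: float = math.nan
    waiting_semi_urgent: float = math.nan
    waiting_very_urgent: float = math.nan
    waiting_emergency: float = math.nan
    anesthesia_turnover_time: float = math.nan

    def to_dict(self) -> Dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


def _window_overlap(start: np.ndarray, end: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return np.clip(np.minimum(end, hi) - np.maximum(start, lo), 0.0, None)


def compute_kpis(log: CaseLog) -> KPIReport:
    """Compute all indicators from a post-warm-up case log."""
    mss = log.mss
    lo_day, hi_day = log.warmup_days, log.total_days
    weeks = max((hi_day - lo_day) / 7.0, 1e-9)

    df = log.to_dataframe()
    if len(df):
        df = df[(df["day"] >= lo_day) & (df["day"] < hi_day)].copy()
    report = KPIReport()

    report.treated_cases_per_week = len(df) / weeks
    n_defer = sum(1 for e in log.deferral_events if lo_day <= e.day < hi_day)
    report.deferrals_per_week = n_defer / weeks

    if not len(df):
        return report

    # waiting time per acuity
    for acuity, attr in (
        (ELECTIVE, "waiting_elective"),
        (SEMI_URGENT, "waiting_semi_urgent"),
        (VERY_URGENT, "waiting_very_urgent"),
        (EMERGENCY, "waiting_emergency"),
    ):
        sub = df.loc[df["acuity"] == acuity, "wait"]
        if len(sub):
            setattr(report, attr, float(sub.mean()))

    # open elective room-days (the dedicated emergency room is excluded)
    open_pairs = [
        (d, r)
        for d in range(lo_day, hi_day)
        if d % 7 < 5
        for r in mss.elective_rooms(d % 7)
    ]
    n_room_days = len(open_pairs)
    if n_room_days == 0:
        return report
    open_set = set(open_pairs)
    er_rooms = {mss.emergency_room(wd) for wd in range(5)}
    dfe = df[~df["room"].isin(er_rooms)].copy()

    day_base = dfe["day"].to_numpy() * MINUTES_PER_DAY
    reg_lo = day_base + mss.regular_open
    reg_hi = day_base + mss.regular_close
    ext_hi = day_base + EXTENDED_CLOSE
    entry = dfe["room_entry"].to_numpy()
    clean_e = dfe["cleaning_end"].to_numpy()
    ind_s = dfe["induction_start"].to_numpy()
    ind_e = dfe["induction_end"].to_numpy()

    busy_reg = _window_overlap(entry, clean_e, reg_lo, reg_hi)
    busy_ext = _window_overlap(entry, clean_e, reg_hi, ext_hi)
    anes_reg = _window_overlap(ind_s, ind_e, reg_lo, reg_hi)
    anes_ext = _window_overlap(ind_s, ind_e, reg_hi, ext_hi)

    reg_len = (mss.regular_close - mss.regular_open) * n_room_days
    ext_len = (EXTENDED_CLOSE - mss.regular_close) * n_room_days
    report.room_utilization_regular = float(busy_reg.sum() / reg_len)
    report.room_utilization_extended = float(busy_ext.sum() / ext_len)
    report.system_utilization_regular = float((busy_reg + anes_reg).sum() / reg_len)
    report.system_utilization_extended = float((busy_ext + anes_ext).sum() / ext_len)

    # overtime / undertime against the regular close, per open room-day
    grouped = dfe.groupby(["day", "room"])["cleaning_end"].max()
    overtime_total = 0.0
    undertime_total = 0.0
    window = mss.regular_close - mss.regular_open
    for (d, r) in open_pairs:
        close_abs = d * MINUTES_PER_DAY + mss.regular_close
        last_end = grouped.get((d, r), None)
        if last_end is None:
            undertime_total += window
        elif last_end > close_abs:
            overtime_total += last_end - close_abs
        else:
            undertime_total += min(close_abs - last_end, window)
    report.overtime_per_room_day = overtime_total / n_room_days
    report.undertime_per_room_day = undertime_total / n_room_days

    # anesthesia turnover: room exit -> next room entry within the room-day
    dfe = dfe[[p in open_set for p in zip(dfe["day"], dfe["room"])]]
    dfe = dfe.sort_values(["day", "room", "room_entry"])
    same_block = (dfe["day"].shift() == dfe["day"]) & (dfe["room"].shift() == dfe["room"])
    gaps = (dfe["room_entry"] - dfe["room_exit"].shift())[same_block]
    if len(gaps):
        report.anesthesia_turnover_time = float(gaps.mean())
    return report


# --- cross-replication aggregation ------------------------------------------------


@dataclass
class CIReport:
    """Means with two-sided 95% t-intervals across independent replications."""

    table: pd.DataFrame  # index: KPI name; columns: mean, sd, n, half_width, lower, upper

    def interval(self, kpi: str) -> Tuple[float, float]:
        row = self.table.loc[kpi]
        return float(row["lower"]), float(row["upper"])

    def mean(self, kpi: str) -> float:
        return float(self.table.loc[kpi, "mean"])

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="index", indent=2)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def aggregate_replications(reports: Sequence[KPIReport], confidence: float = 0.95) -> CIReport:
    """Mean and 95% t-interval per KPI; single replications yield mean only."""
    if len(reports) < 1:
        raise ValueError("need at least one replication report")
    df = pd.DataFrame([r.to_dict() for r in reports])
    rows = {}
    for col in df.columns:
        vals = df[col].dropna().to_numpy()
        n = len(vals)
        mean = float(np.mean(vals)) if n else math.nan
        sd = float(np.std(vals, ddof=1)) if n > 1 else math.nan
        if n > 1:
            hw = float(stats.t.ppf(0.5 + confidence / 2.0, n - 1) * sd / math.sqrt(n))
        else:
            hw = math.nan
        rows[col] = {
            "mean": mean,
            "sd": sd,
            "n": n,
            "half_width": hw,
            "lower": mean - hw if n > 1 else math.nan,
            "upper": mean + hw if n > 1 else math.nan,
        }
    return CIReport(table=pd.DataFrame(rows).T)


def ci_overlap(a: CIReport, b: CIReport, kpi: str) -> bool:
    """True if the two scenarios' 95% intervals for a KPI overlap.

    Non-overlap signals a statistically significant difference at the 0.05
    level under the usual conservative interval-comparison convention."""
    alo, ahi = a.interval(kpi)
    blo, bhi = b.interval(kpi)
    return not (ahi < blo or bhi < alo)


def paired_difference_ci(
    reports_a: Sequence[KPIReport],
    reports_b: Sequence[KPIReport],
    kpi: str,
    confidence: float = 0.95,
) -> Tuple[float, float, float]:
    """Mean and CI of per-replication differences (a - b) under common seeds.

    Common random numbers make the paired contrast far sharper than comparing
    the two marginal intervals."""
    va = np.array([r.to_dict()[kpi] for r in reports_a], dtype=float)
    vb = np.array([r.to_dict()[kpi] for r in reports_b], dtype=float)
    if len(va) != len(vb):
        raise ValueError("paired comparison needs equally many replications")
    diff = va - vb
    diff = diff[~np.isnan(diff)]
    n = len(diff)
    mean = float(diff.mean())
    if n < 2:
        return mean, math.nan, math.nan
    hw = float(stats.t.ppf(0.5 + confidence / 2.0, n - 1) * diff.std(ddof=1) / math.sqrt(n))
    return mean, mean - hw, mean + hw
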