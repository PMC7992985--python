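"""Scenario configuration: the four policy levers plus run parameters."""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from typing import Mapping

__all__ = ["ScenarioError", "ScenarioConfig", "REGULAR_OPEN", "REGULAR_CLOSE", "MAX_CLOSE"]

#: Regular opening window 08:30-15:45 and the hard staffing limit 20:00,
#: minutes from midnight.
REGULAR_OPEN = 510.0
REGULAR_CLOSE = 945.0
MAX_CLOSE = 1200.0

SEQUENCING_POLICIES = ("FIFO", "SF", "LF")


class ScenarioError(ValueError):
    """Raised for invalid policy-lever combinations before any event runs."""


@dataclass(frozen=True)
class ScenarioConfig:
    """One management-policy scenario.

    The Base Case is FIFO sequencing, no buffer hours, sequential anesthesia
    induction and a staffed dedicated emergency OR.
    """

    name: str = "base"
    sequencing: str = "FIFO"
    buffer_hours: float = 0.0
    parallel_induction: bool = False
    extra_teams: int = 0
    dedicated_emergency_or: bool = True
    replications: int = 30
    horizon_weeks: int = 52
    warmup_weeks: int = 4
    base_seed: int = 20_210_324
    emergency_notice_min: float = 30.0

    def __post_init__(self) -> None:
        if self.sequencing not in SEQUENCING_POLICIES:
            raise ScenarioError(f"unknown sequencing policy {self.sequencing!r}")
        if not 0.0 <= self.buffer_hours <= (MAX_CLOSE - REGULAR_CLOSE) / 60.0:
            raise ScenarioError(
                f"buffer_hours must keep the effective close at or before 20:00: {self.buffer_hours}"
            )
        if self.extra_teams not in (0, 1, 2, 3):
            raise ScenarioError(f"extra_teams must be 0-3: {self.extra_teams}")
        if self.extra_teams > 0 and not self.parallel_induction:
            raise ScenarioError("extra anesthesia teams require parallel induction to be enabled")
        if self.horizon_weeks < 1 or self.warmup_weeks < 0 or self.replications < 1:
            raise ScenarioError("horizon_weeks >= 1, warmup_weeks >= 0, replications >= 1 required")
        if self.emergency_notice_min < 0:
            raise ScenarioError("emergency notice must be >= 0")

    @property
    def effective_close(self) -> float:
        """Minute-of-day after which no further elective case may start."""
        return min(REGULAR_CLOSE + 60.0 * self.buffer_hours, MAX_CLOSE)

    def with_(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "ScenarioConfig":
        return cls(**dict(data))
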