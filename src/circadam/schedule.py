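"""Light schedules and circadian time conventions.

An experiment is described as an ordered sequence of phases (LD or DD), each
starting on an integer *experiment day*.  Experiment time is measured in hours
since ZT0 of day 0, where ZT0 is lights-on of the first LD phase.  In DD
phases zeitgeber time is replaced by circadian time (CT) anchored to the
projected lights-on of the preceding LD entrainment, so the same modular
clock applies throughout: ``zt(h) = h mod 24`` for any experiment hour ``h``.

All ZT windows used downstream are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = ["Phase", "LightSchedule"]

MINUTES_PER_DAY = 1440


@dataclass(frozen=True)
class Phase:
    """One constant-regime segment of the recording.

    Parameters
    ----------
    start_day : first experiment day (0-based) of this phase.
    regime : ``"LD"`` or ``"DD"``.
    lights_on, lights_off : clock hours of the transitions.  Ignored for the
        light cycle in DD but retained so CT stays anchored to the projected
        lights-on.
    temperature : °C, metadata only.
    """

    start_day: int
    regime: str
    lights_on: float = 8.0
    lights_off: float = 20.0
    temperature: float = 25.0

    def __post_init__(self) -> None:
        if self.regime not in ("LD", "DD"):
            raise ValueError(f"regime must be 'LD' or 'DD', got {self.regime!r}")
        if self.start_day < 0:
            raise ValueError("start_day must be >= 0")
        if self.regime == "LD" and (self.lights_on % 24) == (self.lights_off % 24):
            raise ValueError("LD phase requires lights_on != lights_off")

    @property
    def light_hours(self) -> float:
        """Photoperiod length in hours (12 for LD12:12)."""
        return (self.lights_off - self.lights_on) % 24


class LightSchedule:
    """Ordered, non-overlapping phases covering ``n_days`` of recording."""

    def __init__(self, phases: Sequence[Phase], n_days: int):
        phases = tuple(phases)
        if not phases:
            raise ValueError("schedule needs at least one phase")
        if phases[0].start_day != 0:
            raise ValueError("first phase must start on day 0")
        starts = [p.start_day for p in phases]
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("phases must be ordered with strictly increasing start_day")
        if n_days < 1 or phases[-1].start_day >= n_days:
            raise ValueError("phases must lie within the recording length")
        ld = [p for p in phases if p.regime == "LD"]
        # reference lights-on anchors ZT0 (and projected CT0 in DD)
        self.reference_lights_on = ld[0].lights_on if ld else phases[0].lights_on
        self.phases = phases
        self.n_days = int(n_days)

    @classmethod
    def ld_dd(
        cls,
        n_ld_days: int,
        n_dd_days: int,
        lights_on: float = 8.0,
        lights_off: float = 20.0,
        temperature: float = 25.0,
    ) -> "LightSchedule":
        """Standard entrainment-then-free-run protocol (e.g. LD12:12 → DD)."""
        phases = [Phase(0, "LD", lights_on, lights_off, temperature)]
        if n_dd_days > 0:
            phases.append(Phase(n_ld_days, "DD", lights_on, lights_off, temperature))
        elif n_ld_days < 1:
            raise ValueError("need at least one day")
        return cls(phases, n_ld_days + n_dd_days)

    def phase_of_day(self, day: int) -> Phase:
        if not 0 <= day < self.n_days:
            raise ValueError(f"day {day} outside recording (0..{self.n_days - 1})")
        current = self.phases[0]
        for p in self.phases:
            if p.start_day <= day:
                current = p
        return current

    def regime_of_day(self, day: int) -> str:
        return self.phase_of_day(day).regime

    def ld_days(self) -> list[int]:
        return [d for d in range(self.n_days) if self.regime_of_day(d) == "LD"]

    def dd_days(self) -> list[int]:
        return [d for d in range(self.n_days) if self.regime_of_day(d) == "DD"]

    @property
    def dd_start_day(self) -> int | None:
        dd = self.dd_days()
        return dd[0] if dd else None

    def zt(self, hours: float | np.ndarray) -> np.ndarray:
        """ZT (or CT in DD) for experiment hours since ZT0 of day 0."""
        return np.asarray(hours, dtype=float) % 24.0

    def is_light(self, hours: float | np.ndarray) -> np.ndarray:
        """Whether lights are on at the given experiment hour(s)."""
        hours = np.atleast_1d(np.asarray(hours, dtype=float))
        day = np.clip(hours // 24, 0, self.n_days - 1).astype(int)
        out = np.zeros(hours.shape, dtype=bool)
        for d in np.unique(day):
            p = self.phase_of_day(int(d))
            if p.regime == "LD":
                sel = day == d
                out[sel] = (hours[sel] % 24.0) < p.light_hours
        return out

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, LightSchedule)
            and self.phases == other.phases
            and self.n_days == other.n_days
        )

    def __repr__(self) -> str:
        seq = ", ".join(f"{p.regime}@d{p.start_day}" for p in self.phases)
        return f"LightSchedule({seq}, n_days={self.n_days})"
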