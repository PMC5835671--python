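"""Light regimes and Zeitgeber time.

Zeitgeber time (ZT) counts hours since lights-on: ZT0 is light onset under
entrainment, and under constant conditions (DD/LL) it refers to the projected
onset of the prior entraining cycle.  A :class:`LightRegime` anchors ZT0 to a
clock time and records, day by day, whether the animal experienced a
light:dark cycle (LD), constant darkness (DD) or constant light (LL).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

__all__ = ["DayEntry", "LightRegime", "PHASE_CODES"]

#: Per-bin phase labels used for actogram shading.  The four-tone convention:
#: photophase (white), scotophase (black), subjective day in DD (dark gray),
#: subjective night in LL (light gray).
PHASE_CODES = ("photophase", "scotophase", "subjective_day", "subjective_night")


@dataclass(frozen=True)
class DayEntry:
    """One recording day's lighting: ``kind`` is ``"LD"``, ``"DD"`` or ``"LL"``."""

    kind: str
    photophase_hours: float = 12.0

    def __post_init__(self) -> None:
        if self.kind not in ("LD", "DD", "LL"):
            raise ValueError(f"unknown light-regime kind {self.kind!r}")
        if self.kind == "LD" and not (0.0 < self.photophase_hours < 24.0):
            raise ValueError("photophase_hours must lie in (0, 24)")

    def phase_at(self, zt: float) -> str:
        """Phase label at Zeitgeber time ``zt`` (hours in [0, 24))."""
        zt = zt % 24.0
        if self.kind == "LD":
            return "photophase" if zt < self.photophase_hours else "scotophase"
        if self.kind == "DD":
            return "subjective_day" if zt < self.photophase_hours else "scotophase"
        # LL: light all day; the projected night is "subjective night"
        return "photophase" if zt < self.photophase_hours else "subjective_night"


@dataclass
class LightRegime:
    """ZT0 anchor plus an ordered per-day lighting schedule.

    ``schedule[d]`` describes the day starting at ``d * 24`` hours after the
    recording's ZT0.  Days beyond the explicit schedule repeat the last entry,
    which is the natural reading of "released into DD/LL".
    """

    zt0_clock_time: _dt.time = _dt.time(8, 0)
    schedule: list[DayEntry] = field(default_factory=lambda: [DayEntry("LD")])
    label: str = ""

    def __post_init__(self) -> None:
        if not self.schedule:
            raise ValueError("schedule must contain at least one day")

    def day_entry(self, day: int) -> DayEntry:
        if day < 0:
            raise IndexError("day must be nonnegative")
        return self.schedule[min(day, len(self.schedule) - 1)]

    def phase_at(self, hours_from_zt0: float) -> str:
        """Phase label at an offset (hours) from the recording's first ZT0."""
        day = int(hours_from_zt0 // 24)
        return self.day_entry(day).phase_at(hours_from_zt0 % 24.0)

    def lights_on_times(self, n_days: int) -> list[float]:
        """Hours (from first ZT0) of every lights-on transition in ``n_days``.

        A lights-on happens at ZT0 of every LD day.  The dawn of day 0 counts:
        animals straight out of the entraining incubator see that transition.
        """
        return [24.0 * d for d in range(n_days) if self.day_entry(d).kind == "LD"]

    def shifted(self, days: int) -> "LightRegime":
        """Regime with the first ``days`` schedule entries dropped (first-day
        exclusion shifts the day axis)."""
        remaining = self.schedule[days:] or [self.schedule[-1]]
        return replace(self, schedule=list(remaining))

    # -- constructors -----------------------------------------------------

    @classmethod
    def constant(cls, kind: str, n_days: int, zt0: _dt.time = _dt.time(8, 0),
                 label: str | None = None) -> "LightRegime":
        """Uniform regime (``kind`` in LD/DD/LL) for ``n_days`` days."""
        return cls(zt0_clock_time=zt0,
                   schedule=[DayEntry(kind) for _ in range(max(n_days, 1))],
                   label=label if label is not None else kind)

    @classmethod
    def entrained_then(cls, kind: str, n_days: int,
                       zt0: _dt.time = _dt.time(8, 0)) -> "LightRegime":
        """Entrainment-release design: day 0 in LD (adaptation), then
        ``kind`` — the usual protocol for probing free-running rhythms."""
        sched = [DayEntry("LD")] + [DayEntry(kind) for _ in range(max(n_days - 1, 1))]
        return cls(zt0_clock_time=zt0, schedule=sched, label=f"LD1+{kind}")

    def to_dict(self) -> dict:
        return {
            "zt0_clock_time": self.zt0_clock_time.strftime("%H:%M:%S"),
            "label": self.label,
            "schedule": [
                {"kind": e.kind, "photophase_hours": e.photophase_hours}
                for e in self.schedule
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LightRegime":
        return cls(
            zt0_clock_time=_dt.time.fromisoformat(d.get("zt0_clock_time", "08:00:00")),
            schedule=[DayEntry(e["kind"], e.get("photophase_hours", 12.0))
                      for e in d["schedule"]],
            label=d.get("label", ""),
        )
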