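"""The in-memory container for one animal's activity record."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

from .light import LightRegime

__all__ = ["ActivitySeries"]

MINUTES_PER_DAY = 1440


@dataclass
class ActivitySeries:
    """Binned beam-break counts for one animal.

    ``counts`` is float so missing bins can be NaN; valid entries are
    nonnegative integers (beam breaks are event counts).  The first bin is
    assumed to start at ZT0 — day ``d`` spans bins ``[d*bins_per_day,
    (d+1)*bins_per_day)`` — which is how both the simulator and the monitor
    reader construct series.  ``alive_through_h`` is the estimated death time
    (hours from start) set by survival trimming; ``None`` means alive to the
    end of the record.
    """

    animal_id: str
    start: pd.Timestamp
    bin_minutes: int
    counts: np.ndarray
    regime: LightRegime
    alive_through_h: float | None = None
    excluded: bool = False
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if self.bin_minutes <= 0 or MINUTES_PER_DAY % self.bin_minutes:
            raise ValueError("bin_minutes must be positive and divide 1440")
        finite = self.counts[np.isfinite(self.counts)]
        if finite.size and finite.min() < 0:
            raise ValueError("counts must be nonnegative")

    # -- geometry ---------------------------------------------------------

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def bins_per_day(self) -> int:
        return MINUTES_PER_DAY // self.bin_minutes

    @property
    def span_hours(self) -> float:
        return self.n_bins * self.bin_minutes / 60.0

    @property
    def n_days(self) -> int:
        """Number of complete recorded days."""
        return self.n_bins // self.bins_per_day

    def bin_start_hours(self) -> np.ndarray:
        """Hours from series start (= from ZT0) at each bin's left edge."""
        return np.arange(self.n_bins) * (self.bin_minutes / 60.0)

    def zt_hours(self) -> np.ndarray:
        """Zeitgeber time of each bin start, in [0, 24)."""
        return self.bin_start_hours() % 24.0

    @property
    def fraction_missing(self) -> float:
        return float(np.isnan(self.counts).mean()) if self.n_bins else 0.0

    # -- helpers ----------------------------------------------------------

    def with_counts(self, counts: np.ndarray, **changes: Any) -> "ActivitySeries":
        return replace(self, counts=np.asarray(counts, dtype=float), **changes)

    def daily_matrix(self) -> np.ndarray:
        """Counts reshaped to (complete days, bins per day)."""
        d, b = self.n_days, self.bins_per_day
        return self.counts[: d * b].reshape(d, b)

    def to_frame(self) -> pd.DataFrame:
        idx = self.start + pd.to_timedelta(
            np.arange(self.n_bins) * self.bin_minutes, unit="m")
        return pd.DataFrame({
            "animal_id": self.animal_id,
            "timestamp": idx,
            "count": self.counts,
        })
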