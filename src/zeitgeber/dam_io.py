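"""Reading, writing and hygiene for activity-monitor records.

The on-disk dialect is the classic 32-channel infrared beam-break monitor
text file: tab-separated, one row per minute, 42 fields per row::

    index  date  time  status  f1 f2 f3 f4 f5 f6  c1 ... c32

* ``index``  — 1-based running record number
* ``date``   — ``D Mon YY`` (e.g. ``8 Sep 25``, day not zero-padded)
* ``time``   — ``HH:MM:SS``
* ``status`` — ``1`` for a valid record; any other code flags the row and
  its minute becomes a missing bin in every channel
* ``f1..f6`` — device/extras fields (written as zeros, preserved on read)
* ``c1..c32`` — integer beam-break counts for channels 1-32

Hygiene operations implement the study conventions: the first recording day
is excluded from analysis (animals adapt to the tubes), and animals whose
record ends in a long terminal run of zero counts are scored dead from the
start of that run and excluded when they did not survive the 4-day analysis
window.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .light import LightRegime
from .series import MINUTES_PER_DAY, ActivitySeries

__all__ = [
    "MonitorFormatError",
    "read_monitor_file",
    "write_monitor_file",
    "read_activity_csv",
    "write_activity_csv",
    "bin_series",
    "exclude_first_day",
    "trim_survival",
    "interpolate_missing",
]

N_CHANNELS = 32
N_FIELDS = 4 + 6 + N_CHANNELS
OK_STATUS = "1"


class MonitorFormatError(ValueError):
    """Raised for malformed monitor files; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


def _parse_timestamp(date_s: str, time_s: str, line: int) -> pd.Timestamp:
    try:
        return pd.to_datetime(f"{date_s} {time_s}", format="%d %b %y %H:%M:%S")
    except ValueError as exc:
        raise MonitorFormatError(f"bad timestamp {date_s!r} {time_s!r}: {exc}", line)


def read_monitor_file(path: str | Path,
                      regime: LightRegime | None = None) -> list[ActivitySeries]:
    """Read a 32-channel monitor file into one 1-min series per channel.

    Rows with a non-OK status become missing (NaN) bins.  Gaps in the
    minute-by-minute timeline are filled with missing bins and warned about;
    non-monotone timestamps are an error.
    """
    path = Path(path)
    regime = regime or LightRegime.constant("LD", 1)
    times: list[pd.Timestamp] = []
    rows: list[np.ndarray] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) != N_FIELDS:
                raise MonitorFormatError(
                    f"expected {N_FIELDS} tab-separated fields, got {len(fields)}",
                    lineno)
            ts = _parse_timestamp(fields[1], fields[2], lineno)
            if times and ts <= times[-1]:
                raise MonitorFormatError(
                    f"non-monotone timestamp {ts} (previous {times[-1]})", lineno)
            status = fields[3]
            try:
                counts = np.array([float(v) for v in fields[10:]], dtype=float)
            except ValueError as exc:
                raise MonitorFormatError(f"bad count field: {exc}", lineno)
            if (counts < 0).any():
                raise MonitorFormatError("negative count", lineno)
            if status != OK_STATUS:
                counts[:] = np.nan
            times.append(ts)
            rows.append(counts)
    if not rows:
        raise MonitorFormatError("empty monitor file")

    start = times[0]
    offsets = np.array([(t - start).total_seconds() / 60.0 for t in times])
    if not np.allclose(offsets, np.round(offsets)):
        raise MonitorFormatError("timestamps not on a 1-minute grid")
    offsets = np.round(offsets).astype(int)
    n_bins = offsets[-1] + 1
    if n_bins != len(rows):
        warnings.warn(
            f"{path.name}: {n_bins - len(rows)} missing minute(s) filled as "
            "missing bins", stacklevel=2)
    data = np.full((n_bins, N_CHANNELS), np.nan)
    data[offsets] = np.vstack(rows)

    stem = path.stem
    return [
        ActivitySeries(
            animal_id=f"{stem}#{ch + 1:02d}",
            start=start,
            bin_minutes=1,
            counts=data[:, ch],
            regime=regime,
            meta={"source": str(path), "channel": ch + 1},
        )
        for ch in range(N_CHANNELS)
    ]


def write_monitor_file(path: str | Path, series: Sequence[ActivitySeries]) -> None:
    """Write up to 32 aligned 1-min series as a monitor file.

    All series must share start, length and 1-min bins; absent channels are
    written as zeros.  A minute in which any channel is missing is written
    with a non-OK status (the format has per-row, not per-channel, status).
    """
    if not series:
        raise ValueError("need at least one series")
    if len(series) > N_CHANNELS:
        raise ValueError(f"monitor files hold at most {N_CHANNELS} channels")
    first = series[0]
    for s in series:
        if s.bin_minutes != 1:
            raise ValueError("monitor files are written at 1-min resolution")
        if s.n_bins != first.n_bins or s.start != first.start:
            raise ValueError("all series must share start and length")
    data = np.zeros((first.n_bins, N_CHANNELS))
    for ch, s in enumerate(series):
        data[:, ch] = s.counts
    missing_row = np.isnan(data).any(axis=1)
    data = np.nan_to_num(data)

    lines = []
    for i in range(first.n_bins):
        ts = first.start + pd.Timedelta(minutes=i)
        date_s = f"{ts.day} {ts.strftime('%b %y')}"
        status = OK_STATUS if not missing_row[i] else "51"
        fields = ([str(i + 1), date_s, ts.strftime("%H:%M:%S"), status]
                  + ["0"] * 6
                  + [str(int(round(v))) for v in data[i]])
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def read_activity_csv(path: str | Path,
                      regime: LightRegime | None = None,
                      bin_minutes: int = 1) -> list[ActivitySeries]:
    """Read the long-format CSV alternative (animal_id, timestamp, count)."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    regime = regime or LightRegime.constant("LD", 1)
    out = []
    for animal, g in df.groupby("animal_id", sort=False):
        g = g.sort_values("timestamp")
        out.append(ActivitySeries(
            animal_id=str(animal),
            start=g["timestamp"].iloc[0],
            bin_minutes=bin_minutes,
            counts=g["count"].to_numpy(dtype=float),
            regime=regime,
        ))
    return out


def write_activity_csv(path: str | Path, series: Sequence[ActivitySeries]) -> None:
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(
        path, index=False)


# ---------------------------------------------------------------------------
# binning and hygiene
# ---------------------------------------------------------------------------

def bin_series(series: ActivitySeries, bin_minutes: int) -> ActivitySeries:
    """Sum counts into wider aligned bins; totals are conserved.

    ``bin_minutes`` must be a multiple of the current width and divide 1440.
    A wide bin containing any missing narrow bin is missing.  A trailing
    partial window is dropped (span may shrink by < one wide bin).
    """
    if bin_minutes <= 0 or bin_minutes % series.bin_minutes:
        raise ValueError(
            f"bin_minutes={bin_minutes} must be a positive multiple of the "
            f"current width {series.bin_minutes}")
    if MINUTES_PER_DAY % bin_minutes:
        raise ValueError(f"bin_minutes={bin_minutes} must divide 1440")
    k = bin_minutes // series.bin_minutes
    if k == 1:
        return series.with_counts(series.counts.copy())
    n = (series.n_bins // k) * k
    grouped = series.counts[:n].reshape(-1, k)
    # plain sum: any NaN in the window propagates, marking the bin missing
    counts = grouped.sum(axis=1)
    return series.with_counts(counts, bin_minutes=bin_minutes)


def exclude_first_day(series: ActivitySeries) -> ActivitySeries:
    """Drop the first 24 h (adaptation day) and shift the day axis."""
    bpd = series.bins_per_day
    if series.n_bins < 2 * bpd:
        raise ValueError("series must span at least 2 days to exclude day 1")
    alive = series.alive_through_h
    if alive is not None:
        alive = max(alive - 24.0, 0.0)
    return series.with_counts(
        series.counts[bpd:],
        start=series.start + pd.Timedelta(days=1),
        regime=series.regime.shifted(1),
        alive_through_h=alive,
    )


def trim_survival(series: ActivitySeries,
                  death_run_hours: float = 24.0,
                  min_alive_days: float = 4.0) -> ActivitySeries:
    """Score death from a terminal all-zero run and flag short survivors.

    If the record ends with >= ``death_run_hours`` of consecutive zero-count
    bins, the animal is scored dead at the start of that run
    (``alive_through_h``).  Animals that did not survive ``min_alive_days``
    are marked ``excluded`` (they cannot contribute a complete analysis
    window).  Missing bins break a zero run: absence of data is not evidence
    of death.
    """
    c = series.counts
    is_zero = np.nan_to_num(c, nan=1.0) == 0.0  # NaN counts as activity-unknown
    run = 0
    for v in is_zero[::-1]:
        if v:
            run += 1
        else:
            break
    run_hours = run * series.bin_minutes / 60.0
    if run_hours >= death_run_hours:
        alive_h = (series.n_bins - run) * series.bin_minutes / 60.0
        return series.with_counts(
            series.counts.copy(),
            alive_through_h=alive_h,
            excluded=alive_h < min_alive_days * 24.0,
            meta={**series.meta, "dead": True},
        )
    return series.with_counts(series.counts.copy(),
                              alive_through_h=None, excluded=False)


def interpolate_missing(series: ActivitySeries,
                        max_missing_fraction: float = 0.05) -> ActivitySeries:
    """Linearly interpolate missing bins for analyses needing complete data.

    Series missing more than ``max_missing_fraction`` of bins are rejected:
    interpolation would then invent, not repair, the signal.
    """
    c = series.counts
    nan = np.isnan(c)
    if not nan.any():
        return series.with_counts(c.copy())
    if nan.mean() > max_missing_fraction:
        raise ValueError(
            f"{series.animal_id}: {nan.mean():.1%} of bins missing exceeds "
            f"the {max_missing_fraction:.0%} limit")
    idx = np.arange(c.size)
    filled = c.copy()
    filled[nan] = np.interp(idx[nan], idx[~nan], c[~nan])
    return series.with_counts(filled, meta={**series.meta, "interpolated": int(nan.sum())})
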