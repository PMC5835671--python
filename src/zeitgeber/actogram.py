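"""Actogram matrices, daily activity profiles, and onset/acrophase calls.

Everything here is data-level: an actogram is a (days × bins) matrix in ZT
coordinates — double-plotting concatenates day d with day d+1 on each row so
free-running rhythms read as diagonal bands — and a daily profile is the
across-animal mean ± SEM of per-ZT-bin activity averaged over the analysis
days.  Rendering is a thin matplotlib layer over those matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .rhythmicity import GroupComparison, compare_groups
from .series import ActivitySeries

__all__ = [
    "ActogramMatrix",
    "DailyProfile",
    "build_actogram",
    "daily_profile",
    "interval_means",
    "onset_acrophase",
    "OnsetAcrophase",
    "render_actogram",
]

DEFAULT_INTERVALS = ((0.0, 6.0), (6.0, 12.0), (12.0, 18.0), (18.0, 24.0))

_SHADE_GRAY = {"photophase": 1.0, "scotophase": 0.0,
               "subjective_day": 0.35, "subjective_night": 0.75}


@dataclass
class ActogramMatrix:
    """Raster of activity: one row per day, columns in ZT order.

    Double-plotted rows span 48 h (day d then day d+1), so the right half of
    row d equals the left half of row d+1 and there are n_days − 1 rows.
    ``shading`` holds the per-cell phase label for the four-tone background.
    """

    values: np.ndarray          # (rows, bins) activity
    shading: np.ndarray         # (rows, bins) phase-label strings
    bin_minutes: int
    double: bool
    animal_id: str = ""

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        hours = np.arange(self.values.shape[1]) * self.bin_minutes / 60.0
        df = pd.DataFrame(self.values,
                          columns=[f"zt{h:g}" for h in hours])
        df.insert(0, "day", np.arange(1, self.n_rows + 1))
        return df


@dataclass
class DailyProfile:
    """Across-animal daily activity profile on the ZT grid.

    ``per_animal`` keeps each animal's day-averaged 24-h vector so interval
    statistics can be computed at the animal level.
    """

    zt_bins: np.ndarray     # bin start ZTs, tiling [0, 24)
    mean_counts: np.ndarray
    sem_counts: np.ndarray
    n_animals: int
    per_animal: np.ndarray  # (n_animals, n_bins)
    sem_defined: bool = True

    @property
    def bin_hours(self) -> float:
        return float(self.zt_bins[1] - self.zt_bins[0])


@dataclass
class OnsetAcrophase:
    onset_zt: float | None
    acrophase_zt: float | None
    flat: bool = False


def build_actogram(series: ActivitySeries, double: bool = True) -> ActogramMatrix:
    """Day-by-day activity raster with phase shading from the light regime."""
    days = series.n_days
    if double and days < 2:
        raise ValueError("double-plotting needs at least 2 complete days")
    if days < 1:
        raise ValueError("need at least 1 complete day")
    mat = series.daily_matrix()
    bpd = series.bins_per_day
    zts = np.arange(bpd) * series.bin_minutes / 60.0
    shade = np.array([[series.regime.day_entry(d).phase_at(z) for z in zts]
                      for d in range(days)], dtype=object)
    if double:
        values = np.hstack([mat[:-1], mat[1:]])
        shading = np.hstack([shade[:-1], shade[1:]])
    else:
        values, shading = mat, shade
    return ActogramMatrix(values=values, shading=shading,
                          bin_minutes=series.bin_minutes, double=double,
                          animal_id=series.animal_id)


def daily_profile(group: Sequence[ActivitySeries],
                  n_days: int | None = None) -> DailyProfile:
    """Mean ± SEM across animals of per-ZT-bin counts averaged over days.

    All series must share bin width (and thus the ZT grid).  ``n_days``
    restricts averaging to the first n complete days (the analysis window);
    by default all complete days contribute.
    """
    if not group:
        raise ValueError("empty group")
    bw = group[0].bin_minutes
    if any(s.bin_minutes != bw for s in group):
        raise ValueError("all series must share the same bin width")
    rows = []
    for s in group:
        mat = s.daily_matrix()
        if n_days is not None:
            if mat.shape[0] < n_days:
                raise ValueError(f"{s.animal_id}: fewer than {n_days} days")
            mat = mat[:n_days]
        rows.append(np.nanmean(mat, axis=0))
    per_animal = np.vstack(rows)
    n = per_animal.shape[0]
    mean = per_animal.mean(axis=0)
    if n > 1:
        sem = per_animal.std(axis=0, ddof=1) / np.sqrt(n)
        sem_defined = True
    else:
        sem = np.zeros_like(mean)
        sem_defined = False
    zts = np.arange(per_animal.shape[1]) * bw / 60.0
    return DailyProfile(zt_bins=zts, mean_counts=mean, sem_counts=sem,
                        n_animals=n, per_animal=per_animal,
                        sem_defined=sem_defined)


def interval_means(profile: DailyProfile,
                   intervals: Sequence[tuple[float, float]] = DEFAULT_INTERVALS,
                   alpha: float = 0.05,
                   ) -> tuple[pd.DataFrame, GroupComparison | None]:
    """Per-interval activity (animal-level sums) with Tukey letters.

    Intervals must tile [0, 24) without overlap.  Each animal contributes
    its summed day-averaged counts per interval; groups are compared across
    intervals by ANOVA + Tukey (or Welch t for two intervals).  With a
    single animal the comparison is skipped (no replication).
    """
    ivals = sorted(intervals)
    for (a_lo, a_hi), (b_lo, b_hi) in zip(ivals, ivals[1:]):
        if b_lo < a_hi:
            raise ValueError("intervals overlap")
    if ivals[0][0] != 0.0 or ivals[-1][1] != 24.0 or any(
            a_hi != b_lo for (_, a_hi), (b_lo, _) in zip(ivals, ivals[1:])):
        raise ValueError("intervals must tile [0, 24) exactly")

    sums = {}
    for lo, hi in intervals:
        mask = (profile.zt_bins >= lo) & (profile.zt_bins < hi)
        sums[f"ZT{lo:g}-{hi:g}"] = profile.per_animal[:, mask].sum(axis=1)

    comp = None
    letters = {k: "" for k in sums}
    if profile.n_animals >= 2:
        comp = compare_groups(sums, alpha=alpha)
        letters = comp.letters or letters
    rows = []
    for name, v in sums.items():
        sem = v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else 0.0
        rows.append((name, v.mean(), sem, letters.get(name, "")))
    return (pd.DataFrame(rows, columns=["interval", "mean", "sem", "letter"]),
            comp)


def _circular_smooth3(y: np.ndarray) -> np.ndarray:
    return (np.roll(y, 1) + y + np.roll(y, -1)) / 3.0


def onset_acrophase(profile: DailyProfile,
                    run_up: int = 2,
                    run_down: int = 2) -> OnsetAcrophase:
    """Activity onset and acrophase of a daily profile.

    The profile is smoothed with a centered circular 3-bin moving average.
    Acrophase is the ZT of the smoothed maximum.  Onset is the start of the
    first run of >= ``run_up`` consecutive bins above the daily mean that is
    preceded by >= ``run_down`` consecutive bins below it, scanning
    circularly from ZT0.  A flat profile yields both undefined.
    """
    y = _circular_smooth3(profile.mean_counts.astype(float))
    if np.ptp(y) == 0.0:
        return OnsetAcrophase(None, None, flat=True)
    acro = float(profile.zt_bins[int(np.argmax(y))])

    above = y > y.mean()
    n = above.size
    onset = None
    for i in range(n):
        up_ok = all(above[(i + j) % n] for j in range(run_up))
        down_ok = all(not above[(i - 1 - j) % n] for j in range(run_down))
        if up_ok and down_ok:
            onset = float(profile.zt_bins[i])
            break
    return OnsetAcrophase(onset_zt=onset, acrophase_zt=acro)


def render_actogram(matrix: ActogramMatrix, path) -> None:
    """Render an actogram raster (activity bars over phase shading) to file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows, cols = matrix.values.shape
    hours = cols * matrix.bin_minutes / 60.0
    fig, axes = plt.subplots(rows, 1, sharex=True,
                             figsize=(8, max(1.0, 0.6 * rows)), squeeze=False)
    x = np.arange(cols) * matrix.bin_minutes / 60.0
    width = matrix.bin_minutes / 60.0
    vmax = np.nanmax(matrix.values) or 1.0
    for r in range(rows):
        ax = axes[r, 0]
        for c in range(cols):
            g = _SHADE_GRAY[str(matrix.shading[r, c])]
            ax.axvspan(x[c], x[c] + width, color=str(g), lw=0, zorder=0)
        ax.bar(x, np.nan_to_num(matrix.values[r]) / vmax, width=width,
               align="edge", color="tab:blue", zorder=1)
        ax.set_ylim(0, 1)
        ax.set_yticks([])
        ax.set_ylabel(f"d{r + 1}", rotation=0, ha="right", va="center")
    axes[-1, 0].set_xlim(0, hours)
    axes[-1, 0].set_xlabel("Zeitgeber time (h)")
    fig.suptitle(matrix.animal_id)
    fig.savefig(path, dpi=120)
    plt.close(fig)
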