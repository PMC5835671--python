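"""Synthetic activity recordings and qPCR Ct tables with known ground truth.

The behavioral generator emulates what an infrared beam-break monitor sees
for a diurnal planthopper entrained to LD 12:12: counts per native 1-minute
slot are Poisson with a sinusoidally modulated rate

    rate(t) = baseline_rate * (1 + rel_amplitude * cos(2*pi*(t - acrophase)/P))

peaking in the late photophase (default acrophase ZT10, matching the
pre-lights-off activity maximum), plus an additive masking spike — the
startle response to abrupt lights-on — confined to the first slot after
each lights-on transition.  Defaults give ~72 counts/day, the magnitude of
real recordings.

The expression generator inverts the cosinor model the analysis fits:
true expression E(t) = cos(t/24*2pi + phase)*amplitude + shift on a 3-hour
sampling grid, three biological replicates per timepoint, converted to
target/reference threshold cycles with Gaussian noise on the Ct (log2)
scale — the standard qPCR error model.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import dam_io
from .light import LightRegime
from .series import MINUTES_PER_DAY, ActivitySeries

__all__ = [
    "SimBehaviorParams",
    "SimExpressionParams",
    "simulate_locomotor_series",
    "simulate_cohort",
    "apply_death",
    "simulate_ct_table",
    "true_expression",
    "write_experiment",
]

_EPOCH = pd.Timestamp("2025-06-01 08:00:00")  # arbitrary anchor; 08:00 = ZT0


@dataclass
class SimBehaviorParams:
    """Ground-truth parameters for one simulated animal.

    period_hours    endogenous period (h)
    rel_amplitude   modulation depth in [0, 1]; 0 is stationary Poisson
    baseline_rate   expected counts per minute at the daily mean
    acrophase_zt    ZT of the rate maximum (h); late photophase by default
    n_days          recorded days (day 1 is the adaptation day upstream
                    analysis discards, leaving the 4-day analysis window)
    bin_minutes     output bin width; counts are generated per minute
    masking_spike   extra expected counts in the first minute after lights-on
    regime          per-day light schedule
    """

    period_hours: float = 24.0
    rel_amplitude: float = 0.8
    baseline_rate: float = 0.05
    acrophase_zt: float = 10.0
    n_days: int = 5
    bin_minutes: int = 30
    masking_spike: float = 1.0
    regime: LightRegime | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_hours <= 0:
            raise ValueError("period_hours must be positive")
        if not 0.0 <= self.rel_amplitude <= 1.0:
            raise ValueError("rel_amplitude must lie in [0, 1] so the "
                             "Poisson rate stays nonnegative")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        if self.masking_spike < 0:
            raise ValueError("masking_spike must be nonnegative")
        if self.bin_minutes <= 0 or MINUTES_PER_DAY % self.bin_minutes:
            raise ValueError("bin_minutes must divide 1440")
        if self.regime is None:
            self.regime = LightRegime.constant("LD", self.n_days)


def minute_rate(params: SimBehaviorParams) -> np.ndarray:
    """Expected counts for every native 1-min slot (the Poisson mean)."""
    minutes = params.n_days * MINUTES_PER_DAY
    t_h = np.arange(minutes) / 60.0  # slot starts, hours from ZT0
    rate = params.baseline_rate * (
        1.0 + params.rel_amplitude
        * np.cos(2 * np.pi * (t_h - params.acrophase_zt) / params.period_hours))
    for on_h in params.regime.lights_on_times(params.n_days):
        slot = int(round(on_h * 60))
        if 0 <= slot < minutes:
            rate[slot] += params.masking_spike
    return rate


def simulate_locomotor_series(params: SimBehaviorParams,
                              animal_id: str = "sim") -> ActivitySeries:
    """Draw one animal's record; identical seeds give identical output."""
    rng = np.random.default_rng(params.seed)
    counts = rng.poisson(minute_rate(params)).astype(float)
    series = ActivitySeries(
        animal_id=animal_id,
        start=_EPOCH,
        bin_minutes=1,
        counts=counts,
        regime=params.regime,
        meta={"truth": {k: v for k, v in asdict(params).items()
                        if k != "regime"}},
    )
    return dam_io.bin_series(series, params.bin_minutes)


def simulate_cohort(n_animals: int,
                    params: SimBehaviorParams,
                    seed: int | None = None,
                    period_jitter_sd: float = 0.0,
                    amplitude_jitter_sd: float = 0.0,
                    prefix: str = "sim") -> list[ActivitySeries]:
    """Independent animals from shared parameters.

    Inter-individual variability is off by default (the study conditions
    state none); optional Gaussian jitter on period and relative amplitude
    (clipped to [0, 1]) is available for sensitivity work.
    """
    root = np.random.default_rng(params.seed if seed is None else seed)
    out = []
    for i in range(n_animals):
        sub = int(root.integers(0, 2**31 - 1))
        p = replace(params, seed=sub)
        if period_jitter_sd or amplitude_jitter_sd:
            jrng = np.random.default_rng(sub)
            p = replace(
                p,
                period_hours=max(params.period_hours
                                 + jrng.normal(0, period_jitter_sd), 1.0),
                rel_amplitude=float(np.clip(
                    params.rel_amplitude
                    + jrng.normal(0, amplitude_jitter_sd), 0.0, 1.0)),
            )
        out.append(simulate_locomotor_series(p, animal_id=f"{prefix}{i + 1:02d}"))
    return out


def apply_death(series: ActivitySeries, death_time_h: float) -> ActivitySeries:
    """Zero all counts from ``death_time_h`` (hours from start) onward.

    Emulates an animal dying mid-recording; the true death time is kept in
    metadata so survival trimming can be validated against it.
    """
    if not 0.0 <= death_time_h <= series.span_hours:
        raise ValueError(
            f"death_time_h={death_time_h} outside the series span "
            f"[0, {series.span_hours}]")
    first_dead = math.ceil(death_time_h * 60.0 / series.bin_minutes)
    counts = series.counts.copy()
    counts[first_dead:] = 0.0
    return series.with_counts(
        counts, meta={**series.meta, "true_death_h": death_time_h})


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

@dataclass
class SimExpressionParams:
    """Ground truth for a simulated diel expression time course.

    The model matches the analysis-side cosinor exactly:
    E(t) = cos(t/24*2pi + phase) * amplitude + shift, with phase in radians
    (phase pi/2 puts the peak at ZT18, the observed middle-of-night maximum
    of the rhythmic cryptochrome transcript).  Cts carry Gaussian noise of
    sd ``ct_noise_sd`` on the log2 scale.
    """

    amplitude: float = 1.0
    phase: float = math.pi / 2
    shift: float = 3.0
    timepoint_step_hours: float = 3.0
    n_replicates: int = 3
    ct_noise_sd: float = 0.2
    ref_ct: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.shift <= self.amplitude:
            raise ValueError("shift must exceed amplitude so expression "
                             "stays positive")
        if self.timepoint_step_hours <= 0:
            raise ValueError("timepoint_step_hours must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.ct_noise_sd < 0:
            raise ValueError("ct_noise_sd must be nonnegative")


def true_expression(params: SimExpressionParams, t_hours: np.ndarray) -> np.ndarray:
    """The noiseless expression curve E(t)."""
    t = np.asarray(t_hours, dtype=float)
    return (np.cos(t / 24.0 * 2 * np.pi + params.phase) * params.amplitude
            + params.shift)


def simulate_ct_table(params: SimExpressionParams,
                      n_days: int = 1,
                      target_gene: str = "cry2",
                      reference_genes: tuple[str, str] = ("actb", "gapdh"),
                      ) -> pd.DataFrame:
    """Ct table on the 3-h grid: target plus two reference genes.

    Target Ct = ref_ct − log2 E(t) + noise; reference Cts = ref_ct + noise
    (constitutive controls).  Columns follow the package CSV schema:
    sample_id, zeitgeber_time_h, gene, role, replicate, ct.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    rng = np.random.default_rng(params.seed)
    times = np.arange(0.0, 24.0 * n_days, params.timepoint_step_hours)
    rows = []
    for t in times:
        e_true = float(true_expression(params, np.array([t]))[0])
        sample = f"t{t:g}h"
        for rep in range(1, params.n_replicates + 1):
            ct_target = (params.ref_ct - math.log2(e_true)
                         + rng.normal(0.0, params.ct_noise_sd))
            rows.append((sample, t, target_gene, "target", rep, ct_target))
            for ref in reference_genes:
                rows.append((sample, t, ref, "reference", rep,
                             params.ref_ct + rng.normal(0.0, params.ct_noise_sd)))
    return pd.DataFrame(
        rows, columns=["sample_id", "zeitgeber_time_h", "gene", "role",
                       "replicate", "ct"])


# ---------------------------------------------------------------------------
# disk output
# ---------------------------------------------------------------------------

def write_experiment(out_dir: str | Path,
                     cohorts: dict[str, list[ActivitySeries]],
                     ct_tables: dict[str, pd.DataFrame],
                     truth: dict) -> None:
    """Write cohorts as monitor files + CSV, Ct tables as CSV, and a JSON
    sidecar with every ground-truth parameter and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, group in cohorts.items():
        if all(s.bin_minutes == 1 for s in group):
            dam_io.write_monitor_file(out / f"monitor_{name}.txt", group)
        dam_io.write_activity_csv(out / f"activity_{name}.csv", group)
    for gene, table in ct_tables.items():
        table.to_csv(out / f"ct_{gene}.csv", index=False)
    (out / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
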