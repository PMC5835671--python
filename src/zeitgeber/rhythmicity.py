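"""Rhythmicity analysis: correlogram, RI, MESA, classification, summaries.

Two independent period detectors are run on each animal's mean-subtracted
activity series:

* **Autocorrelation.**  The biased sample autocorrelation r(k) is scanned in
  the circadian lag band.  With the lag-0 peak counted as peak #1, the peak
  near one period is #2 (its lag is the reported period) and the peak near
  two periods is #3, whose height is the Rhythmicity Index (RI) — the
  strength-of-rhythm statistic.  The period peak is significant when it
  clears the white-noise confidence line ``conf_multiplier/sqrt(n)``.

* **MESA.**  Maximum entropy spectral analysis: an all-pole (autoregressive)
  model is fitted to the series and its power spectral density evaluated on
  a dense frequency grid.  The default fit is the forward-backward
  least-squares (modified covariance) estimator, which localizes weak
  sinusoids in counting noise markedly better than Burg's lattice recursion;
  Burg is available as an option and as the classical reference.  The band
  peak is significant when its power exceeds the 95th percentile of band
  peaks from shuffled (permutation) surrogates of the same series — the
  null that keeps the count distribution but destroys all temporal
  structure.

An animal is *rhythmic* only when both detectors agree; the reported period
is the autocorrelation one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .series import ActivitySeries

__all__ = [
    "AnalysisConfig",
    "Correlogram",
    "MesaSpectrum",
    "RhythmCall",
    "GroupSummary",
    "GroupComparison",
    "autocorrelogram",
    "ac_period_and_ri",
    "burg_ar",
    "mesa_spectrum",
    "mesa_period",
    "classify",
    "total_daily_activity",
    "summarize_group",
    "compare_groups",
    "p_to_stars",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Thresholds and knobs for the rhythmicity pipeline.

    band_h             circadian period search band (hours)
    conf_multiplier    white-noise confidence line c/sqrt(n) for the AC peak
    ri_peak_index      which correlogram peak carries the RI (lag-0 is #1,
                       so 3 puts RI near two periods)
    peak_smooth_h      moving-average width (hours) applied to the
                       correlogram before peak localization
    ar_method          "fb" (forward-backward least squares, default) or
                       "burg"
    ar_order           AR order; None -> n//3 capped at 100; "aic"
                       -> minimum-AIC Burg order up to that cap
    n_surrogates       shuffle surrogates for MESA significance
    surrogate_quantile significance quantile of the surrogate band peaks
    n_freq             frequency-grid size over the 4-40 h period range
    max_lag_h          correlogram reach; None -> min(2.2*band_hi, span-1bin)
    bin_minutes        analysis bin width applied upstream
    detrend            subtract a linear trend (default: mean only)
    """

    band_h: tuple[float, float] = (18.0, 30.0)
    conf_multiplier: float = 2.0
    ri_peak_index: int = 3
    peak_smooth_h: float = 2.5
    ar_method: str = "fb"
    ar_order: int | str | None = None
    n_surrogates: int = 200
    surrogate_quantile: float = 0.95
    n_freq: int = 1024
    max_lag_h: float | None = None
    bin_minutes: int = 30
    detrend: bool = False
    seed: int = 0


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class Correlogram:
    """Sample autocorrelation by lag, with its white-noise confidence line."""

    lags_h: np.ndarray
    r: np.ndarray
    n: int
    conf_limit: float

    @property
    def bin_hours(self) -> float:
        return float(self.lags_h[1] - self.lags_h[0])


@dataclass
class MesaSpectrum:
    """Fitted AR model and its power spectral density.

    ``ar_coefficients`` follow the prediction convention
    x_t = sum_j a_j x_{t-j} + e_t, so
    power(f) = noise_variance * dt / |1 - sum_j a_j exp(-i 2 pi f j dt)|^2.
    """

    ar_order: int
    ar_coefficients: np.ndarray
    noise_variance: float
    frequencies: np.ndarray  # cycles per hour
    power: np.ndarray
    dt_h: float

    @property
    def periods_h(self) -> np.ndarray:
        return 1.0 / self.frequencies


@dataclass
class RhythmCall:
    """Per-animal rhythmicity classification."""

    animal_id: str
    rhythmic: bool
    period_ac_h: float | None
    period_mesa_h: float | None
    rhythmicity_index: float
    total_activity_per_day: float
    ac_significant: bool = False
    mesa_significant: bool = False

    def to_dict(self) -> dict:
        return {
            "animal_id": self.animal_id,
            "rhythmic": self.rhythmic,
            "period_ac_h": self.period_ac_h,
            "period_mesa_h": self.period_mesa_h,
            "rhythmicity_index": self.rhythmicity_index,
            "total_activity_per_day": self.total_activity_per_day,
            "ac_significant": self.ac_significant,
            "mesa_significant": self.mesa_significant,
        }


@dataclass
class GroupSummary:
    """One summary-table row: percent rhythmic plus mean ± SEM columns."""

    label: str
    n: int
    n_rhythmic: int
    percent_rhythmic: float
    mean_sem_activity: tuple[float, float]
    mean_sem_period: tuple[float, float] | None
    mean_sem_ri: tuple[float, float] | None

    def to_row(self) -> dict:
        def fmt(pair):
            if pair is None or not np.isfinite(pair[0]):
                return ""
            return f"{pair[0]:.2f} ± {pair[1]:.2f}"
        return {
            "group": self.label,
            "rhythmic_pct_n": f"{self.percent_rhythmic:.2f}/{self.n}",
            "total_activity_per_day": fmt(self.mean_sem_activity),
            "period_h": fmt(self.mean_sem_period),
            "ri": fmt(self.mean_sem_ri),
        }


# ---------------------------------------------------------------------------
# autocorrelation
# ---------------------------------------------------------------------------

def _prepare(series: ActivitySeries, detrend: bool) -> np.ndarray:
    x = np.asarray(series.counts, dtype=float)
    if np.isnan(x).any():
        raise ValueError(
            f"{series.animal_id}: series has missing bins; interpolate first")
    if detrend:
        t = np.arange(x.size)
        b, a = np.polyfit(t, x, 1)
        x = x - (b * t + a)
    return x - x.mean()


def autocorrelogram(series: ActivitySeries, max_lag_h: float,
                    conf_multiplier: float = 2.0,
                    detrend: bool = False) -> Correlogram:
    """Biased sample autocorrelation up to ``max_lag_h``.

    r(k) = sum_t (x_t - xbar)(x_{t+k} - xbar) / sum_t (x_t - xbar)^2, the
    biased normalization (divisor n at every lag), so r tapers toward zero
    at long lags and the correlogram of a pure cosine is (1 - k/n) cos(wk).
    The confidence line is ``conf_multiplier / sqrt(n)``, the usual 95%
    white-noise band for multiplier 2.
    """
    x = _prepare(series, detrend)
    n = x.size
    denom = float(np.dot(x, x))
    if denom == 0.0:
        raise ValueError(f"{series.animal_id}: zero-variance series, "
                         "correlogram undefined")
    bin_h = series.bin_minutes / 60.0
    max_k = int(round(max_lag_h / bin_h))
    if max_k >= n:
        raise ValueError("max_lag_h must be shorter than the series span")
    full = np.correlate(x, x, mode="full")[n - 1:]  # lags 0..n-1
    r = full[: max_k + 1] / denom
    return Correlogram(
        lags_h=np.arange(max_k + 1) * bin_h,
        r=r, n=n, conf_limit=conf_multiplier / np.sqrt(n))


def _parabolic_apex(y: np.ndarray, i: int) -> tuple[float, float]:
    """Sub-bin apex (offset in bins, height) of a local max at index i."""
    if i <= 0 or i >= y.size - 1:
        return 0.0, float(y[i])
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom >= 0:  # not locally concave; keep the sample
        return 0.0, float(y[i])
    d = 0.5 * (y[i - 1] - y[i + 1]) / denom
    h = y[i] - 0.25 * (y[i - 1] - y[i + 1]) * d
    return float(d), float(h)


def _band_peak(x_axis: np.ndarray, y: np.ndarray,
               band: tuple[float, float],
               prefer: float | None = None) -> tuple[float, float] | None:
    """Highest strict interior local maximum of y with x in band.

    Returns (x_apex, height) with parabolic interpolation, or None when the
    in-band maximum sits on a band edge without being a true local peak
    (monotone spectra/correlograms carry no band peak).  Ties in height are
    broken toward ``prefer`` on the x axis.
    """
    lo, hi = band
    inside = np.where((x_axis >= lo) & (x_axis <= hi))[0]
    if inside.size == 0:
        return None
    seg = y[inside]
    candidates = inside[seg == seg.max()]
    if prefer is not None and candidates.size > 1:  # tie-break toward prefer
        candidates = candidates[np.argsort(np.abs(x_axis[candidates] - prefer))]
    step = float(x_axis[1] - x_axis[0])
    for i in candidates:
        if 0 < i < y.size - 1 and y[i] >= y[i - 1] and y[i] >= y[i + 1] \
                and (y[i] > y[i - 1] or y[i] > y[i + 1]):
            off, h = _parabolic_apex(y, i)
            return float(x_axis[i] + off * step), h
    return None


def _smooth_ma(y: np.ndarray, width_bins: int) -> np.ndarray:
    if width_bins <= 1:
        return y
    k = np.ones(width_bins) / width_bins
    return np.convolve(y, k, mode="same")


def _refine_period_fit(c: Correlogram, period0: float,
                       band_h: tuple[float, float],
                       halfwidth_h: float = 3.0,
                       grid_h: float = 0.02) -> float:
    """Refine a period by fitting the biased-estimator closed form.

    For a sinusoidal signal the biased correlogram is
    A*(1 - k/T)*cos(2*pi*k/P) (T the series span); fitting that template
    over all lags beyond the short-lag transient pools information from the
    whole correlogram instead of a single noisy peak apex.
    """
    span_h = c.n * c.bin_hours
    use = c.lags_h >= band_h[0] / 3.0
    k = c.lags_h[use]
    y = c.r[use]
    damp = 1.0 - k / span_h
    lo = max(band_h[0], period0 - halfwidth_h)
    hi = min(band_h[1], period0 + halfwidth_h)
    best_p, best_rss = period0, np.inf
    for p in np.arange(lo, hi + grid_h / 2, grid_h):
        basis = damp * np.cos(2 * np.pi * k / p)
        denom = float(basis @ basis)
        if denom == 0.0:
            continue
        amp = float(basis @ y) / denom
        resid = y - amp * basis
        rss = float(resid @ resid)
        if rss < best_rss:
            best_rss, best_p = rss, float(p)
    return best_p


def ac_period_and_ri(c: Correlogram,
                     band_h: tuple[float, float] = (18.0, 30.0),
                     ri_peak_index: int = 3,
                     peak_smooth_h: float = 2.5,
                     refine: bool = True,
                     ) -> tuple[float | None, float, bool]:
    """Period, RI and significance from a correlogram.

    The period peak (#2, with lag 0 as #1) is the dominant interior local
    maximum inside ``band_h`` of the lightly smoothed correlogram; its lag,
    refined by a closed-form template fit over the full lag range, is the
    period.  The peak is significant when the raw correlogram apex there
    clears the confidence line.  The RI peak (#``ri_peak_index``) is sought
    in the band scaled by ``ri_peak_index − 1`` (near two periods for the
    default 3); RI is its raw-correlogram height, 0 when no such peak
    exists.  Returns ``(None, 0.0, False)`` when no period peak lies in
    band.
    """
    width = max(1, int(round(peak_smooth_h / c.bin_hours)))
    width += 1 - width % 2  # odd, centered
    smooth = _smooth_ma(c.r, width)

    peak = _band_peak(c.lags_h, smooth, band_h, prefer=24.0)
    if peak is None:
        return None, 0.0, False
    period = peak[0]
    idx = int(round(period / c.bin_hours))
    _, raw_height = _parabolic_apex(c.r, min(idx, c.r.size - 1))
    significant = bool(raw_height > c.conf_limit)
    if refine:
        period = _refine_period_fit(c, period, band_h)

    m = ri_peak_index - 1  # harmonic multiple carrying the RI
    ri_band = (m * band_h[0], m * band_h[1])
    ri_peak = _band_peak(c.lags_h, smooth, ri_band, prefer=m * period)
    ri = 0.0
    if ri_peak is not None:
        ri_idx = int(round(ri_peak[0] / c.bin_hours))
        _, ri = _parabolic_apex(c.r, min(ri_idx, c.r.size - 1))
    return float(period), float(ri), significant


# ---------------------------------------------------------------------------
# MESA (Burg)
# ---------------------------------------------------------------------------

def burg_ar(x: np.ndarray, order: int,
            return_all: bool = False):
    """Burg's recursion for AR coefficients and noise variance.

    Fits x_t = sum_{j=1..p} a_j x_{t-j} + e_t by minimizing forward plus
    backward prediction error, which guarantees a stable all-pole model —
    the maximum-entropy spectral estimate for a process known only through
    its first p sample autocorrelations.

    Returns ``(a, sigma2)`` with ``a`` of length ``order``; with
    ``return_all`` also the per-order noise variances (for AIC selection).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if not 0 < order < n:
        raise ValueError(f"order must satisfy 0 < order < n (got {order}, n={n})")
    ef = x.copy()
    eb = x.copy()
    a = np.array([1.0])  # error-filter polynomial [1, -a_1, ..., -a_p]
    e = float(np.dot(x, x)) / n
    variances = [e]
    for m in range(order):
        efp = ef[1:]
        ebp = eb[:-1]
        den = float(np.dot(efp, efp) + np.dot(ebp, ebp))
        if den <= 0.0:
            raise FloatingPointError(
                f"Burg recursion became degenerate at order {m + 1}")
        k = -2.0 * float(np.dot(ebp, efp)) / den
        a = np.concatenate([a, [0.0]])
        a = a + k * a[::-1]
        e *= (1.0 - k * k)
        ef = efp + k * ebp
        eb = ebp + k * efp
        variances.append(e)
        if not np.isfinite(e) or e < 0:
            raise FloatingPointError(
                f"Burg recursion unstable at order {m + 1}")
    coeffs = -a[1:]  # prediction convention
    if return_all:
        return coeffs, e, np.array(variances)
    return coeffs, e


def modcov_ar(x: np.ndarray, order: int) -> tuple[np.ndarray, float]:
    """Forward-backward least-squares AR fit (modified covariance method).

    Minimizes the summed forward and backward prediction error without
    Burg's lattice constraint, which makes it markedly more accurate than
    Burg at locating weak sinusoids in counting noise (at the price of not
    guaranteeing pole stability — irrelevant for PSD peak reading).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if not 0 < order <= (n - order):
        raise ValueError(
            f"order must satisfy 0 < order <= n - order (got {order}, n={n})")
    fwd = np.column_stack([x[order - 1 - j: n - 1 - j] for j in range(order)])
    bwd = np.column_stack([x[1 + j: n - order + 1 + j] for j in range(order)])
    design = np.vstack([fwd, bwd])
    target = np.concatenate([x[order:], x[: n - order]])
    coeffs, *_ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ coeffs
    sigma2 = float(resid @ resid) / target.size
    return coeffs, sigma2


def _default_order(n: int) -> int:
    return max(1, min(n // 3, 100))


def _ar_psd(coeffs: np.ndarray, sigma2: float, freqs: np.ndarray,
            dt_h: float) -> np.ndarray:
    j = np.arange(1, coeffs.size + 1)
    # A(f) = 1 - sum_j a_j exp(-i 2 pi f j dt)
    phases = np.exp(-2j * np.pi * np.outer(freqs, j) * dt_h)
    a_f = 1.0 - phases @ coeffs.astype(complex)
    return sigma2 * dt_h / np.abs(a_f) ** 2


def _freq_grid(n_freq: int, period_range_h: tuple[float, float] = (4.0, 40.0)
               ) -> np.ndarray:
    lo, hi = period_range_h
    return np.linspace(1.0 / hi, 1.0 / lo, n_freq)


def mesa_spectrum(series: ActivitySeries,
                  ar_order: int | str | None = None,
                  n_freq: int = 1024,
                  detrend: bool = False,
                  method: str = "fb") -> MesaSpectrum:
    """All-pole (AR) power spectral density of a series.

    The grid spans periods 4-40 h, comfortably covering the 18-30 h
    circadian search band.  ``ar_order=None`` uses n//3 capped at 100
    (common chronobiology practice for short, noisy records); ``"aic"``
    picks the minimum-AIC Burg order up to that cap.  ``method`` selects the
    forward-backward least-squares fit (``"fb"``, default — best period
    localization at low count rates) or the classical Burg recursion
    (``"burg"``).
    """
    if method not in ("fb", "burg"):
        raise ValueError(f"unknown AR method {method!r}")
    fit = modcov_ar if method == "fb" else burg_ar
    x = _prepare(series, detrend)
    n = x.size
    cap = _default_order(n)
    if ar_order is None:
        order = cap
        coeffs, sigma2 = fit(x, order)
    elif ar_order == "aic":
        _, _, variances = burg_ar(x, cap, return_all=True)
        orders = np.arange(cap + 1)
        with np.errstate(divide="ignore"):
            aic = n * np.log(variances) + 2 * orders
        order = max(int(np.argmin(aic)), 1)
        coeffs, sigma2 = fit(x, order)
    else:
        order = int(ar_order)
        coeffs, sigma2 = fit(x, order)
    dt_h = series.bin_minutes / 60.0
    freqs = _freq_grid(n_freq)
    power = _ar_psd(coeffs, sigma2, freqs, dt_h)
    return MesaSpectrum(ar_order=order, ar_coefficients=coeffs,
                        noise_variance=sigma2, frequencies=freqs,
                        power=power, dt_h=dt_h)


def mesa_period(s: MesaSpectrum,
                band_h: tuple[float, float] = (18.0, 30.0),
                ) -> tuple[float | None, float]:
    """Dominant in-band spectral period and its peak power.

    Returns ``(None, 0.0)`` when the in-band maximum is not an interior
    local peak (e.g. a monotone spectrum leaking in from outside the band).
    """
    # work on the period axis restricted to the band
    peak = _band_peak(s.frequencies, s.power,
                      (1.0 / band_h[1], 1.0 / band_h[0]),
                      prefer=1.0 / 24.0)
    if peak is None:
        return None, 0.0
    f_apex, height = peak
    return 1.0 / f_apex, float(height)


def mesa_significance(series: ActivitySeries,
                      observed_peak_power: float,
                      ar_order: int,
                      band_h: tuple[float, float] = (18.0, 30.0),
                      n_surrogates: int = 200,
                      quantile: float = 0.95,
                      n_freq: int = 256,
                      rng: np.random.Generator | None = None,
                      detrend: bool = False,
                      method: str = "fb") -> bool:
    """Permutation-surrogate test of the MESA band peak.

    Shuffling the bins keeps the count distribution but destroys all
    temporal structure, so surrogate spectra carry only chance band peaks;
    the observed peak is significant when it exceeds the ``quantile`` of
    the surrogate band-peak distribution.
    """
    rng = rng or np.random.default_rng(0)
    fit = modcov_ar if method == "fb" else burg_ar
    x = _prepare(series, detrend)
    dt_h = series.bin_minutes / 60.0
    freqs = _freq_grid(n_freq)
    in_band = (freqs >= 1.0 / band_h[1]) & (freqs <= 1.0 / band_h[0])
    peaks = np.empty(n_surrogates)
    for i in range(n_surrogates):
        xs = rng.permutation(x)
        try:
            coeffs, sigma2 = fit(xs, ar_order)
        except (FloatingPointError, np.linalg.LinAlgError):
            peaks[i] = np.inf  # degenerate surrogate counts against us
            continue
        peaks[i] = _ar_psd(coeffs, sigma2, freqs[in_band], dt_h).max()
    return bool(observed_peak_power > np.quantile(peaks, quantile))


# ---------------------------------------------------------------------------
# classification and activity
# ---------------------------------------------------------------------------

def total_daily_activity(series: ActivitySeries, n_days: int = 4) -> float:
    """Average counts per 24 h over the first ``n_days`` complete days."""
    bpd = series.bins_per_day
    need = n_days * bpd
    if series.n_bins < need:
        raise ValueError(
            f"{series.animal_id}: need {n_days} complete days, have "
            f"{series.n_bins / bpd:.2f}")
    window = series.counts[:need]
    return float(np.nansum(window) / n_days)


def classify(series: ActivitySeries,
             config: AnalysisConfig | None = None,
             rng: np.random.Generator | None = None) -> RhythmCall:
    """Dual-criterion rhythmicity call for one hygiene-passed series.

    Rhythmic iff the autocorrelation period peak clears the confidence line
    AND the MESA band peak beats its surrogate threshold.  The reported
    period is the autocorrelation one (MESA corroborates); RI is always
    reported as the strength of rhythm.
    """
    cfg = config or AnalysisConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    bin_h = series.bin_minutes / 60.0
    max_lag = cfg.max_lag_h
    if max_lag is None:
        max_lag = min(2.2 * cfg.band_h[1], series.span_hours - bin_h)

    c = autocorrelogram(series, max_lag, cfg.conf_multiplier, cfg.detrend)
    period_ac, ri, ac_sig = ac_period_and_ri(
        c, cfg.band_h, cfg.ri_peak_index, cfg.peak_smooth_h)

    spec = mesa_spectrum(series, cfg.ar_order, cfg.n_freq, cfg.detrend,
                         method=cfg.ar_method)
    period_mesa, peak_power = mesa_period(spec, cfg.band_h)
    mesa_sig = False
    if period_mesa is not None and cfg.n_surrogates > 0:
        mesa_sig = mesa_significance(
            series, peak_power, spec.ar_order, cfg.band_h,
            cfg.n_surrogates, cfg.surrogate_quantile, rng=rng,
            detrend=cfg.detrend, method=cfg.ar_method)

    rhythmic = bool(ac_sig and mesa_sig)
    return RhythmCall(
        animal_id=series.animal_id,
        rhythmic=rhythmic,
        period_ac_h=period_ac if ac_sig else None,
        period_mesa_h=period_mesa if mesa_sig else None,
        rhythmicity_index=float(ri),
        total_activity_per_day=total_daily_activity(series),
        ac_significant=ac_sig,
        mesa_significant=mesa_sig,
    )


# ---------------------------------------------------------------------------
# group summaries and comparisons
# ---------------------------------------------------------------------------

def _mean_sem(values: Sequence[float]) -> tuple[float, float]:
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        return float("nan"), float("nan")
    sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
    return float(v.mean()), sem


def summarize_group(calls: Sequence[RhythmCall], label: str = "") -> GroupSummary:
    """Table-row summary: percent rhythmic over all animals; activity over
    all animals; period and RI over rhythmic animals only."""
    if not calls:
        raise ValueError("empty group")
    n = len(calls)
    rhythmic = [c for c in calls if c.rhythmic]
    pct = round(100.0 * len(rhythmic) / n, 2)
    periods = [c.period_ac_h for c in rhythmic if c.period_ac_h is not None]
    ris = [c.rhythmicity_index for c in rhythmic]
    return GroupSummary(
        label=label, n=n, n_rhythmic=len(rhythmic), percent_rhythmic=pct,
        mean_sem_activity=_mean_sem([c.total_activity_per_day for c in calls]),
        mean_sem_period=_mean_sem(periods) if periods else None,
        mean_sem_ri=_mean_sem(ris) if ris else None,
    )


def p_to_stars(p: float) -> str:
    """Figure-legend star codes at 0.05 / 0.01 / 0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupComparison:
    """ANOVA/Tukey (>=3 groups) or Welch t (2 groups) comparison report."""

    method: str
    statistic: float
    p_value: float
    stars: str
    letters: dict[str, str] | None = None
    pairwise: list[dict] = field(default_factory=list)


def _compact_letters(groups: list[str],
                     sig_pairs: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups NOT significantly different may share a letter; each significant
    pair must differ in at least one letter.
    """
    classes: list[set[str]] = [set(groups)]
    for a, b in sig_pairs:
        new: list[set[str]] = []
        for cls in classes:
            if a in cls and b in cls:
                new.append(cls - {a})
                new.append(cls - {b})
            else:
                new.append(cls)
        # absorb subsets and duplicates
        classes = []
        for cls in sorted(new, key=len, reverse=True):
            if cls and not any(cls <= kept for kept in classes):
                classes.append(cls)
    # stable letter order: by first group each class contains
    classes.sort(key=lambda cls: min(groups.index(g) for g in cls))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for letter, cls in zip(alphabet, classes):
        for g in groups:
            if g in cls:
                out[g] += letter
    return out


def compare_groups(groups: Mapping[str, Sequence[float]],
                   alpha: float = 0.05) -> GroupComparison:
    """Omnibus + post-hoc comparison matching the study's statistics.

    Two groups: Welch's t-test.  Three or more: one-way ANOVA with Tukey HSD
    pairwise letters at ``alpha``.  All-identical data short-circuits to
    "no difference" (the F statistic is 0/0 there).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(list(v), dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ValueError(f"group {k!r} needs n >= 2")

    pooled = np.concatenate(list(arrays.values()))
    if np.ptp(pooled) == 0.0:  # degenerate: every value identical
        letters = {k: "a" for k in names}
        method = "welch_t" if len(names) == 2 else "anova_tukey"
        return GroupComparison(method, 0.0, 1.0, "ns", letters)

    if len(names) == 2:
        t, p = sps.ttest_ind(arrays[names[0]], arrays[names[1]],
                             equal_var=False)
        sig = p < alpha
        letters = {names[0]: "a", names[1]: "b" if sig else "a"}
        return GroupComparison("welch_t", float(t), float(p), p_to_stars(p),
                               letters,
                               [{"a": names[0], "b": names[1],
                                 "p": float(p), "significant": bool(sig)}])

    f, p = sps.f_oneway(*arrays.values())
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    values = np.concatenate([arrays[k] for k in names])
    labels = np.concatenate([[k] * arrays[k].size for k in names])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairwise = []
    sig_pairs: set[tuple[str, str]] = set()
    res = tukey.summary().data[1:]
    for row in res:
        a, b, _, p_adj, *_rest, reject = row
        pairwise.append({"a": str(a), "b": str(b), "p": float(p_adj),
                         "significant": bool(reject)})
        if reject:
            sig_pairs.add((str(a), str(b)))
    letters = _compact_letters(names, sig_pairs)
    return GroupComparison("anova_tukey", float(f), float(p), p_to_stars(p),
                           letters, pairwise)
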