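"""qPCR relative quantification and cosinor analysis of diel expression.

Relative quantities follow the 2^−ΔΔCt method with two constitutive
reference genes (β-actin and GAPDH): their Cts are averaged per
sample-replicate before ΔCt — equivalent to a geometric mean of the linear
reference quantities — and the linear quantity 2^−ΔCt is scaled by the
replicate-mean linear quantity of a calibrator sample (default: the ZT0
sample), so the calibrator's mean RQ is exactly 1.

Rhythmicity of a time course is assessed two ways, as in diel expression
studies: a one-way ANOVA across Zeitgeber times (with Tukey letters), and a
least-squares cosinor fit of the fixed-24-h model

    value = amplitude * cos(2*pi*t/24 + phase) + shift

via the linearization value = b1*cos(wt) + b2*sin(wt) + shift, from which
amplitude = hypot(b1, b2) and phase = atan2(-b2, b1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .rhythmicity import GroupComparison, compare_groups, p_to_stars

__all__ = [
    "CT_COLUMNS",
    "validate_ct_table",
    "RQSeries",
    "relative_expression",
    "CosinorFit",
    "fit_cosinor",
    "cosinor_curve",
    "ExpressionRhythmReport",
    "rhythm_anova",
    "knockdown_contrast",
]

CT_COLUMNS = ("sample_id", "zeitgeber_time_h", "gene", "role", "replicate", "ct")


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if not set(table["role"]).issubset({"target", "reference"}):
        raise ValueError("role must be 'target' or 'reference'")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return table


@dataclass
class RQSeries:
    """Relative quantities per (timepoint, replicate) for one target gene.

    ``calibrator_scale`` is the calibrator's mean linear quantity
    (mean over its replicates of 2^−ΔCt) the series was divided by; feeding
    it to :func:`relative_expression` for a second table puts both series
    on one scale (required for between-group contrasts).
    """

    data: pd.DataFrame  # columns: sample_id, zeitgeber_time_h, replicate, rq
    gene: str
    calibrator_id: str
    calibrator_scale: float = 1.0

    @property
    def timepoints(self) -> np.ndarray:
        return np.sort(self.data["zeitgeber_time_h"].unique())

    def values_at(self, t: float) -> np.ndarray:
        return self.data.loc[self.data["zeitgeber_time_h"] == t, "rq"].to_numpy()


def relative_expression(table: pd.DataFrame,
                        gene: str | None = None,
                        calibrator_sample: str | None = None,
                        calibrator_scale: float | None = None) -> RQSeries:
    """2^−ΔΔCt relative quantities against a calibrator sample.

    ΔCt = Ct_target − mean(Ct_references) per sample-replicate; the linear
    quantity 2^−ΔCt is then divided by the calibrator's replicate-mean
    linear quantity, so the calibrator's mean RQ is exactly 1 (with a
    single calibrator replicate this is identical to RQ = 2^−ΔΔCt).
    Replicates lacking a reference measurement are dropped with a warning.
    Passing ``calibrator_scale`` (from another series) normalizes against
    that external calibrator instead, putting two groups on a common scale.
    """
    table = validate_ct_table(table)
    targets = table[table["role"] == "target"]
    if gene is None:
        genes = targets["gene"].unique()
        if len(genes) != 1:
            raise ValueError(f"table holds several target genes {list(genes)}; "
                             "pass gene=")
        gene = genes[0]
    targets = targets[targets["gene"] == gene]
    if targets.empty:
        raise ValueError(f"no target records for gene {gene!r}")

    refs = (table[table["role"] == "reference"]
            .groupby(["sample_id", "replicate"])["ct"].mean())
    rows = []
    for rec in targets.itertuples():
        key = (rec.sample_id, rec.replicate)
        if key not in refs.index:
            warnings.warn(
                f"sample {rec.sample_id} replicate {rec.replicate}: no "
                "reference Ct; replicate dropped", stacklevel=2)
            continue
        rows.append((rec.sample_id, rec.zeitgeber_time_h, rec.replicate,
                     rec.ct - refs[key]))
    dct = pd.DataFrame(rows, columns=["sample_id", "zeitgeber_time_h",
                                      "replicate", "dct"])
    if dct.empty:
        raise ValueError("no target replicate has a matching reference Ct")

    q = np.power(2.0, -dct["dct"])
    if calibrator_scale is not None:
        scale = float(calibrator_scale)
        calibrator_sample = "<external>"
    else:
        if calibrator_sample is None:  # earliest timepoint = the ZT0 sample
            calibrator_sample = dct.loc[dct["zeitgeber_time_h"].idxmin(),
                                        "sample_id"]
        cal = q[dct["sample_id"] == calibrator_sample]
        if cal.empty:
            raise ValueError(
                f"calibrator sample {calibrator_sample!r} not found")
        scale = float(cal.mean())
    out = dct.drop(columns="dct").assign(rq=q / scale)
    return RQSeries(data=out, gene=gene, calibrator_id=str(calibrator_sample),
                    calibrator_scale=scale)


# ---------------------------------------------------------------------------
# cosinor
# ---------------------------------------------------------------------------

@dataclass
class CosinorFit:
    """Least-squares fit of the fixed-24-h cosine model."""

    amplitude: float
    phase: float  # radians in (-pi, pi]
    shift: float  # mesor
    rss: float
    r_squared: float
    fitted_period_h: float = 24.0

    @property
    def acrophase_zt(self) -> float:
        """ZT (hours) at which the fitted curve peaks."""
        return (-self.phase * self.fitted_period_h / (2 * np.pi)) % self.fitted_period_h

    def predict(self, t_hours: np.ndarray) -> np.ndarray:
        t = np.asarray(t_hours, dtype=float)
        return (self.amplitude
                * np.cos(2 * np.pi * t / self.fitted_period_h + self.phase)
                + self.shift)


def fit_cosinor(times_h, values, period_h: float = 24.0) -> CosinorFit:
    """Fit value = amplitude*cos(2*pi*t/P + phase) + shift by least squares.

    Requires >= 4 observations at >= 3 distinct phases of the cycle so the
    (cos, sin, intercept) design has full rank.  Constant data fit as
    amplitude 0 with r_squared defined as 0.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("times_h and values must be equal-length 1-D arrays")
    if np.unique(t).size < 4:
        raise ValueError("need at least 4 distinct timepoints")
    w = 2 * np.pi / period_h
    design = np.column_stack([np.cos(w * t), np.sin(w * t), np.ones_like(t)])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("rank-deficient design: timepoints collapse onto "
                         "too few phases of the cycle")
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    b1, b2, shift = beta
    amplitude = float(np.hypot(b1, b2))
    phase = float(math.atan2(-b2, b1)) if amplitude > 0 else 0.0
    resid = y - design @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    return CosinorFit(amplitude=amplitude, phase=phase, shift=float(shift),
                      rss=rss, r_squared=float(min(max(r2, 0.0), 1.0)),
                      fitted_period_h=period_h)


def cosinor_curve(fit: CosinorFit, step_h: float = 1.0,
                  span_h: float = 24.0) -> pd.DataFrame:
    """Hourly-sampled fitted curve for plotting overlays."""
    t = np.arange(0.0, span_h + step_h / 2, step_h)
    return pd.DataFrame({"time_h": t, "fitted": fit.predict(t)})


# ---------------------------------------------------------------------------
# rhythm assessment and contrasts
# ---------------------------------------------------------------------------

@dataclass
class ExpressionRhythmReport:
    """Per-gene diel rhythmicity: ANOVA across times + cosinor fit."""

    gene: str
    anova: GroupComparison
    cosinor: CosinorFit
    significant_time_effect: bool
    fragile: bool = False  # significance hinges on a single replicate

    def to_dict(self) -> dict:
        return {
            "gene": self.gene,
            "anova_F": self.anova.statistic,
            "anova_p": self.anova.p_value,
            "tukey_letters": self.anova.letters,
            "significant_time_effect": self.significant_time_effect,
            "fragile": self.fragile,
            "cosinor": {
                "amplitude": self.cosinor.amplitude,
                "phase_rad": self.cosinor.phase,
                "acrophase_zt": self.cosinor.acrophase_zt,
                "shift": self.cosinor.shift,
                "r_squared": self.cosinor.r_squared,
            },
        }


def rhythm_anova(rq: RQSeries, alpha: float = 0.05) -> ExpressionRhythmReport:
    """ANOVA across Zeitgeber times combined with the cosinor fit.

    A leave-one-out pass flags "fragile" significance: if dropping any
    single replicate observation lifts the ANOVA p above ``alpha``, the time
    effect is likely driven by one outlier rather than a shared waveform.
    """
    df = rq.data
    times = rq.timepoints
    if times.size < 3:
        raise ValueError("need >= 3 timepoints")
    groups = {f"t{t:g}": df.loc[df["zeitgeber_time_h"] == t, "rq"].to_numpy()
              for t in times}
    if any(v.size < 2 for v in groups.values()):
        raise ValueError("every timepoint needs >= 2 replicates")
    comp = compare_groups(groups, alpha=alpha)
    significant = comp.p_value < alpha

    fragile = False
    if significant:
        for i in range(len(df)):
            sub = df.drop(df.index[i])
            loo = [sub.loc[sub["zeitgeber_time_h"] == t, "rq"].to_numpy()
                   for t in times]
            if any(len(g) < 2 for g in loo):
                continue
            if np.ptp(np.concatenate(loo)) == 0:
                p = 1.0
            else:
                p = sps.f_oneway(*loo).pvalue
            if p >= alpha:
                fragile = True
                break

    fit = fit_cosinor(df["zeitgeber_time_h"], df["rq"])
    return ExpressionRhythmReport(
        gene=rq.gene, anova=comp, cosinor=fit,
        significant_time_effect=bool(significant), fragile=fragile)


def knockdown_contrast(rq_treated: RQSeries, rq_control: RQSeries,
                       timepoints=None) -> pd.DataFrame:
    """Welch t-test per timepoint plus knockdown efficiency.

    Efficiency = 1 − mean(RQ_treated)/mean(RQ_control); stars follow the
    0.05/0.01/0.001 figure-legend codes.  Both series must cover the
    requested timepoints and must share a calibrator scale (compute the
    treated series with ``calibrator_scale=control.calibrator_scale``).
    """
    if timepoints is None:
        timepoints = rq_treated.timepoints
        if not np.array_equal(np.sort(timepoints),
                              np.sort(rq_control.timepoints)):
            raise ValueError("series have mismatched timepoints; pass "
                             "timepoints= explicitly")
    rows = []
    for t in timepoints:
        a = rq_treated.values_at(t)
        b = rq_control.values_at(t)
        if a.size == 0 or b.size == 0:
            raise ValueError(f"timepoint {t} missing from one series")
        if np.ptp(np.concatenate([a, b])) == 0:
            tstat, p = 0.0, 1.0
        else:
            tstat, p = sps.ttest_ind(a, b, equal_var=False)
        eff = 1.0 - a.mean() / b.mean()
        rows.append((t, a.mean(), b.mean(), eff, float(tstat), float(p),
                     p_to_stars(p) if p < 0.05 else ""))
    return pd.DataFrame(rows, columns=[
        "zeitgeber_time_h", "mean_treated", "mean_control",
        "knockdown_efficiency", "t", "p", "stars"])
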