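"""Correlogram, RI, MESA and classification against independent oracles."""

import numpy as np
import pytest
from scipy.signal import lfilter

from zeitgeber import dam_io, synthetic
from zeitgeber.light import LightRegime
from zeitgeber.rhythmicity import (AnalysisConfig, ac_period_and_ri,
                                   autocorrelogram, burg_ar, classify,
                                   compare_groups, mesa_period, mesa_spectrum,
                                   modcov_ar, p_to_stars, summarize_group,
                                   total_daily_activity, RhythmCall)

from conftest import cosine_series, make_series


def brute_force_acf(x, max_k):
    """O(n^2) biased autocorrelation: the independent oracle."""
    x = np.asarray(x, float) - np.mean(x)
    denom = np.sum(x * x)
    out = np.empty(max_k + 1)
    for k in range(max_k + 1):
        acc = 0.0
        for t in range(len(x) - k):
            acc += x[t] * x[t + k]
        out[k] = acc / denom
    return out


class TestCorrelogram:
    def test_lag_zero_is_one(self, rhythm_series):
        c = autocorrelogram(rhythm_series, 48.0)
        assert c.r[0] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(50, 200))
            x = rng.poisson(2.0, n).astype(float)
            if x.std() == 0:
                continue
            s = make_series(x, bin_minutes=30)
            max_k = n // 3
            c = autocorrelogram(s, max_k * 0.5)
            np.testing.assert_allclose(c.r, brute_force_acf(x, max_k),
                                       atol=1e-12)

    def test_pure_cosine_closed_form(self):
        # r(k) = (1 - k/n) cos(2 pi k / P) for the biased estimator
        s = cosine_series(period_h=24.0, bin_h=0.5, n_days=6)
        c = autocorrelogram(s, 66.0)
        assert c.r[96] == pytest.approx((1 - 96 / 288), abs=0.02)
        assert c.n == 288 and c.conf_limit == pytest.approx(2 / np.sqrt(288))

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            autocorrelogram(make_series(np.full(200, 3.0)), 20.0)

    def test_ri_invariant_to_affine_rescaling(self, rhythm_series):
        c1 = autocorrelogram(rhythm_series, 60.0)
        scaled = rhythm_series.with_counts(rhythm_series.counts * 7.0 + 3.0)
        c2 = autocorrelogram(scaled, 60.0)
        _, ri1, _ = ac_period_and_ri(c1)
        _, ri2, _ = ac_period_and_ri(c2)
        assert ri1 == pytest.approx(ri2, abs=1e-12)


class TestAcPeriodAndRi:
    def test_cosine_period_and_third_peak_ri(self):
        s = cosine_series(period_h=24.0, bin_h=0.5, n_days=6)
        c = autocorrelogram(s, 66.0)
        period, ri, sig = ac_period_and_ri(c)
        assert period == pytest.approx(24.0, abs=0.5)
        assert ri == pytest.approx(2 / 3, abs=0.02)
        assert sig

    def test_flat_plus_spike_has_no_band_peak(self):
        x = np.full(6 * 48, 2.0)
        x[10] = 50.0
        c = autocorrelogram(make_series(x), 60.0)
        period, ri, sig = ac_period_and_ri(c)
        assert period is None and ri == 0.0 and not sig

    def test_white_noise_rarely_significant(self):
        hits = 0
        n_runs = 60
        for seed in range(n_runs):
            rng = np.random.default_rng(seed)
            s = make_series(rng.poisson(1.5, 192).astype(float), kind="DD")
            c = autocorrelogram(s, 60.0)
            _, _, sig = ac_period_and_ri(c)
            hits += sig
        assert hits <= 0.2 * n_runs  # AC criterion alone, lenient bound


class TestBurg:
    def test_ar2_coefficients_recovered(self):
        rng = np.random.default_rng(1)
        x = lfilter([1.0], [1.0, -1.0, 0.5], rng.normal(size=2000))
        a, s2 = burg_ar(x, 2)
        np.testing.assert_allclose(a, [1.0, -0.5], atol=0.05)
        assert s2 == pytest.approx(1.0, abs=0.1)

    def test_fb_least_squares_agrees_on_ar2(self):
        rng = np.random.default_rng(2)
        x = lfilter([1.0], [1.0, -1.0, 0.5], rng.normal(size=2000))
        a, _ = modcov_ar(x, 2)
        np.testing.assert_allclose(a, [1.0, -0.5], atol=0.05)

    def test_consistency_error_shrinks_with_n(self):
        rng = np.random.default_rng(3)
        errs = []
        for n in (200, 5000):
            x = lfilter([1.0], [1.0, -1.0, 0.5], rng.normal(size=n))
            a, _ = burg_ar(x, 2)
            errs.append(np.abs(a - [1.0, -0.5]).max())
        assert errs[1] < errs[0]

    def test_order_bounds_enforced(self):
        with pytest.raises(ValueError):
            burg_ar(np.ones(10), 10)


class TestMesa:
    def test_noiseless_cosine_peak_at_24(self):
        s = cosine_series(period_h=24.0, bin_h=0.5, n_days=6)
        spec = mesa_spectrum(s, ar_order=32)
        period, power = mesa_period(spec)
        assert period == pytest.approx(24.0, abs=0.25)
        assert power > 0

    def test_power_positive_everywhere(self, rhythm_series):
        spec = mesa_spectrum(rhythm_series)
        assert (spec.power > 0).all()
        assert spec.frequencies.min() <= 1 / 30 and \
            spec.frequencies.max() >= 1 / 18

    def test_monotone_spectrum_has_no_band_peak(self):
        # AR(1) low-pass: PSD strictly decreasing in f, max at band edge
        rng = np.random.default_rng(4)
        x = lfilter([1.0], [1.0, -0.9], rng.normal(size=400))
        s = make_series(x - x.min() + 1.0, bin_minutes=30, kind="DD")
        spec = mesa_spectrum(s, ar_order=1)
        period, _ = mesa_period(spec)
        assert period is None

    def test_simulated_rhythm_period_recovered(self):
        errs = []
        for seed in range(15):
            p = synthetic.SimBehaviorParams(seed=seed)
            s = dam_io.exclude_first_day(
                synthetic.simulate_locomotor_series(p))
            period, _ = mesa_period(mesa_spectrum(s))
            errs.append(abs(period - 24.0))
        assert np.median(errs) <= 0.5


class TestClassify:
    def test_strong_rhythm_is_rhythmic(self, rhythm_series):
        call = classify(rhythm_series, rng=np.random.default_rng(0))
        assert call.rhythmic
        assert call.period_ac_h == pytest.approx(24.0, abs=0.5)
        assert call.period_mesa_h == pytest.approx(24.0, abs=0.5)

    def test_noise_is_not_rhythmic(self, noise_series):
        call = classify(noise_series, rng=np.random.default_rng(0))
        assert not call.rhythmic

    def test_rhythmic_requires_both_criteria(self, rhythm_series):
        # suppressing the MESA surrogate test forces mesa_significant False
        cfg = AnalysisConfig(n_surrogates=0)
        call = classify(rhythm_series, cfg)
        assert call.ac_significant and not call.mesa_significant
        assert not call.rhythmic
        assert call.period_mesa_h is None  # only populated when it passes


class TestActivity:
    def test_constant_one_per_minute_gives_1440(self):
        s = make_series(np.ones(4 * 1440), bin_minutes=1)
        assert total_daily_activity(s) == 1440.0

    def test_all_zero_gives_zero(self):
        s = make_series(np.zeros(4 * 48))
        assert total_daily_activity(s) == 0.0

    def test_matches_brute_force_sum(self):
        rng = np.random.default_rng(5)
        x = rng.poisson(2.0, 4 * 48).astype(float)
        s = make_series(x)
        assert total_daily_activity(s) == pytest.approx(x.sum() / 4)

    def test_insufficient_days_rejected(self):
        with pytest.raises(ValueError):
            total_daily_activity(make_series(np.ones(3 * 48)))


def _call(i, rhythmic, period=24.0, ri=0.2, activity=70.0):
    return RhythmCall(animal_id=f"a{i}", rhythmic=rhythmic,
                      period_ac_h=period if rhythmic else None,
                      period_mesa_h=period if rhythmic else None,
                      rhythmicity_index=ri, total_activity_per_day=activity,
                      ac_significant=rhythmic, mesa_significant=rhythmic)


class TestSummaries:
    @pytest.mark.parametrize("k,n,expected", [
        (21, 33, 63.64), (13, 18, 72.22), (8, 30, 26.67)])
    def test_percent_rhythmic_formatting(self, k, n, expected):
        calls = [_call(i, i < k) for i in range(n)]
        out = summarize_group(calls, "g")
        assert out.percent_rhythmic == expected
        assert out.to_row()["rhythmic_pct_n"] == f"{expected}/{n}"

    def test_none_rhythmic_leaves_period_summary_empty(self):
        out = summarize_group([_call(i, False) for i in range(5)], "g")
        assert out.percent_rhythmic == 0.0
        assert out.mean_sem_period is None and out.mean_sem_ri is None

    def test_period_averaged_over_rhythmic_only(self):
        calls = [_call(0, True, period=23.0), _call(1, True, period=25.0),
                 _call(2, False)]
        out = summarize_group(calls, "g")
        assert out.mean_sem_period[0] == pytest.approx(24.0)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            summarize_group([], "g")


class TestCompareGroups:
    def test_identical_groups_share_one_letter(self):
        out = compare_groups({"a": [1, 1, 1], "b": [1, 1, 1],
                              "c": [1, 1, 1]})
        assert out.statistic == 0.0 and out.p_value == 1.0
        assert set(out.letters.values()) == {"a"}

    def test_anova_f_matches_hand_computation(self):
        groups = {"g1": [1.0, 2.0, 3.0], "g2": [2.0, 3.0, 4.0],
                  "g3": [6.0, 7.0, 8.0]}
        # closed-form one-way ANOVA on the fixture
        all_v = np.concatenate(list(groups.values()))
        grand = all_v.mean()
        ss_between = sum(len(v) * (np.mean(v) - grand) ** 2
                         for v in groups.values())
        ss_within = sum(np.sum((np.asarray(v) - np.mean(v)) ** 2)
                        for v in groups.values())
        f_expected = (ss_between / 2) / (ss_within / 6)
        out = compare_groups(groups)
        assert out.statistic == pytest.approx(f_expected, abs=1e-10)
        assert out.letters["g1"] == out.letters["g2"] != out.letters["g3"]

    def test_two_well_separated_groups_get_three_stars(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(10.0, 1.0, 10)
        out = compare_groups({"a": a, "b": b})
        assert out.method == "welch_t"
        assert out.p_value < 0.001 and out.stars == "***"

    def test_star_codes(self):
        assert p_to_stars(0.2) == "ns"
        assert p_to_stars(0.03) == "*"
        assert p_to_stars(0.005) == "**"
        assert p_to_stars(0.0005) == "***"


class TestRiNoise:
    def test_ri_decreases_as_noise_swamps_amplitude(self):
        # fixed period; lower relative amplitude = higher noise:signal.
        # Run at 0.5 counts/min so RI stays resolvable above the
        # correlogram noise floor across the whole grid.
        amps = [0.8, 0.6, 0.4, 0.3, 0.2]
        mean_ri = []
        for amp in amps:
            ris = []
            for seed in range(12):
                p = synthetic.SimBehaviorParams(
                    rel_amplitude=amp, baseline_rate=0.5,
                    masking_spike=0.0, seed=seed,
                    regime=LightRegime.constant("DD", 5))
                s = dam_io.exclude_first_day(
                    synthetic.simulate_locomotor_series(p))
                c = autocorrelogram(s, 60.0)
                ris.append(ac_period_and_ri(c)[1])
            mean_ri.append(np.mean(ris))
        assert all(a > b for a, b in zip(mean_ri, mean_ri[1:]))
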