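import numpy as np
import pandas as pd
import pytest

from zeitgeber.light import LightRegime
from zeitgeber.series import ActivitySeries

EPOCH = pd.Timestamp("2025-06-01 08:00:00")  # 08:00 = ZT0 everywhere in tests


def make_series(counts, bin_minutes=30, regime=None, animal_id="a",
                kind="LD"):
    counts = np.asarray(counts, dtype=float)
    n_days = max(1, int(np.ceil(counts.size * bin_minutes / 1440)))
    regime = regime or LightRegime.constant(kind, n_days)
    return ActivitySeries(animal_id=animal_id, start=EPOCH,
                          bin_minutes=bin_minutes, counts=counts,
                          regime=regime)


def cosine_series(period_h=24.0, bin_h=0.5, n_days=6, offset=2.0,
                  amplitude=1.0, phase_h=0.0, kind="DD"):
    """Noiseless sinusoid-plus-offset series for closed-form checks."""
    n = int(round(n_days * 24 / bin_h))
    t = np.arange(n) * bin_h
    x = offset + amplitude * np.cos(2 * np.pi * (t - phase_h) / period_h)
    return make_series(x, bin_minutes=int(bin_h * 60), kind=kind)


@pytest.fixture
def rhythm_series():
    """One strongly rhythmic simulated animal, hygiene applied."""
    from zeitgeber import dam_io, synthetic
    p = synthetic.SimBehaviorParams(seed=3)
    return dam_io.exclude_first_day(synthetic.simulate_locomotor_series(p))


@pytest.fixture
def noise_series():
    """Stationary Poisson (arrhythmic) animal, hygiene applied."""
    from zeitgeber import dam_io, synthetic
    p = synthetic.SimBehaviorParams(
        rel_amplitude=0.0, masking_spike=0.0, seed=11,
        regime=LightRegime.constant("DD", 5))
    return dam_io.exclude_first_day(synthetic.simulate_locomotor_series(p))
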