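import math

import numpy as np
import pytest

from gaitspeed import inventory
from gaitspeed.features import (
    basic_stats,
    build_feature_table,
    count_features,
    extract_sensor_features,
    feature_columns,
    mean_crossing_rate,
    modulus,
    peak_frequency,
    shannon_entropy,
    signal_magnitude_area,
)
from gaitspeed.preprocess import WindowSpec, dual_filter

FS = 50.0


# ---------------------------------------------------------------------------
# scalar statistics against closed forms and brute-force oracles
# ---------------------------------------------------------------------------

def test_basic_stats_constant_and_symmetric_windows():
    c = basic_stats(np.full(100, 2.0))
    assert (c["MEAN"], c["STD"], c["CV"], c["RMS"], c["RNG"], c["MAX"]) == \
        (2.0, 0.0, 0.0, 2.0, 0.0, 2.0)
    s = basic_stats(np.array([-1.0, 1.0]))
    assert (s["MEAN"], s["RMS"], s["RNG"], s["MAX"]) == (0.0, 1.0, 2.0, 1.0)


def test_basic_stats_population_std_denominator():
    x = np.array([1.0, 2.0, 3.0])
    assert basic_stats(x)["STD"] == pytest.approx(math.sqrt(2.0 / 3.0))


def test_rms_of_unit_sine_whole_periods():
    t = np.arange(500) / FS
    x = np.sin(2 * np.pi * 2.0 * t)  # 20 whole periods
    assert basic_stats(x)["RMS"] == pytest.approx(1 / math.sqrt(2), abs=1e-3)


def test_cv_guard_near_zero_mean():
    x = np.array([-1.0, 1.0, -1.0, 1.0])
    assert basic_stats(x)["CV"] == 0.0


def test_mcr_constant_sine_and_ramp():
    assert mean_crossing_rate(np.full(250, 5.0), FS) == 0.0
    t = np.arange(250) / FS
    f = 2.0
    x = np.sin(2 * np.pi * f * t + 0.3)
    assert mean_crossing_rate(x, FS) == pytest.approx(2 * f, abs=1 / 5.0)
    ramp = np.linspace(0.0, 1.0, 250)
    assert mean_crossing_rate(ramp, FS) == pytest.approx(1 / 5.0)


def test_mcr_matches_brute_force_with_exact_zero_rule():
    """Exact zeros take the sign of the previous nonzero deviation."""
    rng = np.random.default_rng(3)
    for _ in range(20):
        x = rng.integers(-3, 4, size=60).astype(float)  # many exact-mean hits
        d = x - x.mean()
        signs, prev, count = [], 0.0, 0
        for v in d:
            s = np.sign(v) if v != 0 else prev
            if s != 0:
                if prev != 0 and s != prev:
                    count += 1
                prev = s
        assert mean_crossing_rate(x, FS) == pytest.approx(count / (len(x) / FS))


def test_peak_frequency_exact_bin_and_amplitude_dominance():
    t = np.arange(250) / FS  # resolution 0.2 Hz
    assert peak_frequency(np.sin(2 * np.pi * 2.0 * t), FS) == pytest.approx(2.0)
    mix = np.sin(2 * np.pi * 1.0 * t) + 2.0 * np.sin(2 * np.pi * 3.0 * t)
    assert peak_frequency(mix, FS) == pytest.approx(3.0)


def test_peak_frequency_matches_spectrum_argmax_on_noise():
    rng = np.random.default_rng(11)
    x = rng.normal(size=250)
    mag = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(250, 1 / FS)
    best = max(range(1, len(mag)), key=lambda i: mag[i])
    assert peak_frequency(x, FS) == freqs[best]


def test_sma_constants_and_sine():
    n = 500
    assert signal_magnitude_area(np.ones((n, 3))) == pytest.approx(3.0)
    assert signal_magnitude_area(np.zeros((n, 3))) == 0.0
    t = np.arange(n) / FS
    xyz = np.column_stack([np.sin(2 * np.pi * 2.0 * t), np.zeros(n), np.zeros(n)])
    assert signal_magnitude_area(xyz) == pytest.approx(2 / np.pi, abs=1e-2)
    with pytest.raises(ValueError):
        signal_magnitude_area(np.ones((10, 2)))


def test_entropy_bounds_and_uniform_bins():
    assert shannon_entropy(np.full(250, 1.0)) == 0.0
    # values spread exactly uniformly across all 16 bins
    x = np.repeat(np.arange(16) + 0.5, 10) / 16.0
    assert shannon_entropy(x) == pytest.approx(4.0)


def test_entropy_matches_histogram_oracle():
    rng = np.random.default_rng(5)
    for _ in range(10):
        x = rng.normal(size=250)
        lo, hi = x.min(), x.max()
        counts = np.zeros(16, dtype=int)
        for v in x:
            counts[min(int((v - lo) / (hi - lo) * 16), 15)] += 1
        p = counts[counts > 0] / len(x)
        assert shannon_entropy(x) == pytest.approx(float(-(p * np.log2(p)).sum()))


def test_modulus_pythagorean_and_oracle():
    n = 100
    assert np.allclose(modulus(np.tile([3.0, 4.0, 0.0], (n, 1))), 5.0)
    assert np.all(modulus(np.zeros((n, 3))) == 0.0)
    rng = np.random.default_rng(2)
    a = rng.normal(size=(n, 3))
    brute = np.array([math.sqrt(r[0] ** 2 + r[1] ** 2 + r[2] ** 2) for r in a])
    np.testing.assert_allclose(modulus(a), brute, rtol=1e-15)


def test_scale_behaviour_of_statistics():
    """Amplitude statistics scale linearly; CV, MCR, PF, ENT are invariant."""
    rng = np.random.default_rng(9)
    x = rng.normal(loc=1.0, size=250)
    a = 7.3
    s1, s2 = basic_stats(x), basic_stats(a * x)
    for stat in ("MEAN", "STD", "RMS", "RNG", "MAX"):
        assert s2[stat] == pytest.approx(a * s1[stat], rel=1e-12)
    assert s2["CV"] == pytest.approx(s1["CV"], rel=1e-12)
    assert mean_crossing_rate(a * x, FS) == mean_crossing_rate(x, FS)
    assert peak_frequency(a * x, FS) == peak_frequency(x, FS)
    assert shannon_entropy(a * x) == pytest.approx(shannon_entropy(x), abs=1e-9)
    xyz = rng.normal(size=(250, 3))
    assert signal_magnitude_area(a * xyz) == pytest.approx(
        a * signal_magnitude_area(xyz), rel=1e-12)


# ---------------------------------------------------------------------------
# feature bank combinatorics and naming
# ---------------------------------------------------------------------------

def test_sensor_feature_vector_has_74_distinct_names():
    rng = np.random.default_rng(0)
    lp = rng.normal(size=(250, 3))
    bp = rng.normal(size=(250, 3))
    feats = extract_sensor_features(lp, bp, "acc", "dev_2")
    assert len(feats) == 74
    assert len(set(feats)) == 74
    assert "RMS_acc_lp_mod_dev_2" in feats
    assert "SMA_acc_lp-hp_dev_2" in feats
    assert all(np.isfinite(v) for v in feats.values())


@pytest.mark.parametrize("devices,expected", [
    (["phone"], 148),
    (["watch"], 148),
    (["shoes"], 222),
    (["phone", "watch", "shoes"], 518),
    (["watch", "shoes"], 370),
    ([], 0),
])
def test_count_features_per_device_subset(devices, expected):
    assert count_features(devices) == expected


def test_pool_names_match_counts_single_shoe():
    for name, logical in inventory.COMBINATIONS.items():
        pool = inventory.pool_feature_names(name, both_shoes=False)
        assert len(pool) == count_features(logical)
        assert len(set(pool)) == len(pool)


def test_feature_name_parsing_and_device_mapping():
    p = inventory.parse_feature_name("MCR_press_lp_mod_dev_3")
    assert p["statistic"] == "MCR" and p["component"] == "mod"
    assert inventory.device_of_feature("MCR_press_lp_mod_dev_3") == "shoes"
    assert inventory.device_of_feature("SMA_acc_lp-hp_dev_2") == "watch"
    with pytest.raises(ValueError):
        inventory.parse_feature_name("bogus")


# ---------------------------------------------------------------------------
# table builder: vectorised path vs. per-window scalar extraction
# ---------------------------------------------------------------------------

def test_feature_table_matches_scalar_extraction(medium_trial):
    _, trial = medium_trial
    spec = WindowSpec(5.0, 1.0)
    table = build_feature_table(trial, spec=spec)
    nw = spec.n_window(trial.fs)
    fp = dual_filter(trial.channels["watch"]["acc"], fs=trial.fs)
    for widx in (0, 17, 55):
        s = widx * spec.n_hop(trial.fs)
        feats = extract_sensor_features(
            fp.lp[s:s + nw], fp.bp[s:s + nw], "acc", "dev_2", fs=trial.fs)
        row = table.iloc[widx]
        for name, val in feats.items():
            assert row[name] == pytest.approx(val, rel=1e-9, abs=1e-12), name


def test_feature_table_shape_and_finiteness(small_table):
    cols = feature_columns(small_table)
    assert len(cols) == 740  # 148 + 148 + 222 + 222 with both shoes emitted
    assert len(small_table) == 12 * 86  # 12 trials x floor((90-5)/1)+1 windows
    assert np.all(np.isfinite(small_table[cols].to_numpy()))
    assert small_table["y"].min() > 0
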