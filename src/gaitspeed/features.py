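"""Windowed feature bank: ten statistics per channel over both filtered views.

For every tri-axial sensor group, each sliding window yields, per filter
mode (``lp`` and ``lp-hp``):

* nine per-component statistics — mean, standard deviation, coefficient of
  variation, RMS, range, max, mean-crossing rate, peak frequency and
  Shannon entropy — computed on each of x, y, z and the per-sample modulus
  sqrt(x^2 + y^2 + z^2);
* one signal magnitude area (SMA), computed once per sensor on the three
  channels jointly.

That is 9 x 4 + 1 = 37 features per mode and 74 per sensor, hence 148 for
the phone (accelerometer + orientation), 148 for the watch (accelerometer +
gyroscope) and 222 for a shoe's inventory (accelerometer + gyroscope +
pressure); pooling all devices gives 518.

Two code paths exist: scalar functions (one window at a time), which define
the semantics and are what the tests exercise against brute-force oracles,
and a vectorised path over all windows of a trial used by the table builder.
The vectorised path is required to agree bit-for-bit with the scalar one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import inventory
from .inventory import (
    COMPONENTS,
    DEVICE_CODES,
    FILTER_MODES,
    SAMPLING_RATE_HZ,
    SENSOR_GROUPS,
    STATISTICS,
    count_features,  # re-exported: combinatorial pool size per device subset
)
from .preprocess import FilterParams, WindowSpec, filter_trial, window_starts, window_targets
from .synthetic import TrialRecording

__all__ = [
    "basic_stats", "mean_crossing_rate", "peak_frequency",
    "signal_magnitude_area", "shannon_entropy", "modulus",
    "extract_sensor_features", "count_features", "build_feature_table",
    "META_COLUMNS",
]

META_COLUMNS = ("subject_id", "trial_id", "pace", "window_index", "y")

DEFAULT_ENTROPY_BINS = 16


# ---------------------------------------------------------------------------
# scalar statistics (reference semantics)
# ---------------------------------------------------------------------------

def basic_stats(segment: np.ndarray) -> dict[str, float]:
    """MEAN, STD (population), CV, RMS, RNG and MAX of one window.

    CV is STD / |MEAN|, defined as 0 when |MEAN| < 1e-12: band-passed
    signals have near-zero means and an unguarded ratio explodes.
    """
    x = np.asarray(segment, dtype=float)
    mean = float(np.mean(x))
    std = float(np.std(x))  # population denominator N
    return {
        "MEAN": mean,
        "STD": std,
        "CV": std / abs(mean) if abs(mean) >= 1e-12 else 0.0,
        "RMS": float(np.sqrt(np.mean(x * x))),
        "RNG": float(np.max(x) - np.min(x)),
        "MAX": float(np.max(x)),
    }


def _filled_signs(dev: np.ndarray) -> np.ndarray:
    """Signs of deviations with exact zeros carried forward from the last
    nonzero deviation (leading zeros stay 0 and contribute no crossing)."""
    s = np.sign(dev)
    idx = np.where(s != 0, np.arange(s.shape[-1]), 0)
    np.maximum.accumulate(idx, axis=-1, out=idx)
    return np.take_along_axis(s, idx, axis=-1)


def mean_crossing_rate(segment: np.ndarray, fs: float = SAMPLING_RATE_HZ) -> float:
    """Crossings of the window's own mean, per second."""
    x = np.asarray(segment, dtype=float)
    s = _filled_signs(x - np.mean(x))
    crossings = int(np.sum(s[1:] * s[:-1] < 0))
    return crossings / (len(x) / fs)


def peak_frequency(segment: np.ndarray, fs: float = SAMPLING_RATE_HZ) -> float:
    """Frequency (Hz) of the maximum of the magnitude spectrum, DC excluded.

    Single rectangular-window FFT periodogram; resolution fs / N; ties go to
    the lowest frequency.
    """
    x = np.asarray(segment, dtype=float)
    if len(x) < 16:
        raise ValueError("segment too short for a meaningful spectrum")
    mag = np.abs(np.fft.rfft(x))
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    return float(freqs[1 + np.argmax(mag[1:])])


def signal_magnitude_area(segment_xyz: np.ndarray) -> float:
    """SMA: mean over samples of |x| + |y| + |z| for a 3-channel window."""
    a = np.asarray(segment_xyz, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("SMA requires an (n, 3) channel window")
    return float(np.mean(np.sum(np.abs(a), axis=1)))


def _entropy_from_binned(idx: np.ndarray, n_bins: int) -> float:
    counts = np.bincount(idx, minlength=n_bins)
    p = counts[counts > 0] / idx.size
    return float(-np.sum(p * np.log2(p)))


def shannon_entropy(segment: np.ndarray, bins: int = DEFAULT_ENTROPY_BINS) -> float:
    """Shannon entropy (bits) of a fixed-bin histogram of the window.

    Equal-width bins span the window's own [min, max], making the value
    scale- and offset-invariant and bounded by log2(bins); a constant
    window is defined as 0 bits.
    """
    x = np.asarray(segment, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        return 0.0
    idx = np.clip(((x - lo) / (hi - lo) * bins).astype(int), 0, bins - 1)
    return _entropy_from_binned(idx, bins)


def modulus(segment_xyz: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of a 3-channel window."""
    a = np.asarray(segment_xyz, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("modulus requires an (n, 3) channel window")
    return np.sqrt(np.sum(a * a, axis=1))


def _component_features(seg: np.ndarray, fs: float, bins: int) -> dict[str, float]:
    out = basic_stats(seg)
    out["MCR"] = mean_crossing_rate(seg, fs)
    out["PF"] = peak_frequency(seg, fs)
    out["ENT"] = shannon_entropy(seg, bins)
    return out


def extract_sensor_features(
    lp_segment: np.ndarray,
    bp_segment: np.ndarray,
    sensor: str,
    device_code: str,
    fs: float = SAMPLING_RATE_HZ,
    bins: int = DEFAULT_ENTROPY_BINS,
) -> dict[str, float]:
    """The 74 named features of one sensor group for one window.

    ``lp_segment`` and ``bp_segment`` are the (n, 3) low-pass and band-pass
    views of the same window.
    """
    out: dict[str, float] = {}
    for mode, seg in zip(FILTER_MODES, (lp_segment, bp_segment)):
        seg = np.asarray(seg, dtype=float)
        comps = {"x": seg[:, 0], "y": seg[:, 1], "z": seg[:, 2], "mod": modulus(seg)}
        for stat in STATISTICS:
            for comp_name in COMPONENTS:
                series = comps[comp_name]
                name = f"{stat}_{sensor}_{mode}_{comp_name}_{device_code}"
                if stat == "MCR":
                    out[name] = mean_crossing_rate(series, fs)
                elif stat == "PF":
                    out[name] = peak_frequency(series, fs)
                elif stat == "ENT":
                    out[name] = shannon_entropy(series, bins)
                else:
                    out[name] = basic_stats(series)[stat]
        out[f"SMA_{sensor}_{mode}_{device_code}"] = signal_magnitude_area(seg)
    return out


# ---------------------------------------------------------------------------
# vectorised path over all windows of a trial
# ---------------------------------------------------------------------------

def _windowed_view(x: np.ndarray, starts: np.ndarray, nw: int) -> np.ndarray:
    """(n_windows, nw) strided view of a 1-D series."""
    sw = np.lib.stride_tricks.sliding_window_view(x, nw)
    return sw[starts]

def _stats_matrix(W: np.ndarray, fs: float, bins: int) -> dict[str, np.ndarray]:
    """All nine per-component statistics for a (m, nw) window stack."""
    m, nw = W.shape
    mean = W.mean(axis=1)
    std = W.std(axis=1)
    mx = W.max(axis=1)
    mn = W.min(axis=1)
    cv = np.where(np.abs(mean) >= 1e-12, std / np.abs(np.where(mean == 0, 1.0, mean)), 0.0)
    rms = np.sqrt(np.mean(W * W, axis=1))
    # mean-crossing rate
    s = _filled_signs(W - mean[:, None])
    mcr = np.sum(s[:, 1:] * s[:, :-1] < 0, axis=1) / (nw / fs)
    # peak frequency
    mag = np.abs(np.fft.rfft(W, axis=1))
    freqs = np.fft.rfftfreq(nw, d=1.0 / fs)
    pf = freqs[1 + np.argmax(mag[:, 1:], axis=1)]
    # entropy via per-row fixed bins
    rng = mx - mn
    safe = np.where(rng > 0, rng, 1.0)
    idx = np.clip(((W - mn[:, None]) / safe[:, None] * bins).astype(int), 0, bins - 1)
    flat = (idx + bins * np.arange(m)[:, None]).ravel()
    counts = np.bincount(flat, minlength=bins * m).reshape(m, bins)
    p = counts / nw
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = -np.sum(np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0), axis=1)
    ent = np.where(rng > 0, ent, 0.0)
    return {
        "MEAN": mean, "STD": std, "CV": cv, "RMS": rms,
        "RNG": mx - mn, "MAX": mx, "MCR": mcr, "PF": pf, "ENT": ent,
    }


def _sensor_block(lp: np.ndarray, bp: np.ndarray, starts: np.ndarray, nw: int,
                  sensor: str, device_code: str, fs: float, bins: int
                  ) -> dict[str, np.ndarray]:
    """Vectorised 74-feature block for one sensor group over all windows."""
    out: dict[str, np.ndarray] = {}
    for mode, arr in zip(FILTER_MODES, (lp, bp)):
        comps = {
            "x": arr[:, 0], "y": arr[:, 1], "z": arr[:, 2],
            "mod": np.sqrt(np.sum(arr * arr, axis=1)),
        }
        stacked = {c: _windowed_view(v, starts, nw) for c, v in comps.items()}
        per_comp = {c: _stats_matrix(Wc, fs, bins) for c, Wc in stacked.items()}
        for stat in STATISTICS:
            for comp_name in COMPONENTS:
                out[f"{stat}_{sensor}_{mode}_{comp_name}_{device_code}"] = \
                    per_comp[comp_name][stat]
        abs_sum = np.sum(np.abs(arr), axis=1)
        out[f"SMA_{sensor}_{mode}_{device_code}"] = \
            _windowed_view(abs_sum, starts, nw).mean(axis=1)
    return out


def build_feature_table(
    trials: list[TrialRecording] | TrialRecording,
    spec: WindowSpec = WindowSpec(),
    params: FilterParams = FilterParams(),
    bins: int = DEFAULT_ENTROPY_BINS,
    target_mode: str = "mean",
) -> pd.DataFrame:
    """Filter, window and featurise trials into one table.

    Returns a DataFrame with one row per window: metadata columns
    (subject_id, trial_id, pace, window_index, y) followed by the named
    feature columns in deterministic device/sensor/statistic order.
    """
    if isinstance(trials, TrialRecording):
        trials = [trials]
    frames: list[pd.DataFrame] = []
    for trial in trials:
        filtered = filter_trial(trial, params)
        starts = window_starts(trial.n_samples, spec, trial.fs)
        if len(starts) == 0:
            continue
        y = window_targets(trial.reference_speed, spec, trial.fs, target_mode)
        nw = spec.n_window(trial.fs)
        cols: dict[str, np.ndarray] = {
            "subject_id": np.repeat(trial.subject_id, len(starts)),
            "trial_id": np.repeat(trial.trial_id, len(starts)),
            "pace": np.repeat(trial.pace, len(starts)),
            "window_index": np.arange(len(starts)),
            "y": y,
        }
        for device in inventory.DEVICES:
            if device not in trial.channels:
                continue
            code = DEVICE_CODES[device]
            for group in SENSOR_GROUPS[device]:
                fp = filtered[(device, group)]
                cols.update(_sensor_block(
                    fp.lp, fp.bp, starts, nw, group, code, trial.fs, bins))
        frames.append(pd.DataFrame(cols))
    if not frames:
        raise ValueError("no trial produced any complete window")
    table = pd.concat(frames, ignore_index=True)
    values = table.drop(columns=list(META_COLUMNS), errors="ignore")
    if not np.all(np.isfinite(values.to_numpy(dtype=float))):
        raise ValueError("non-finite feature values produced")
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Names of the feature columns of a table (metadata excluded)."""
    return [c for c in table.columns if c not in META_COLUMNS]
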