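"""Loading, filtering and windowing of walking-trial recordings.

Two filtered views of every channel are produced and kept side by side:

* ``lp`` — low-pass at 10 Hz, preserving the DC/gravity content of the
  accelerometer signals;
* ``lp-hp`` (band-pass 0.1-10 Hz) — the same passband with the
  low-frequency/gravity content removed.

Both use a 4th-order Butterworth applied forward-backward (zero phase), so
filtered windows stay aligned with the reference speed trace.  Signals are
then cut into sliding windows (default 5 s, hop 1 s, i.e. 80 % overlap and
one feature vector per second) and each window is paired with the mean
reference speed over its span as the regression target.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .inventory import SAMPLING_RATE_HZ, SENSOR_GROUPS
from .synthetic import TrialRecording


@dataclass(frozen=True)
class FilterParams:
    """Butterworth filter bank parameters."""

    lp_cutoff_hz: float = 10.0
    bp_band_hz: tuple[float, float] = (0.1, 10.0)
    order: int = 4


@dataclass
class FilteredPair:
    """Low-pass and band-pass views of one channel matrix."""

    lp: np.ndarray
    bp: np.ndarray
    params: FilterParams


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry.

    ``length_s`` in {2.5, 5, 10, 20}; ``hop_s`` defaults to 1 s so the
    pipeline always emits one feature vector per second of recording (at
    the default 5 s length that is 80 % overlap).
    """

    length_s: float = 5.0
    hop_s: float = 1.0

    def __post_init__(self) -> None:
        if not (self.length_s > self.hop_s > 0):
            raise ValueError("window length must exceed hop and both must be > 0")

    def n_window(self, fs: float = SAMPLING_RATE_HZ) -> int:
        return int(round(self.length_s * fs))

    def n_hop(self, fs: float = SAMPLING_RATE_HZ) -> int:
        return int(round(self.hop_s * fs))

    @property
    def overlap(self) -> float:
        return (self.length_s - self.hop_s) / self.length_s


@dataclass
class AlignedWindow:
    """One window of filtered segments with its reference-speed target."""

    subject_id: str
    trial_id: str
    index: int
    start: int
    lp: dict[tuple[str, str], np.ndarray]
    bp: dict[tuple[str, str], np.ndarray]
    target_speed: float


def dual_filter(raw: np.ndarray, fs: float = SAMPLING_RATE_HZ,
                params: FilterParams = FilterParams()) -> FilteredPair:
    """Produce the low-pass and band-pass views of a channel matrix.

    Zero-phase (forward-backward) filtering; the low-pass keeps DC exactly,
    the band-pass removes it.  Raises on non-finite input.
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("non-finite samples in input channel")
    sos_lp = sps.butter(params.order, params.lp_cutoff_hz, btype="low", fs=fs, output="sos")
    sos_bp = sps.butter(params.order, params.bp_band_hz, btype="band", fs=fs, output="sos")
    lp = sps.sosfiltfilt(sos_lp, raw, axis=0)
    bp = sps.sosfiltfilt(sos_bp, raw, axis=0)
    return FilteredPair(lp=lp, bp=bp, params=params)


def filter_trial(trial: TrialRecording,
                 params: FilterParams = FilterParams()) -> dict[tuple[str, str], FilteredPair]:
    """Filter every (device, sensor group) channel matrix of a trial.

    Orientation angles are unwrapped (period 360 deg) before filtering so
    that +-180 deg discontinuities do not ring through the filters.
    """
    out: dict[tuple[str, str], FilteredPair] = {}
    for device, groups in trial.channels.items():
        for group, arr in groups.items():
            if group == "ori":
                arr = np.unwrap(arr, axis=0, period=360.0)
            out[(device, group)] = dual_filter(arr, fs=trial.fs, params=params)
    return out


def window_starts(n_samples: int, spec: WindowSpec, fs: float = SAMPLING_RATE_HZ) -> np.ndarray:
    """Start indices of complete windows (incomplete tails discarded)."""
    nw, nh = spec.n_window(fs), spec.n_hop(fs)
    if n_samples < nw:
        return np.empty(0, dtype=int)
    return np.arange(0, n_samples - nw + 1, nh)


def window_targets(reference_speed: np.ndarray, spec: WindowSpec,
                   fs: float = SAMPLING_RATE_HZ, mode: str = "mean") -> np.ndarray:
    """Per-window target speed: mean (default) or midpoint reference value."""
    starts = window_starts(len(reference_speed), spec, fs)
    nw = spec.n_window(fs)
    if mode == "mean":
        cs = np.concatenate([[0.0], np.cumsum(reference_speed)])
        return (cs[starts + nw] - cs[starts]) / nw
    if mode == "midpoint":
        return np.asarray(reference_speed)[starts + nw // 2]
    raise ValueError(f"unknown target mode {mode!r}")


def segment(trial: TrialRecording, spec: WindowSpec,
            params: FilterParams = FilterParams(),
            target_mode: str = "mean") -> list[AlignedWindow]:
    """Cut a trial into aligned windows of filtered segments.

    Reference implementation of the windowing contract; the feature-table
    builder uses an equivalent vectorised path.  Returns an empty list when
    the trial is shorter than one window.
    """
    filtered = filter_trial(trial, params)
    starts = window_starts(trial.n_samples, spec, trial.fs)
    targets = window_targets(trial.reference_speed, spec, trial.fs, target_mode)
    nw = spec.n_window(trial.fs)
    windows: list[AlignedWindow] = []
    for i, (s, y) in enumerate(zip(starts, targets)):
        lp = {key: fp.lp[s:s + nw] for key, fp in filtered.items()}
        bp = {key: fp.bp[s:s + nw] for key, fp in filtered.items()}
        windows.append(AlignedWindow(
            subject_id=trial.subject_id, trial_id=trial.trial_id,
            index=i, start=int(s), lp=lp, bp=bp, target_speed=float(y),
        ))
    return windows


# ---------------------------------------------------------------------------
# CSV dialect: one file per device plus a reference file per trial directory.
# Device file header: t,<group>_<channel>,... ; reference header: t,speed_mps.
# File names: <subject>_<pace>_<device>.csv and <subject>_<pace>_reference.csv.
# ---------------------------------------------------------------------------

def write_trial(trial: TrialRecording, directory: str | Path) -> Path:
    """Write a trial in the package CSV dialect; floats round-trip exactly."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = f"{trial.subject_id}_{trial.pace}"
    t = np.arange(trial.n_samples) / trial.fs
    for device, groups in trial.channels.items():
        cols: dict[str, np.ndarray] = {"t": t}
        for group, arr in groups.items():
            names = trial.channel_names.get(device, {}).get(group) or SENSOR_GROUPS[device][group]
            for j, ch in enumerate(names):
                cols[f"{group}_{ch}"] = arr[:, j]
        pd.DataFrame(cols).to_csv(directory / f"{stem}_{device}.csv", index=False)
    pd.DataFrame({"t": t, "speed_mps": trial.reference_speed}).to_csv(
        directory / f"{stem}_reference.csv", index=False)
    return directory


def load_trial(directory: str | Path, fs: float = SAMPLING_RATE_HZ) -> TrialRecording:
    """Load one trial directory written in the package CSV dialect.

    A missing device file raises a warning and the device is simply absent
    (the trial then only serves combinations not using it).  A missing
    reference file is fatal, as is a sample-count mismatch above 2 %
    between device files.  A reference sampled at a different rate is
    linearly resampled onto the 50 Hz device grid.
    """
    directory = Path(directory)
    refs = sorted(directory.glob("*_reference.csv"))
    if not refs:
        raise FileNotFoundError(f"no reference CSV in {directory}")
    ref_path = refs[0]
    subject_id, pace = ref_path.stem.rsplit("_", 1)[0].rsplit("_", 1)
    stem = f"{subject_id}_{pace}"

    channels: dict[str, dict[str, np.ndarray]] = {}
    counts: list[int] = []
    for device, groups in SENSOR_GROUPS.items():
        path = directory / f"{stem}_{device}.csv"
        if not path.exists():
            warnings.warn(f"missing device file {path.name}; {device} excluded from trial")
            continue
        df = pd.read_csv(path, float_precision="round_trip")
        dev_groups: dict[str, np.ndarray] = {}
        for group, names in groups.items():
            want = [f"{group}_{ch}" for ch in names]
            missing = [c for c in want if c not in df.columns]
            if missing:
                raise ValueError(f"{path.name}: missing channels {missing}")
            dev_groups[group] = df[want].to_numpy(dtype=float)
        channels[device] = dev_groups
        counts.append(len(df))
    if not channels:
        raise FileNotFoundError(f"no device CSVs found in {directory}")
    n = min(counts)
    if max(counts) - n > 0.02 * n:
        raise ValueError(f"device sample counts differ by more than 2%: {counts}")
    channels = {d: {g: a[:n] for g, a in gs.items()} for d, gs in channels.items()}

    ref = pd.read_csv(ref_path, float_precision="round_trip")
    t_dev = np.arange(n) / fs
    t_ref = ref["t"].to_numpy(dtype=float)
    speed = ref["speed_mps"].to_numpy(dtype=float)
    if len(speed) == n and np.allclose(t_ref, t_dev):
        resampled = speed
    else:
        resampled = np.interp(t_dev, t_ref, speed)
    return TrialRecording(
        subject_id=subject_id, pace=pace, fs=fs,
        channels=channels, reference_speed=resampled,
        channel_names={d: dict(SENSOR_GROUPS[d]) for d in channels},
    )


def write_cohort(trials: list[TrialRecording], directory: str | Path) -> Path:
    """Write each trial of a cohort into its own sub-directory."""
    directory = Path(directory)
    for trial in trials:
        write_trial(trial, directory / trial.trial_id)
    return directory


def load_cohort(directory: str | Path) -> list[TrialRecording]:
    """Load every trial sub-directory under ``directory`` (sorted order)."""
    directory = Path(directory)
    subdirs = sorted(p for p in directory.iterdir() if p.is_dir())
    return [load_trial(p) for p in subdirs]
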