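"""Synthetic walking-trial generator with ground-truth gait speed.

Emulates a cohort of healthy adults each performing a modified six-minute
walking test three times (self-selected slow, medium and fast paces) along a
10 m back-and-forth path, while wearing a smartphone, a smartwatch and a
pair of instrumented shoes, all sampling at 50 Hz.

The generator is phenomenological, not biomechanical: every sensor channel
is built from a shared instantaneous speed profile ``v(t)`` through a simple
cadence model.  Step frequency follows ``f_step = c0 + c1 * v`` (defaults
0.9 + 0.9 v steps/s, placing cadence in the 1.5-2.6 Hz band typical of adult
walking); oscillation amplitudes grow linearly with speed.  Direction changes
at the ends of the 10 m path appear as short (1-2 s) multiplicative speed
dips of 20-40 %, which give each trial genuine within-trial speed variance.
The reference trace records ``v(t)`` itself at 50 Hz, playing the role a
motion-capture centre-of-mass velocity plays with real hardware.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inventory import SAMPLING_RATE_HZ, SENSOR_GROUPS, VERTICAL_AXIS

PACES: tuple[str, ...] = ("slow", "medium", "fast")

#: self-selected pace ranges, m/s (uniform draws; disjoint so the ordering
#: slow < medium < fast holds by construction)
PACE_SPEED_RANGES: dict[str, tuple[float, float]] = {
    "slow": (0.7, 1.0),
    "medium": (1.1, 1.4),
    "fast": (1.5, 1.9),
}

GRAVITY = 9.81  # m/s^2
PATH_LENGTH_M = 10.0  # straight walkway length between turns


@dataclass(frozen=True)
class SubjectProfile:
    """Per-subject gait parameters.

    Parameters
    ----------
    base_speeds
        Self-selected speed per pace, m/s; strictly increasing
        slow < medium < fast, all within (0.4, 2.5).
    cadence_slope, cadence_intercept
        Linear cadence model ``f_step = intercept + slope * v`` (steps/s).
    amp_scale
        Dimensionless scale on every oscillation amplitude (inter-subject
        gait "vigour").
    noise_sd_acc, noise_sd_gyr
        White-noise standard deviations, m/s^2 and rad/s.
    """

    subject_id: str
    base_speeds: dict[str, float]
    cadence_slope: float
    cadence_intercept: float
    amp_scale: float
    noise_sd_acc: float
    noise_sd_gyr: float

    def __post_init__(self) -> None:
        s, m, f = (self.base_speeds[p] for p in PACES)
        if not (s < m < f):
            raise ValueError("base speeds must be strictly increasing slow<medium<fast")
        if not all(0.4 < v < 2.5 for v in (s, m, f)):
            raise ValueError("base speeds must lie in (0.4, 2.5) m/s")
        if self.noise_sd_acc < 0 or self.noise_sd_gyr < 0:
            raise ValueError("noise standard deviations must be >= 0")


@dataclass
class TrialRecording:
    """One walking trial: raw 50 Hz channels per device plus the reference.

    ``channels[device][group]`` is an (n, 3) float array; every group shares
    the same sample count ``n = duration * 50``.  ``reference_speed`` is the
    ground-truth horizontal speed trace, m/s, same length.
    """

    subject_id: str
    pace: str
    fs: float
    channels: dict[str, dict[str, np.ndarray]]
    reference_speed: np.ndarray
    channel_names: dict[str, dict[str, tuple[str, str, str]]] = field(default_factory=dict)

    @property
    def trial_id(self) -> str:
        return f"{self.subject_id}_{self.pace}"

    @property
    def n_samples(self) -> int:
        return len(self.reference_speed)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def devices(self) -> tuple[str, ...]:
        return tuple(self.channels)


def generate_subject_profile(rng_seed: int, subject_id: str | None = None) -> SubjectProfile:
    """Draw a subject's gait parameters; deterministic for a fixed seed."""
    rng = np.random.default_rng(rng_seed)
    base = {p: float(rng.uniform(*PACE_SPEED_RANGES[p])) for p in PACES}
    return SubjectProfile(
        subject_id=subject_id if subject_id is not None else f"S{rng_seed % 10**6}",
        base_speeds=base,
        cadence_slope=float(rng.uniform(0.85, 0.95)),
        cadence_intercept=float(rng.uniform(0.85, 0.95)),
        amp_scale=float(rng.uniform(0.8, 1.2)),
        noise_sd_acc=float(rng.uniform(0.1, 0.3)),
        noise_sd_gyr=float(rng.uniform(0.02, 0.08)),
    )


def _speed_profile(base: float, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Instantaneous speed: base pace, slow drift, and turn dips every ~10 m."""
    t = np.arange(n) / fs
    phase = rng.uniform(0, 2 * np.pi)
    v = base * (1.0 + 0.04 * np.sin(2 * np.pi * t / 45.0 + phase))
    # place turns where the un-dipped profile has covered each 10 m leg
    dist = np.cumsum(v) / fs
    n_turns = int(dist[-1] // PATH_LENGTH_M)
    starts = np.searchsorted(dist, PATH_LENGTH_M * np.arange(1, n_turns + 1))
    for s in starts:
        dur = rng.uniform(1.0, 2.0)
        depth = rng.uniform(0.2, 0.4)  # peak fractional speed reduction
        m = int(round(dur * fs))
        e = min(s + m, n)
        if e <= s:
            continue
        # smooth half-sine dip: full reduction mid-turn, zero at the edges
        shape = np.sin(np.pi * np.arange(e - s) / m) ** 2
        v[s:e] *= 1.0 - depth * shape
    return v


def synthesize_trial(
    profile: SubjectProfile,
    pace: str,
    duration: float = 360.0,
    seed: int = 0,
) -> TrialRecording:
    """Simulate one walking trial for ``profile`` at the given pace.

    All periodic content is driven by the instantaneous step frequency
    ``f(t) = cadence_intercept + cadence_slope * v(t)`` through the running
    phase ``phi(t)``.  The vertical accelerometer channel of every device is
    a gravity offset plus two harmonics of the step frequency whose
    amplitude scales with speed; gyroscope channels are zero-mean band-limited
    oscillations; orientation channels are slowly varying angles with a
    step-frequency ripple; insole pressure channels are rectified,
    phase-shifted pulse trains.
    """
    if pace not in PACES:
        raise ValueError(f"unknown pace {pace!r}; expected one of {PACES}")
    if duration < 30:
        raise ValueError("trial duration must be >= 30 s")
    fs = SAMPLING_RATE_HZ
    n = int(round(duration * fs))
    rng = np.random.default_rng(np.random.SeedSequence([seed, PACES.index(pace)]))

    v = _speed_profile(profile.base_speeds[pace], n, fs, rng)
    f_step = profile.cadence_intercept + profile.cadence_slope * v
    phi = 2 * np.pi * np.cumsum(f_step) / fs
    t = np.arange(n) / fs

    a1 = 0.35 * profile.amp_scale * v * GRAVITY  # vertical acc amplitude
    g1 = 0.6 * profile.amp_scale * v  # gyro amplitude, rad/s

    def acc_group(device: str, dphi: float) -> np.ndarray:
        """Tri-axial accelerometer: gravity on the vertical axis, two
        harmonics of the step frequency, weaker quadrature horizontals."""
        vert = (
            GRAVITY
            + a1 * np.sin(phi + dphi)
            + 0.4 * a1 * np.sin(2 * (phi + dphi) + 0.3)
        )
        h1 = 0.45 * a1 * np.sin(phi + dphi + 1.1)
        h2 = 0.30 * a1 * np.sin(phi + dphi + 2.3)
        # assemble in x, y, z order with the vertical channel in place
        out = []
        horizontals = iter((h1, h2))
        for ax in ("x", "y", "z"):
            out.append(vert if ax == VERTICAL_AXIS[device] else next(horizontals))
        arr = np.column_stack(out)
        arr += rng.normal(0.0, profile.noise_sd_acc, arr.shape)
        return arr

    def gyr_group(dphi: float) -> np.ndarray:
        cols = [
            g1 * np.sin(phi + dphi + off) + 0.3 * g1 * np.sin(2 * phi + off)
            for off in (0.0, 1.5, 3.0)
        ]
        arr = np.column_stack(cols)
        arr += rng.normal(0.0, profile.noise_sd_gyr, arr.shape)
        return arr

    def ori_group() -> np.ndarray:
        ripple = 1.5 * profile.amp_scale * v
        az = 12.0 * np.sin(2 * np.pi * t / 40.0) + ripple * np.sin(phi + 0.4)
        pitch = 5.0 + 2.0 * np.sin(2 * np.pi * t / 55.0) + ripple * np.sin(phi + 1.7)
        roll = -3.0 + 1.5 * np.sin(2 * np.pi * t / 35.0) + ripple * np.sin(phi + 2.9)
        arr = np.column_stack([az, pitch, roll])
        arr += rng.normal(0.0, 0.3, arr.shape)
        return arr

    def press_group(foot_phase: float) -> np.ndarray:
        amp = 150.0 * profile.amp_scale * (0.5 + 0.5 * v / 1.5)  # mV
        cols = []
        for off in (0.0, 0.6, 1.2):  # heel -> forefoot roll-over
            pulse = amp * np.clip(np.sin(phi + foot_phase + off), 0.0, None) ** 2
            cols.append(pulse)
        arr = np.column_stack(cols)
        arr += rng.normal(0.0, 2.0, arr.shape)
        return np.clip(arr, 0.0, None)

    channels: dict[str, dict[str, np.ndarray]] = {
        "phone": {"acc": acc_group("phone", 0.0), "ori": ori_group()},
        "watch": {"acc": acc_group("watch", 0.7), "gyr": gyr_group(0.7)},
        "shoe_left": {
            "acc": acc_group("shoe_left", 0.0),
            "gyr": gyr_group(0.0),
            "press": press_group(0.0),
        },
        "shoe_right": {
            "acc": acc_group("shoe_right", np.pi),
            "gyr": gyr_group(np.pi),
            "press": press_group(np.pi),
        },
    }
    names = {dev: dict(SENSOR_GROUPS[dev]) for dev in channels}
    return TrialRecording(
        subject_id=profile.subject_id,
        pace=pace,
        fs=fs,
        channels=channels,
        reference_speed=v,
        channel_names=names,
    )


def generate_cohort(
    n_subjects: int = 20,
    seed: int = 0,
    duration: float = 360.0,
) -> list[TrialRecording]:
    """Generate ``3 * n_subjects`` trials (one per pace per subject)."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects (leave-one-subject-out undefined)")
    ss = np.random.SeedSequence(seed)
    states = ss.generate_state(2 * n_subjects)
    trials: list[TrialRecording] = []
    for i in range(n_subjects):
        profile = generate_subject_profile(
            int(states[2 * i]), subject_id=f"S{i + 1:02d}"
        )
        trial_seed = int(states[2 * i + 1]) % (2**31)
        for pace in PACES:
            trials.append(synthesize_trial(profile, pace, duration=duration, seed=trial_seed))
    return trials
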