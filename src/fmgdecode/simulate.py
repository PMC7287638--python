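"""Synthetic force-myography wristband recordings.

Generates multichannel barometric-pressure time series with the statistical
structure the decoding pipeline assumes: each trial cycles through the five
fingers (thumb..pinky) in order, one finger flexing/extending at the
metacarpophalangeal (MCP) joint per segment, while a ring of pressure sensors
around the wrist responds to the movement through a finger-specific coupling
pattern.

The generative model is a stand-in for real wristband physiology, not a claim
about it: a raised-cosine MCP-angle trajectory drives a monotone saturating
channel response, corrupted by slow random-walk drift and Gaussian noise.
Channel/finger coupling patterns are sparse and distinct per finger, and vary
between subjects but not between a subject's trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SimConfig",
    "TrialRecording",
    "InvalidConfigError",
    "angle_trajectory",
    "sensor_response",
    "simulate_trial",
    "simulate_dataset",
    "subject_coupling",
]

N_FINGERS = 5

#: Per-finger MCP flexion range in degrees: thumb 0-55, other fingers 0-90.
DEFAULT_AMPLITUDES = (55.0, 90.0, 90.0, 90.0, 90.0)


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration is inconsistent."""


@dataclass(frozen=True)
class SimConfig:
    """Study-design and noise parameters for the synthetic wristband cohort.

    Defaults reproduce the reference protocol: 10 subjects x 10 trials,
    5 s per finger x 5 fingers at 40 Hz = 1000 samples per trial, i.e.
    100,000 samples over the full design.
    """

    n_subjects: int = 10
    n_trials_per_subject: int = 10
    seconds_per_finger: float = 5.0
    sample_rate: float = 40.0
    n_channels: int = 10
    amplitude_per_finger: tuple[float, ...] = DEFAULT_AMPLITUDES
    flexion_freq_range: tuple[float, float] = (0.4, 0.6)
    coupling_strength: float = 1.0
    crosstalk: float = 0.1
    noise_sd: float = 0.05
    drift_sd: float = 0.005
    #: per-subject amplitude attenuation in [0.85, 1.0] (some subjects cannot
    #: reach the nominal maximum flexion); set False for exact nominal ranges.
    subject_attenuation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials_per_subject < 1:
            raise InvalidConfigError("need at least one subject and one trial")
        if self.seconds_per_finger <= 0 or self.sample_rate <= 0:
            raise InvalidConfigError("seconds_per_finger and sample_rate must be positive")
        n = self.seconds_per_finger * self.sample_rate
        if abs(n - round(n)) > 1e-9:
            raise InvalidConfigError(
                f"seconds_per_finger*sample_rate = {n} is not an integer sample count"
            )
        if self.n_channels < 2:
            raise InvalidConfigError("need at least two channels")
        if len(self.amplitude_per_finger) != N_FINGERS:
            raise InvalidConfigError("amplitude_per_finger must have five entries")
        if any(a <= 0 for a in self.amplitude_per_finger):
            raise InvalidConfigError("amplitudes must be positive")
        if not (0.0 <= self.crosstalk < 1.0):
            raise InvalidConfigError("crosstalk must lie in [0, 1)")
        if self.noise_sd < 0 or self.drift_sd < 0:
            raise InvalidConfigError("noise_sd and drift_sd must be non-negative")
        lo, hi = self.flexion_freq_range
        if not (0 < lo <= hi):
            raise InvalidConfigError("flexion_freq_range must be a positive interval")

    @property
    def samples_per_segment(self) -> int:
        return int(round(self.seconds_per_finger * self.sample_rate))

    @property
    def samples_per_trial(self) -> int:
        return self.samples_per_segment * N_FINGERS


@dataclass
class TrialRecording:
    """One trial: pressures [T x n_channels], per-sample finger label 0..4
    (thumb..pinky) and ground-truth MCP angle in degrees."""

    subject_id: int
    trial_id: int
    pressures: np.ndarray
    labels: np.ndarray
    angles: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.pressures = np.asarray(self.pressures, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.angles = np.asarray(self.angles, dtype=float)
        t = self.pressures.shape[0]
        if self.labels.shape != (t,) or self.angles.shape != (t,):
            raise ValueError("pressures, labels and angles must share their time length")

    @property
    def n_samples(self) -> int:
        return self.pressures.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pressures.shape[1]


def angle_trajectory(
    finger_class: int,
    duration: float,
    sample_rate: float,
    amplitude: float,
    freq: float,
    phase: float = 0.0,
) -> np.ndarray:
    """Raised-cosine MCP-angle trajectory for one flexion/extension segment.

    theta(t) = amplitude/2 * (1 - cos(2*pi*freq*t + phase)), sampled at
    ``sample_rate`` for ``duration`` seconds. Ranges over [0, amplitude] with
    repeated smooth flexion/extension cycles at ``freq`` Hz.
    """
    if duration <= 0 or sample_rate <= 0:
        raise InvalidConfigError("duration and sample_rate must be positive")
    if amplitude <= 0 or freq <= 0:
        raise InvalidConfigError("amplitude and freq must be positive")
    if not 0 <= finger_class < N_FINGERS:
        raise InvalidConfigError(f"finger_class must be in 0..{N_FINGERS - 1}")
    n = int(round(duration * sample_rate))
    t = np.arange(n) / sample_rate
    return amplitude / 2.0 * (1.0 - np.cos(2.0 * math.pi * freq * t + phase))


def _saturating(u: np.ndarray) -> np.ndarray:
    """Fixed monotone saturating map on [0, 1] with g(0)=0, g(1)=1."""
    return np.tanh(1.5 * u) / math.tanh(1.5)


def sensor_response(
    angles_by_finger: np.ndarray,
    coupling: np.ndarray,
    baseline: np.ndarray,
    noise_sd: float = 0.0,
    drift_sd: float = 0.0,
    seed: int | np.random.SeedSequence | None = 0,
    amplitudes: tuple[float, ...] = DEFAULT_AMPLITUDES,
) -> np.ndarray:
    """Map per-finger MCP angles [T x 5] to channel pressures [T x C].

    pressures = baseline + coupling @ g(angles/amplitude) + drift + noise,
    where g is a fixed monotone saturating map on [0, 1], drift is a Gaussian
    random walk (per-step sd ``drift_sd``) and noise is iid Gaussian
    (sd ``noise_sd``). Deterministic given the seed; exactly ``baseline`` plus
    the coupling term when both noise terms are zero.
    """
    angles_by_finger = np.asarray(angles_by_finger, dtype=float)
    coupling = np.asarray(coupling, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if angles_by_finger.ndim != 2 or angles_by_finger.shape[1] != N_FINGERS:
        raise ValueError("angles_by_finger must be [T x 5]")
    if coupling.ndim != 2 or coupling.shape[1] != N_FINGERS:
        raise ValueError("coupling must be [n_channels x 5]")
    n_channels = coupling.shape[0]
    if baseline.shape != (n_channels,):
        raise ValueError("baseline length must equal the channel count")
    if np.any(coupling < 0):
        raise ValueError("coupling must be non-negative")
    activation = _saturating(angles_by_finger / np.asarray(amplitudes, dtype=float))
    pressures = baseline[None, :] + activation @ coupling.T
    if noise_sd > 0 or drift_sd > 0:
        rng = np.random.default_rng(seed)
        t = angles_by_finger.shape[0]
        if drift_sd > 0:
            pressures = pressures + np.cumsum(
                rng.normal(0.0, drift_sd, size=(t, n_channels)), axis=0
            )
        if noise_sd > 0:
            pressures = pressures + rng.normal(0.0, noise_sd, size=(t, n_channels))
    return pressures


def _subject_seed(config: SimConfig, subject_id: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([config.seed, int(subject_id)])


def _trial_seed(config: SimConfig, subject_id: int, trial_id: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([config.seed, int(subject_id), int(trial_id)])


def subject_coupling(config: SimConfig, subject_id: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-subject (coupling [C x 5], baseline [C], amplitude attenuation).

    Each finger couples strongly to a distinct pair of channels (channels
    2f and 2f+1 modulo C for finger f), with weaker crosstalk onto the rest;
    strengths are jittered per subject so that inter-subject variability is
    present, but a subject's coupling is identical across trials.
    """
    rng = np.random.default_rng(_subject_seed(config, subject_id))
    c, s = config.n_channels, config.coupling_strength
    coupling = config.crosstalk * s * rng.uniform(0.0, 1.0, size=(c, N_FINGERS))
    for f in range(N_FINGERS):
        for ch in ((2 * f) % c, (2 * f + 1) % c):
            coupling[ch, f] = s * rng.uniform(0.8, 1.2)
    baseline = rng.uniform(0.5, 1.5, size=c)
    attenuation = rng.uniform(0.85, 1.0) if config.subject_attenuation else 1.0
    return coupling, baseline, attenuation


def simulate_trial(
    config: SimConfig,
    subject_id: int,
    trial_id: int,
) -> TrialRecording:
    """Simulate one trial: five contiguous equal-length segments in the order
    thumb, index, middle, ring, pinky; only the active finger's angle is
    nonzero within its segment.

    All randomness derives from ``config.seed`` via the per-(subject, trial)
    seed sequence [seed, subject_id, trial_id], so any trial is reproducible
    in isolation.
    """
    coupling, baseline, attenuation = subject_coupling(config, subject_id)
    rng = np.random.default_rng(_trial_seed(config, subject_id, trial_id))
    n_seg = config.samples_per_segment
    lo, hi = config.flexion_freq_range
    phase = rng.uniform(0.0, 2.0 * math.pi)

    angles_by_finger = np.zeros((config.samples_per_trial, N_FINGERS))
    labels = np.repeat(np.arange(N_FINGERS), n_seg)
    for f in range(N_FINGERS):
        freq = rng.uniform(lo, hi)
        amp = attenuation * config.amplitude_per_finger[f]
        seg = angle_trajectory(
            f, config.seconds_per_finger, config.sample_rate, amp, freq, phase
        )
        angles_by_finger[f * n_seg : (f + 1) * n_seg, f] = seg

    pressures = sensor_response(
        angles_by_finger,
        coupling,
        baseline,
        noise_sd=config.noise_sd,
        drift_sd=config.drift_sd,
        seed=rng.bit_generator.random_raw(4).tolist(),
        amplitudes=config.amplitude_per_finger,
    )
    angles = angles_by_finger[np.arange(config.samples_per_trial), labels]
    return TrialRecording(
        subject_id=subject_id,
        trial_id=trial_id,
        pressures=pressures,
        labels=labels,
        angles=angles,
        sample_rate=config.sample_rate,
    )


def simulate_dataset(config: SimConfig) -> list[TrialRecording]:
    """Simulate the full cohort: n_subjects x n_trials_per_subject recordings,
    ordered by (subject_id, trial_id)."""
    return [
        simulate_trial(config, subject, trial)
        for subject in range(config.n_subjects)
        for trial in range(config.n_trials_per_subject)
    ]
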