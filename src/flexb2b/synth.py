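"""Synthetic SSVEP EEG trials and command-conditioned mouse trajectories.

The generators emulate the statistical structure the downstream analyses
assume: occipital EEG containing a steady-state visual evoked response at
one of eight joint frequency-phase targets (8-15 Hz in 1 Hz steps, phases
cycling 0, pi/2, pi, 3pi/2) riding on 1/f-plus-white background noise, and
2-D trajectories whose heading drifts at a command-dependent rate during
the stimulation phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CHANNEL_NAMES",
    "COMMANDS",
    "TargetCode",
    "EEGTrial",
    "SynthSpec",
    "TrajectorySpec",
    "Trajectory",
    "target_table",
    "synth_ssvep_trial",
    "synth_dataset",
    "synth_trajectory",
]

#: Occipital montage used for SSVEP recording, in acquisition order.
CHANNEL_NAMES = ("O1", "POz", "PO3", "PO5", "Oz", "PO6", "PO4", "O2")

#: Two-letter motion commands for the two mice (first letter = mouse 1).
COMMANDS = ("LL", "RR", "LR", "RL", "LX", "RX", "XL", "XR")


@dataclass(frozen=True)
class TargetCode:
    """One flicker target: joint frequency-phase code plus its command."""

    index: int
    frequency: float  # Hz
    phase: float  # radians
    command: str

    def __post_init__(self):
        if not 0 <= self.index <= 7:
            raise ValueError(f"target index must be 0-7, got {self.index}")


def target_table() -> list[TargetCode]:
    """The eight stimulus targets, index-ordered.

    Frequencies run 8..15 Hz at 1 Hz spacing; phase offsets cycle
    0, pi/2, pi, 3pi/2 twice; commands are assigned in the fixed order
    LL, RR, LR, RL, LX, RX, XL, XR.
    """
    return [
        TargetCode(i, 8.0 + i, (i % 4) * math.pi / 2, COMMANDS[i])
        for i in range(8)
    ]


@dataclass
class EEGTrial:
    """One multichannel EEG trial (channels x samples, microvolts)."""

    data: np.ndarray
    fs: float = 1000.0
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    label: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("trial data must be channels x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("trial contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class SynthSpec:
    """Parameters of the SSVEP trial generator.

    ``snr_db`` is the ratio of SSVEP component power to noise power in the
    4-100 Hz band, in dB; ``np.inf`` yields a noise-free trial.  The k-th
    harmonic's amplitude is ``k ** -harmonic_decay`` (default 1/k) and its
    phase is ``k * phase``, i.e. a periodic non-sinusoidal response.
    """

    n_harmonics: int = 3
    harmonic_decay: float = 1.0
    noise_model: str = "mixture"  # white | pink | mixture
    snr_db: float = 10.0
    duration: float = 1.0
    fs: float = 1000.0
    amplitude_uv: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.duration < 0.2:
            raise ValueError("duration must be at least 0.2 s")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.n_harmonics < 1:
            raise ValueError("need at least one harmonic")
        if self.noise_model not in ("white", "pink", "mixture"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


_NOISE_BAND = (4.0, 100.0)


def _background_noise(rng: np.random.Generator, n_ch: int, n: int, fs: float,
                      model: str) -> np.ndarray:
    """Unit-scale EEG-like background: white, pink (1/f) or equal-power mix."""
    white = rng.standard_normal((n_ch, n))
    if model == "white":
        return white
    # shape white noise to 1/f amplitude in the frequency domain
    spec = np.fft.rfft(rng.standard_normal((n_ch, n)), axis=1)
    f = np.fft.rfftfreq(n, 1 / fs)
    scale = np.zeros_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    pink = np.fft.irfft(spec * scale, n=n, axis=1)
    pink /= pink.std() + 1e-30
    if model == "pink":
        return pink
    return (white + pink) / math.sqrt(2.0)


def _band_power(x: np.ndarray, fs: float, band=_NOISE_BAND) -> float:
    """Mean power of ``x`` restricted to a frequency band (periodogram sum)."""
    spec = np.fft.rfft(x, axis=-1)
    f = np.fft.rfftfreq(x.shape[-1], 1 / fs)
    sel = (f >= band[0]) & (f <= band[1])
    # Parseval: power = sum |X_k|^2 * w_k / n^2, one-sided weights
    w = np.full_like(f, 2.0)
    w[0] = 1.0
    if x.shape[-1] % 2 == 0:
        w[-1] = 1.0
    p = (np.abs(spec) ** 2 * w)[..., sel].sum(axis=-1) / x.shape[-1] ** 2
    return float(p.sum())


def synth_ssvep_trial(target: TargetCode, spec: SynthSpec,
                      return_components: bool = False):
    """Generate one labelled SSVEP trial.

    The SSVEP component is a harmonic series at the target frequency,
    mixed across channels with a fixed all-positive random gain vector
    (every occipital channel sees the response at a different amplitude),
    plus background noise scaled to ``spec.snr_db``.  Deterministic given
    ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.fs * spec.duration))
    t = np.arange(n) / spec.fs

    s = np.zeros(n)
    for k in range(1, spec.n_harmonics + 1):
        amp = k ** (-spec.harmonic_decay)
        s += amp * np.sin(2 * math.pi * k * target.frequency * t
                          + k * target.phase)
    gains = 0.5 + rng.random(len(CHANNEL_NAMES))  # all positive
    signal = spec.amplitude_uv * gains[:, None] * s[None, :]

    if np.isinf(spec.snr_db):
        noise = np.zeros_like(signal)
    else:
        noise = _background_noise(rng, signal.shape[0], n, spec.fs,
                                  spec.noise_model)
        p_sig = _band_power(signal, spec.fs)
        p_noise = _band_power(noise, spec.fs)
        want = p_sig / 10 ** (spec.snr_db / 10)
        noise *= math.sqrt(want / p_noise)

    trial = EEGTrial(signal + noise, fs=spec.fs, label=target.index)
    if return_components:
        return trial, signal, noise
    return trial


def synth_dataset(n_per_class: int, spec: SynthSpec) -> list[EEGTrial]:
    """Balanced labelled dataset: ``8 * n_per_class`` trials.

    Per-trial seeds are spawned deterministically from ``spec.seed`` so the
    whole dataset is a pure function of the spec.  Trials are ordered
    class-major (all label-0 trials first); shuffle at training time.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    targets = target_table()
    seeds = np.random.SeedSequence(spec.seed).generate_state(8 * n_per_class)
    trials = []
    for c, tgt in enumerate(targets):
        for r in range(n_per_class):
            sub = replace(spec, seed=int(seeds[c * n_per_class + r]))
            trials.append(synth_ssvep_trial(tgt, sub))
    return trials


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class TrajectorySpec:
    """Command-conditioned mouse trajectory generator parameters.

    ``command_letter`` 'L' turns counterclockwise (positive heading drift)
    during stimulation, 'R' clockwise, 'X' not at all.  Outside the
    stimulation window the animal performs a near-stationary jittering walk
    whose step lengths stay below the behavior module's minimum-motion
    threshold.  ``jitter`` scales both heading noise (3 deg/step * jitter)
    and resting step length (0.3 mm * jitter).
    """

    command_letter: str = "L"
    phase_durations: tuple[float, float, float] = (10.0, 10.0, 10.0)
    turn_rate: float = 25.0  # deg/s during stimulation, unsigned
    speed: float = 45.0  # mm/s during stimulation
    jitter: float = 1.0
    sample_rate: float = 30.0  # video-tracking-like
    seed: int = 0

    def validate(self) -> None:
        if self.command_letter not in ("L", "R", "X"):
            raise ValueError("command letter must be L, R or X")
        if any(d <= 0 for d in self.phase_durations):
            raise ValueError("phase durations must be positive")
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")


@dataclass
class Trajectory:
    """Timestamped 2-D positions of one mouse (seconds, millimetres)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    phases: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("coordinates must be finite")


def synth_trajectory(spec: TrajectorySpec) -> Trajectory:
    """Generate one before/during/after trajectory.

    During stimulation the heading drifts at ``+turn_rate`` deg/s for 'L',
    ``-turn_rate`` for 'R' and 0 for 'X' while the animal moves at
    ``speed``; at ``jitter=0`` the net during-phase heading change is
    exactly ``sign * turn_rate * duration``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    dt = 1.0 / spec.sample_rate
    n_b, n_d, n_a = (int(round(d * spec.sample_rate))
                     for d in spec.phase_durations)
    sign = {"L": 1.0, "R": -1.0, "X": 0.0}[spec.command_letter]

    heading = 0.0  # degrees
    pos = np.zeros(2)
    xs, ys = [pos[0]], [pos[1]]
    head_noise = 3.0 * spec.jitter  # deg per step
    rest_step = 0.3 * spec.jitter  # mm per step, sub-threshold

    def rest_steps(k):
        nonlocal pos
        for _ in range(k):
            ang = rng.uniform(0, 2 * math.pi)
            r = rest_step * rng.random()
            pos = pos + [r * math.cos(ang), r * math.sin(ang)]
            xs.append(pos[0]); ys.append(pos[1])

    rest_steps(n_b)
    moving = spec.command_letter != "X"
    for _ in range(n_d):
        if moving:
            heading += sign * spec.turn_rate * dt
            heading += head_noise * rng.standard_normal() * math.sqrt(dt)
            step = spec.speed * dt
            h = math.radians(heading)
            pos = pos + [step * math.cos(h), step * math.sin(h)]
            xs.append(pos[0]); ys.append(pos[1])
        else:
            rest_steps(1)
    rest_steps(n_a)

    t = np.arange(len(xs)) * dt
    t_b = n_b * dt
    t_d = t_b + n_d * dt
    phases = {"before": (0.0, t_b), "during": (t_b, t_d),
              "after": (t_d, t[-1] + 0.5 * dt)}
    return Trajectory(t, np.array(xs), np.array(ys), phases)
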