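"""Command mapping and charge-balanced biphasic stimulation synthesis.

Each decoded class carries a two-letter command, one letter per mouse:
'L' commands a left turn by stimulating the right secondary motor cortex
(M2), 'R' a right turn by stimulating the left M2, 'X' no stimulation.
The stimulation waveform is a cathodic-leading biphasic pulse train:
200 us cathodic at amplitude -I, a 100 us interphase gap, then 400 us
anodic at +I/2, repeated at 100 Hz, so each pulse is exactly
charge-balanced (200 us x I = 400 us x I/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synth import COMMANDS

__all__ = [
    "StimParams",
    "StimCommand",
    "StimTrain",
    "class_to_command",
    "make_biphasic_train",
    "accelerated_aging_equivalent",
]

_ACTIONS = {
    "L": "stimulate-right-M2",
    "R": "stimulate-left-M2",
    "X": "none",
}


@dataclass(frozen=True)
class StimCommand:
    """Per-mouse stimulation actions derived from a two-letter command."""

    command: str
    mouse1: str
    mouse2: str


def class_to_command(index: int) -> StimCommand:
    """Map a decoded class (0-7) to the per-mouse stimulation pair."""
    if not 0 <= index <= 7:
        raise ValueError(f"class index must be 0-7, got {index}")
    cmd = COMMANDS[index]
    return StimCommand(cmd, _ACTIONS[cmd[0]], _ACTIONS[cmd[1]])


@dataclass
class StimParams:
    """Biphasic pulse-train parameters (times in seconds, currents in uA).

    ``anodic_amp`` defaults to half the cathodic amplitude, which together
    with the 200/400 us phase widths gives zero net charge per pulse.
    ``fs_out`` defaults to 1 MHz so every phase width is an integer number
    of samples and charge balance is bit-exact.
    """

    cathodic_amp: float = 5.0
    anodic_amp: float | None = None
    cathodic_width: float = 200e-6
    interphase_gap: float = 100e-6
    anodic_width: float = 400e-6
    rate: float = 100.0
    duration: float = 1.0
    fs_out: float = 1e6

    def __post_init__(self):
        if self.anodic_amp is None:
            self.anodic_amp = self.cathodic_amp / 2.0
        if self.cathodic_amp <= 0 or self.anodic_amp <= 0:
            raise ValueError("amplitudes must be positive")
        if self.fs_out < 1e5:
            raise ValueError(
                "fs_out must be >= 100 kHz to resolve 100 us features")
        active = self.cathodic_width + self.interphase_gap + self.anodic_width
        if active >= 1.0 / self.rate:
            raise ValueError("active pulse span exceeds the pulse period")

    def samples_per(self, width: float) -> int:
        n = width * self.fs_out
        if abs(n - round(n)) > 1e-9:
            fs_ok = round(1.0 / np.gcd(int(self.cathodic_width * 1e7),
                                       np.gcd(int(self.interphase_gap * 1e7),
                                              int(self.anodic_width * 1e7)))
                          * 1e7)
            raise ValueError(
                f"fs_out={self.fs_out} does not represent a {width*1e6:.0f} "
                f"us phase exactly; use a multiple of {fs_ok:.0f} Hz")
        return int(round(n))


@dataclass
class StimTrain:
    """Sampled biphasic current waveform (uA) and its parameter snapshot."""

    samples: np.ndarray
    params: StimParams

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.params.fs_out

    @property
    def n_pulses(self) -> int:
        return int(round(self.params.duration * self.params.rate))

    def net_charge(self) -> float:
        """Total charge in uA*s; zero for a balanced train."""
        return float(self.samples.sum() / self.params.fs_out)


def make_biphasic_train(params: StimParams | None = None) -> StimTrain:
    """Synthesize the cathodic-leading biphasic pulse train.

    Cathodic current is encoded as negative.  Each period holds -I for the
    cathodic width, 0 for the interphase gap, +anodic_amp for the anodic
    width, then 0 until the next period.
    """
    params = params or StimParams()
    n_cat = params.samples_per(params.cathodic_width)
    n_gap = params.samples_per(params.interphase_gap)
    n_ano = params.samples_per(params.anodic_width)
    n_period = params.samples_per(1.0 / params.rate)
    pulse = np.zeros(n_period)
    pulse[:n_cat] = -params.cathodic_amp
    pulse[n_cat + n_gap:n_cat + n_gap + n_ano] = params.anodic_amp
    n_pulses = int(round(params.duration * params.rate))
    return StimTrain(np.tile(pulse, n_pulses), params)


def accelerated_aging_equivalent(test_temp_c: float, real_temp_c: float,
                                 test_duration_weeks: float,
                                 q10: float = 2.0) -> float:
    """Equivalent real-time duration of an elevated-temperature soak.

    ASTM-style accelerated aging: time scales by ``q10 ** (dT / 10)``.
    A 4-week soak at 60 C corresponds to ~19.7 weeks at body temperature.
    """
    if q10 <= 0:
        raise ValueError("q10 must be positive")
    if test_duration_weeks <= 0:
        raise ValueError("duration must be positive")
    if not (np.isfinite(test_temp_c) and np.isfinite(real_temp_c)):
        raise ValueError("temperatures must be finite")
    return test_duration_weeks * q10 ** ((test_temp_c - real_temp_c) / 10.0)
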