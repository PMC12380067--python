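"""EEG preprocessing: power-line notches, Butterworth band-pass, tensors.

Filters are second-order Butterworth sections applied forward-backward
(zero-phase), matching an offline decoding pipeline where waveform shape
matters more than causality.  Defaults: band-stops at 48-52 and 98-102 Hz
and a 4-100 Hz band-pass.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .synth import EEGTrial

__all__ = ["FilterSpec", "notch_filter", "bandpass_filter",
           "preprocess_trial", "to_tensor"]


@dataclass
class FilterSpec:
    """Filter bands in Hz; ``order`` is the analogue prototype order."""

    notch_bands: tuple[tuple[float, float], ...] = ((48.0, 52.0),
                                                    (98.0, 102.0))
    bandpass: tuple[float, float] = (4.0, 100.0)
    order: int = 2
    zero_phase: bool = True

    def _check_band(self, lo: float, hi: float, fs: float) -> None:
        if not 0 < lo < hi < fs / 2:
            raise ValueError(
                f"band ({lo}, {hi}) Hz outside (0, fs/2) for fs={fs}")


def _apply_sos(trial: EEGTrial, sos: np.ndarray,
               zero_phase: bool) -> EEGTrial:
    if zero_phase:
        out = signal.sosfiltfilt(sos, trial.data, axis=-1)
    else:
        out = signal.sosfilt(sos, trial.data, axis=-1)
    return EEGTrial(out, fs=trial.fs, channel_names=trial.channel_names,
                    label=trial.label)


def notch_filter(trial: EEGTrial, spec: FilterSpec | None = None) -> EEGTrial:
    """Attenuate the power-line bands with Butterworth band-stops.

    Applied forward-backward so passband phase is preserved; output has
    the same shape as the input.
    """
    spec = spec or FilterSpec()
    out = trial
    for lo, hi in spec.notch_bands:
        spec._check_band(lo, hi, trial.fs)
        sos = signal.butter(spec.order, (lo, hi), btype="bandstop",
                            fs=trial.fs, output="sos")
        out = _apply_sos(out, sos, spec.zero_phase)
    return out


def bandpass_filter(trial: EEGTrial,
                    spec: FilterSpec | None = None) -> EEGTrial:
    """Second-order Butterworth band-pass (default 4-100 Hz), zero-phase."""
    spec = spec or FilterSpec()
    lo, hi = spec.bandpass
    spec._check_band(lo, hi, trial.fs)
    sos = signal.butter(spec.order, (lo, hi), btype="bandpass", fs=trial.fs,
                        output="sos")
    return _apply_sos(trial, sos, spec.zero_phase)


def preprocess_trial(trial: EEGTrial,
                     spec: FilterSpec | None = None) -> EEGTrial:
    """Notch filtering followed by the band-pass, as used before decoding."""
    spec = spec or FilterSpec()
    return bandpass_filter(notch_filter(trial, spec), spec)


def to_tensor(trials: list[EEGTrial]) -> tuple[np.ndarray, np.ndarray]:
    """Stack trials into a (batch, 1, channels, time_steps) tensor.

    Returns ``(tensor, labels)`` with input order preserved; unlabelled
    trials get label -1.
    """
    if not trials:
        raise ValueError("no trials")
    shape = trials[0].data.shape
    if any(t.data.shape != shape for t in trials):
        raise ValueError("trials have heterogeneous shapes")
    x = np.stack([t.data for t in trials])[:, None, :, :].astype(np.float32)
    y = np.array([-1 if t.label is None else t.label for t in trials],
                 dtype=np.int64)
    return x, y
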