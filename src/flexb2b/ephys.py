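"""Spike-waveform and firing-rate summaries for recording stability.

Consumes already-sorted spike trains and mean waveforms (spike sorting
itself is upstream); provides the peak-to-peak amplitude, an SNR defined
as p2p / (k * noise SD) with k configurable, firing-rate binning, and the
rate-velocity correlation used to relate single units to locomotion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["p2p_amplitude", "spike_snr", "firing_rate",
           "rate_velocity_correlation", "load_spike_trains"]


def p2p_amplitude(waveform) -> float:
    """Peak-to-peak amplitude max - min, in the waveform's units (uV)."""
    w = np.asarray(waveform, dtype=float)
    if w.size == 0:
        raise ValueError("empty waveform")
    return float(w.max() - w.min())


def spike_snr(waveform, noise_trace, k: float = 2.0) -> float:
    """Waveform p2p divided by ``k`` times the noise standard deviation.

    ``noise_trace`` must be a spike-free recording segment.  There is no
    single field convention for spike SNR; report k alongside the value.
    """
    noise = np.asarray(noise_trace, dtype=float)
    sd = noise.std()
    if sd == 0:
        raise ValueError("noise trace has zero variance")
    return p2p_amplitude(waveform) / (k * sd)


def firing_rate(spike_times, bin_s: float,
                t_span: tuple[float, float] | None = None):
    """Binned firing rate in Hz.

    Returns ``(t_centers, rates)``; the rate series integrates back to the
    total spike count within the span.
    """
    if bin_s <= 0:
        raise ValueError("bin width must be positive")
    times = np.sort(np.asarray(spike_times, dtype=float))
    if t_span is None:
        t_span = (0.0, float(times[-1]) if len(times) else bin_s)
    n_bins = max(1, int(np.ceil((t_span[1] - t_span[0]) / bin_s)))
    edges = t_span[0] + np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(times, bins=edges)
    return 0.5 * (edges[:-1] + edges[1:]), counts / bin_s


def rate_velocity_correlation(rate_series, velocity_series) -> float:
    """Pearson correlation between firing rate and max-normalized velocity."""
    r = np.asarray(rate_series, dtype=float)
    v = np.asarray(velocity_series, dtype=float)
    if len(r) != len(v):
        raise ValueError("series must have equal length")
    if len(r) < 10:
        raise ValueError("need at least 10 bins")
    if v.max() > 0:
        v = v / v.max()
    if r.std() == 0 or v.std() == 0:
        raise ValueError("correlation undefined for a constant series")
    return float(np.corrcoef(r, v)[0, 1])


def load_spike_trains(path) -> pd.DataFrame:
    """Read sorted spikes as CSV with columns time, neuron, channel."""
    df = pd.read_csv(path)
    missing = {"time", "neuron", "channel"} - set(df.columns)
    if missing:
        raise ValueError(f"spike CSV missing columns {sorted(missing)}")
    return df.sort_values("time").reset_index(drop=True)
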