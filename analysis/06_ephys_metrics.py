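#!/usr/bin/env python
"""Spike-train stability metrics on synthetic sorted units.

Builds eight synthetic units (velocity-modulated Poisson firing, fixed
mean waveforms) and reports peak-to-peak amplitude, SNR (p2p / 2*noise
SD) and the firing-rate vs. normalized-velocity correlation for
positively and negatively modulated example neurons.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from flexb2b.ephys import (firing_rate, p2p_amplitude,
                           rate_velocity_correlation, spike_snr)

OUT = Path(__file__).resolve().parents[1] / "results"
FS = 30_000.0
DUR = 120.0  # s

if __name__ == "__main__":
    OUT.mkdir(exist_ok=True)
    rng = np.random.default_rng(0)
    # slowly varying locomotion velocity, normalized later
    t_bins = np.arange(0, DUR, 1.0)
    velocity = np.abs(np.convolve(rng.standard_normal(len(t_bins)),
                                  np.ones(10) / 10, mode="same"))

    rows = []
    for unit in range(8):
        gain = (+1 if unit % 2 == 0 else -1) * 15.0  # P / N neurons
        base = 20.0
        lam = np.clip(base + gain * velocity / velocity.max(), 0.5, None)
        spikes = np.concatenate([
            np.sort(b + rng.uniform(0, 1, rng.poisson(l)))
            for b, l in zip(t_bins, lam)])
        _, rate = firing_rate(spikes, 1.0, t_span=(0.0, DUR))
        corr = rate_velocity_correlation(rate, velocity)
        # mean waveform: biphasic spike plus measurement noise
        tw = np.linspace(0, 1.6e-3, 48)
        wf = -80 * np.exp(-((tw - 4e-4) / 1.2e-4) ** 2) \
            + 45 * np.exp(-((tw - 8e-4) / 2.5e-4) ** 2) \
            + rng.normal(0, 2.0, 48)
        noise = rng.normal(0, 5.0, 3000)
        rows.append({
            "unit": unit + 1,
            "modulation": "P" if gain > 0 else "N",
            "n_spikes": len(spikes),
            "p2p_uV": round(p2p_amplitude(wf), 2),
            "snr_k2": round(spike_snr(wf, noise), 2),
            "rate_velocity_r": round(corr, 3),
        })
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "ephys_metrics.csv", index=False)
    print(df.to_string(index=False))
    print("\nP-units correlate positively with velocity, N-units "
          "negatively, mirroring movement-locked firing.")
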