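#!/usr/bin/env python
"""Command-to-stimulation mapping and the biphasic pulse train.

Prints the eight two-mouse commands with their per-mouse stimulation
actions, synthesizes the charge-balanced cathodic-leading train
(200 us / 100 us / 400 us at 100 Hz), and verifies the accelerated-aging
equivalence of the 4-week 60 C soak.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from flexb2b.controller import (StimParams, accelerated_aging_equivalent,
                                class_to_command, make_biphasic_train)

OUT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    OUT.mkdir(exist_ok=True)
    print("command map (mouse1 / mouse2):")
    for i in range(8):
        c = class_to_command(i)
        print(f"  {i}: {c.command}  {c.mouse1:20s} {c.mouse2}")

    params = StimParams(cathodic_amp=5.0)
    train = make_biphasic_train(params)
    q_cat = -train.samples[train.samples < 0].sum() / params.fs_out / 100
    print(f"\nbiphasic train: {train.n_pulses} pulses, "
          f"amplitudes [{train.samples.min():.1f}, "
          f"{train.samples.max():.1f}] uA, "
          f"cathodic charge {q_cat * 1e3:.3f} nC/pulse, "
          f"net charge {train.net_charge():.2e} uC")

    # export one pulse period at full resolution plus the parameter record
    period = int(params.fs_out / params.rate)
    pd.DataFrame({"t_s": train.t[:period],
                  "i_uA": train.samples[:period]}).to_csv(
        OUT / "stim_pulse.csv", index=False)
    with open(OUT / "stim_params.json", "w") as f:
        json.dump({k: getattr(params, k) for k in (
            "cathodic_amp", "anodic_amp", "cathodic_width",
            "interphase_gap", "anodic_width", "rate", "duration",
            "fs_out")}, f, indent=2)

    weeks = accelerated_aging_equivalent(60.0, 37.0, 4.0)
    print(f"accelerated aging: 4 weeks @ 60C = {weeks:.1f} weeks @ 37C")
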