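#!/usr/bin/env python
"""Generate the synthetic SSVEP datasets used by the decoding analysis.

Emulates the single-participant protocol: 1-s, 8-channel occipital trials
at 1000 samples/s, one of eight joint frequency-phase targets per trial,
+10 dB in-band SNR over a pink+white background.  Writes a 640-trial
training set and a 320-trial test set as HDF5.
"""

from pathlib import Path
from dataclasses import replace

import numpy as np

from flexb2b.io import save_trials
from flexb2b.synth import SynthSpec, synth_dataset, target_table

OUT = Path(__file__).resolve().parents[1] / "results"
SPEC = SynthSpec(snr_db=10.0, n_harmonics=3, noise_model="mixture",
                 seed=1000)

if __name__ == "__main__":
    OUT.mkdir(exist_ok=True)
    print("targets:")
    for t in target_table():
        print(f"  {t.index}: {t.frequency:4.0f} Hz  phase {t.phase:5.2f} "
              f"rad  command {t.command}")
    train = synth_dataset(80, SPEC)               # 640 trials
    test = synth_dataset(40, replace(SPEC, seed=2000))  # 320 trials
    save_trials(OUT / "eeg_train.h5", train)
    save_trials(OUT / "eeg_test.h5", test)
    labels = np.array([t.label for t in train])
    print(f"train: {len(train)} trials ({np.bincount(labels)} per class) "
          f"-> {OUT / 'eeg_train.h5'}")
    print(f"test:  {len(test)} trials -> {OUT / 'eeg_test.h5'}")
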