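#!/usr/bin/env python
"""Train the dual-branch decoder on the synthetic SSVEP sets.

Preprocesses (notch + 4-100 Hz band-pass), trains with SGD (batch 32,
lr 0.2, cosine warm restarts) for a reduced 100 epochs, and writes the
training history, held-out confusion matrix, t-SNE layout of the learned
embeddings, and a checkpoint.  Run 01_simulate_eeg.py first.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from flexb2b.decoder import (DecoderConfig, TrainConfig, build_decoder,
                             predict, save_decoder, train_decoder)
from flexb2b.evaluate import confusion, tsne_embed
from flexb2b.io import load_trials
from flexb2b.preprocess import preprocess_trial, to_tensor
from flexb2b.synth import COMMANDS

OUT = Path(__file__).resolve().parents[1] / "results"
EPOCHS = 100
SEED = 0

if __name__ == "__main__":
    x, y = to_tensor([preprocess_trial(t)
                      for t in load_trials(OUT / "eeg_train.h5")])
    xt, yt = to_tensor([preprocess_trial(t)
                        for t in load_trials(OUT / "eeg_test.h5")])
    model = build_decoder(DecoderConfig(), seed=SEED)

    labels0, _ = predict(model, xt)
    print(f"untrained accuracy: {(labels0 == yt).mean():.3f} "
          f"(chance 0.125)")

    hist = train_decoder(model, x, y,
                         TrainConfig(epochs=EPOCHS, seed=SEED),
                         verbose=True)
    hist.to_csv(OUT / "training_history.csv", index=False)

    labels, emb = predict(model, xt)
    acc = (labels == yt).mean()
    cm = confusion(yt, labels, list(COMMANDS))
    cm.to_tsv(OUT / "decoder_confusion.tsv")
    print(f"held-out accuracy: {acc:.4f} on {len(yt)} trials")

    pts = tsne_embed(emb, seed=SEED)
    pd.DataFrame({"x": pts[:, 0], "y": pts[:, 1], "label": yt}).to_csv(
        OUT / "decoder_tsne.csv", index=False)
    save_decoder(model, OUT / "decoder_checkpoint.npz")
    print(f"wrote history, confusion, t-SNE and checkpoint under {OUT}")
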