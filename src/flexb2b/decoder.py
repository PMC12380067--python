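"""Dual-branch time/frequency network for 8-class SSVEP decoding.

The model ingests (batch, 1, channels, time_steps) tensors of 1-s filtered
EEG.  A time-domain branch applies 2-D convolution blocks (conv -> batch
norm -> ReLU -> max pool) followed by a linear layer; a frequency-domain
branch applies the short-time Fourier transform per channel and decodes
the resulting time-frequency maps with residual blocks built from broad
dilated (9, 13) kernels.  The two branch features are concatenated into
the classification embedding and a final fully connected layer emits the
8-class logits.  Training uses plain SGD (batch 32, initial rate 0.2,
cosine annealing with warm restarts) with additive-noise augmentation on
a random half of each batch.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import scipy.fft as sfft
from scipy.signal.windows import hann

from . import nn

__all__ = [
    "DecoderConfig", "TrainConfig", "stft_transform", "build_decoder",
    "DualBranchDecoder", "augment", "train_decoder", "predict",
    "save_decoder", "load_decoder",
]


@dataclass
class DecoderConfig:
    """Architecture hyper-parameters.

    The layer counts are the smallest arrangement containing every named
    component: three conv blocks in the time branch, two residual blocks
    with dilated (9, 13) kernels in the frequency branch.  ``stft_window``
    of 250 samples gives 4 Hz bins (two cycles of the lowest 8 Hz target
    per window) and with ``stft_hop`` 62 a 1-s trial yields 13 frames.
    """

    n_classes: int = 8
    n_channels: int = 8
    n_samples: int = 1000
    fs: float = 1000.0
    # time branch: (out_channels, kernel, pool) per block
    time_blocks: tuple = (
        (8, (1, 25), (1, 4)),
        (8, (8, 11), (1, 4)),
        (16, (1, 11), (1, 4)),
    )
    # frequency branch
    stft_window: int = 250
    stft_hop: int = 62
    stft_fmax: float = 100.0  # keep bins inside the band-pass
    freq_channels: int = 8
    n_res_blocks: int = 2
    dilated_kernel: tuple[int, int] = (9, 13)
    dilation: tuple[int, int] = (2, 2)
    dropout_rate: float = 0.5
    branch_dim: int = 32  # per-branch feature width

    @property
    def embed_dim(self) -> int:
        """Width of the concatenated pre-classifier embedding."""
        return 2 * self.branch_dim

    def validate(self) -> None:
        if self.stft_window > self.n_samples:
            raise ValueError("STFT window longer than the trial")
        if not 0 < self.stft_hop < self.stft_window:
            raise ValueError("STFT hop must be in (0, window)")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")


@dataclass
class TrainConfig:
    """SGD training recipe (defaults follow the decoding protocol)."""

    batch_size: int = 32
    lr0: float = 0.2
    epochs: int = 500
    restart_period: int = 50
    restart_mult: int = 2
    augment_fraction: float = 0.5
    augment_noise_scale: float = 0.1  # x per-batch RMS
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.augment_fraction <= 1:
            raise ValueError("augment fraction must be in [0, 1]")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch size must be positive")


def stft_transform(tensor: np.ndarray,
                   config: DecoderConfig) -> np.ndarray:
    """Per-channel magnitude spectrograms of a trial tensor.

    Input (batch, 1, channels, time_steps); output (batch, channels,
    height, width) where height counts frequency bins up to
    ``config.stft_fmax`` and width = floor((T - window) / hop) + 1 frames.
    Hann-windowed, non-negative.
    """
    config.validate()
    x = np.asarray(tensor)
    if x.ndim != 4 or x.shape[1] != 1:
        raise ValueError("expected a (batch, 1, channels, time) tensor")
    T = x.shape[3]
    w, h = config.stft_window, config.stft_hop
    if w > T:
        raise ValueError("STFT window longer than the signal")
    n_frames = (T - w) // h + 1
    starts = np.arange(n_frames) * h
    # advanced indexing puts the (frames, window) axes first
    frames = x[:, 0, :, starts[:, None] + np.arange(w)[None, :]]
    frames = frames.transpose(2, 3, 0, 1)  # -> (B, C, frames, window)
    taper = hann(w, sym=False).astype(x.dtype)
    spec = np.abs(sfft.rfft(frames * taper, axis=-1))
    freqs = np.arange(spec.shape[-1]) * (config.fs / w)
    keep = int(np.searchsorted(freqs, config.stft_fmax, side="right"))
    spec = spec[:, :, :, :keep]
    # axes currently (B, C, frames, freq): make height=freq, width=frames
    return np.ascontiguousarray(spec.transpose(0, 1, 3, 2))


class DualBranchDecoder:
    """Dual-branch SSVEP decoder with explicit forward/backward passes."""

    def __init__(self, config: DecoderConfig | None = None, seed: int = 0):
        self.config = config or DecoderConfig()
        self.config.validate()
        self.seed = seed
        rng = np.random.default_rng(seed)
        c = self.config

        blocks = []
        ch_in, h, t = 1, c.n_channels, c.n_samples
        for ch_out, kernel, pool in c.time_blocks:
            blocks += [
                nn.Conv2d(ch_in, ch_out, kernel, rng=rng),
                nn.BatchNorm2d(ch_out),
                nn.ReLU(),
                nn.MaxPool2d(pool),
            ]
            h = (h - kernel[0] + 1) // pool[0]
            t = (t - kernel[1] + 1) // pool[1]
            ch_in = ch_out
        blocks += [
            nn.Flatten(),
            nn.Dropout(c.dropout_rate, rng=np.random.default_rng(seed + 1)),
            nn.Linear(ch_in * h * t, c.branch_dim, rng=rng),
            nn.ReLU(),
        ]
        self.time_branch = nn.Sequential(*blocks)

        n_frames = (c.n_samples - c.stft_window) // c.stft_hop + 1
        n_bins = int(np.searchsorted(
            np.arange(c.stft_window // 2 + 1) * (c.fs / c.stft_window),
            c.stft_fmax, side="right"))
        fb = [
            nn.Conv2d(c.n_channels, c.freq_channels, (1, 1), rng=rng),
            nn.BatchNorm2d(c.freq_channels),
            nn.ReLU(),
        ]
        for _ in range(c.n_res_blocks):
            fb.append(nn.Residual(nn.Sequential(
                nn.Conv2d(c.freq_channels, c.freq_channels, c.dilated_kernel,
                          dilation=c.dilation, padding="same", rng=rng),
                nn.BatchNorm2d(c.freq_channels),
                nn.ReLU(),
                nn.Conv2d(c.freq_channels, c.freq_channels, c.dilated_kernel,
                          dilation=c.dilation, padding="same", rng=rng),
                nn.BatchNorm2d(c.freq_channels),
            )))
        fb += [
            nn.Flatten(),
            nn.Dropout(c.dropout_rate, rng=np.random.default_rng(seed + 2)),
            nn.Linear(c.freq_channels * n_bins * n_frames, c.branch_dim,
                      rng=rng),
            nn.ReLU(),
        ]
        self.freq_branch = nn.Sequential(*fb)
        self.head = nn.Linear(c.embed_dim, c.n_classes, rng=rng)

    def params(self) -> list[nn.Param]:
        return (self.time_branch.params() + self.freq_branch.params()
                + self.head.params())

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        spec = np.log1p(stft_transform(x, self.config)).astype(np.float32)
        ft = self.time_branch.forward(x, train)
        ff = self.freq_branch.forward(spec, train)
        self._embed = np.concatenate([ft, ff], axis=1)
        return self.head.forward(self._embed, train)

    def backward(self, dlogits: np.ndarray) -> None:
        d_embed = self.head.backward(dlogits)
        d = self.config.branch_dim
        self.time_branch.backward(d_embed[:, :d])
        self.freq_branch.backward(d_embed[:, d:])


def build_decoder(config: DecoderConfig | None = None,
                  seed: int = 0) -> DualBranchDecoder:
    """Construct an untrained decoder (seed fixes the initialization)."""
    return DualBranchDecoder(config, seed)


def augment(batch: np.ndarray, cfg: TrainConfig,
            rng: np.random.Generator) -> np.ndarray:
    """Add white Gaussian noise to a Bernoulli-selected subset of samples.

    Noise standard deviation is ``augment_noise_scale`` times the batch
    RMS; labels are untouched (augmentation returns features only).
    """
    cfg.validate()
    if len(batch) == 0:
        raise ValueError("empty batch")
    mask = rng.random(len(batch)) < cfg.augment_fraction
    if cfg.augment_noise_scale == 0 or not mask.any():
        return batch
    rms = float(np.sqrt(np.mean(batch.astype(np.float64) ** 2)))
    out = batch.copy()
    noise = rng.standard_normal(
        (int(mask.sum()),) + batch.shape[1:]).astype(batch.dtype)
    out[mask] += (cfg.augment_noise_scale * rms) * noise
    return out


def train_decoder(model: DualBranchDecoder, x: np.ndarray, y: np.ndarray,
                  cfg: TrainConfig | None = None,
                  x_val: np.ndarray | None = None,
                  y_val: np.ndarray | None = None,
                  verbose: bool = False):
    """Train in place; returns a per-epoch history DataFrame.

    Data order is re-shuffled every epoch from the training seed; the
    learning-rate trace follows cosine annealing with warm restarts from
    ``lr0``.  A non-finite loss aborts with the offending epoch.
    """
    cfg = cfg or TrainConfig()
    cfg.validate()
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.int64)
    if len(x) == 0:
        raise ValueError("empty training set")
    if len(x) != len(y):
        raise ValueError("feature/label length mismatch")
    rng = np.random.default_rng(cfg.seed)
    opt = nn.SGD(model.params(), cfg.lr0)
    rows = []
    for epoch in range(cfg.epochs):
        lr = nn.cosine_warm_restarts(epoch, cfg.lr0, cfg.restart_period,
                                     cfg.restart_mult)
        opt.lr = lr
        order = rng.permutation(len(x))
        losses, correct = [], 0
        for i in range(0, len(x), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            xb = augment(x[idx], cfg, rng)
            logits = model.forward(xb, train=True)
            loss, dlogits = nn.cross_entropy(logits, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch} (loss={loss})")
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
        row = {"epoch": epoch, "lr": lr,
               "loss": float(np.mean(losses)),
               "train_acc": correct / len(x)}
        if x_val is not None:
            labels, _ = predict(model, x_val)
            row["val_acc"] = float((labels == y_val).mean())
        rows.append(row)
        if verbose and (epoch % 10 == 0 or epoch == cfg.epochs - 1):
            print(f"epoch {epoch:4d} lr {lr:.4f} loss {row['loss']:.4f} "
                  f"acc {row['train_acc']:.3f}"
                  + (f" val {row.get('val_acc', float('nan')):.3f}"
                     if x_val is not None else ""))
    return pd.DataFrame(rows)


def predict(model: DualBranchDecoder, x: np.ndarray,
            batch_size: int = 64):
    """Evaluation-mode argmax labels and pre-classifier embeddings.

    Deterministic: dropout is disabled and batch norm uses running
    statistics, so repeated calls are bit-identical.
    """
    x = np.asarray(x, dtype=np.float32)
    labels, embeds = [], []
    for i in range(0, len(x), batch_size):
        logits = model.forward(x[i:i + batch_size], train=False)
        labels.append(logits.argmax(axis=1))
        embeds.append(model._embed)
    return np.concatenate(labels), np.concatenate(embeds)


def save_decoder(model: DualBranchDecoder, path) -> None:
    """Single-file checkpoint: parameters, BN statistics, config JSON."""
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.params())}
    bn = [l for branch in (model.time_branch, model.freq_branch)
          for l in _iter_layers(branch) if isinstance(l, nn.BatchNorm2d)]
    for i, l in enumerate(bn):
        arrays[f"bn_mean_{i}"] = l.running_mean
        arrays[f"bn_var_{i}"] = l.running_var
    cfg = asdict(model.config)
    arrays["config_json"] = np.frombuffer(
        json.dumps({"config": cfg, "seed": model.seed}).encode(),
        dtype=np.uint8)
    np.savez(path, **arrays)


def load_decoder(path) -> DualBranchDecoder:
    with np.load(path) as data:
        meta = json.loads(bytes(data["config_json"]).decode())
        cfg = DecoderConfig(**{
            k: tuple(map(tuple, v)) if k == "time_blocks" else
            (tuple(v) if isinstance(v, list) else v)
            for k, v in meta["config"].items()})
        model = DualBranchDecoder(cfg, seed=meta["seed"])
        for i, p in enumerate(model.params()):
            p.value = data[f"param_{i}"].copy()
            p.grad = np.zeros_like(p.value)
        bn = [l for branch in (model.time_branch, model.freq_branch)
              for l in _iter_layers(branch) if isinstance(l, nn.BatchNorm2d)]
        for i, l in enumerate(bn):
            l.running_mean = data[f"bn_mean_{i}"].copy()
            l.running_var = data[f"bn_var_{i}"].copy()
    return model


def _iter_layers(layer):
    yield layer
    if isinstance(layer, nn.Sequential):
        for sub in layer.layers:
            yield from _iter_layers(sub)
    elif isinstance(layer, nn.Residual):
        yield from _iter_layers(layer.inner)
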