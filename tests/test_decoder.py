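"""Decoder: STFT maps, architecture contracts, augmentation, training."""

import numpy as np
import pytest

from flexb2b.decoder import (
    DecoderConfig,
    TrainConfig,
    augment,
    build_decoder,
    load_decoder,
    predict,
    save_decoder,
    stft_transform,
    train_decoder,
)
from flexb2b.nn import softmax


def tone_tensor(freq, n=1000, fs=1000.0, n_ch=8, batch=1):
    t = np.arange(n) / fs
    x = np.tile(np.sin(2 * np.pi * freq * t), (batch, 1, n_ch, 1))
    return x.astype(np.float32)


class TestSTFT:
    def test_tone_localized_every_frame(self):
        cfg = DecoderConfig(stft_window=250, stft_hop=125)
        m = stft_transform(tone_tensor(12.0), cfg)
        assert m.shape == (1, 8, 26, 7)  # 4 Hz bins to 100 Hz, 7 frames
        peak_bins = m[0, 0].argmax(axis=0)
        assert (peak_bins == 3).all()  # 12 Hz / 4 Hz per bin

    def test_frame_count_formula(self):
        cfg = DecoderConfig()
        m = stft_transform(np.zeros((2, 1, 8, 1000), np.float32), cfg)
        assert m.shape[-1] == (1000 - 250) // 62 + 1
        np.testing.assert_array_equal(m, 0.0)

    def test_chirp_argmax_nondecreasing(self):
        from scipy.signal import chirp
        t = np.arange(1000) / 1000.0
        x = chirp(t, f0=8, f1=15, t1=1.0)[None, None, None, :]
        x = np.tile(x, (1, 1, 8, 1)).astype(np.float32)
        cfg = DecoderConfig(stft_window=250, stft_hop=125)
        m = stft_transform(x, cfg)
        peaks = m[0, 0].argmax(axis=0)
        assert (np.diff(peaks) >= 0).all()

    def test_window_longer_than_signal_rejected(self):
        cfg = DecoderConfig(stft_window=2000)
        with pytest.raises(ValueError):
            stft_transform(np.zeros((1, 1, 8, 1000), np.float32), cfg)

    def test_nonnegative(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 1, 8, 1000)).astype(np.float32)
        assert (stft_transform(x, DecoderConfig()) >= 0).all()


class TestArchitecture:
    def test_forward_shape_and_softmax(self, tiny_config):
        m = build_decoder(tiny_config, seed=0)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((4, 1, 8, 1000)).astype(np.float32)
        logits = m.forward(x, train=False)
        assert logits.shape == (4, 8)
        np.testing.assert_allclose(softmax(logits).sum(axis=1), 1.0,
                                   atol=1e-6)

    def test_untrained_accuracy_near_chance(self, small_dataset,
                                            tiny_config):
        x, y = small_dataset
        m = build_decoder(tiny_config, seed=1)
        labels, _ = predict(m, x)
        acc = (labels == y).mean()
        assert 0.0 <= acc <= 0.45  # 48 trials; chance 0.125

    def test_predict_returns_embeddings(self, small_dataset, tiny_config):
        x, y = small_dataset
        m = build_decoder(tiny_config, seed=0)
        labels, emb = predict(m, x[:5])
        assert labels.shape == (5,)
        assert emb.shape == (5, tiny_config.embed_dim)
        assert set(labels) <= set(range(8))

    def test_predict_deterministic(self, small_dataset, tiny_config):
        x, _ = small_dataset
        m = build_decoder(tiny_config, seed=0)
        a, ea = predict(m, x[:8])
        b, eb = predict(m, x[:8])
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(ea, eb)


class TestAugment:
    def test_identity_cases(self):
        rng = np.random.default_rng(0)
        batch = rng.standard_normal((16, 1, 8, 100)).astype(np.float32)
        out = augment(batch, TrainConfig(augment_fraction=0.0), rng)
        np.testing.assert_array_equal(out, batch)
        out = augment(batch, TrainConfig(augment_fraction=1.0,
                                         augment_noise_scale=0.0), rng)
        np.testing.assert_array_equal(out, batch)

    def test_selection_fraction_concentrates(self):
        rng = np.random.default_rng(0)
        batch = np.ones((10000, 1, 1, 4), np.float32)
        out = augment(batch, TrainConfig(augment_fraction=0.5), rng)
        frac = (np.abs(out - batch).max(axis=(1, 2, 3)) > 0).mean()
        assert 0.48 <= frac <= 0.52

    def test_labels_not_part_of_contract(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            augment(np.zeros((0, 1, 8, 10), np.float32), TrainConfig(), rng)


class TestTraining:
    def test_learns_separable_data(self, small_dataset, tiny_config):
        x, y = small_dataset
        m = build_decoder(tiny_config, seed=0)
        cfg = TrainConfig(epochs=30, seed=0, restart_period=30)
        hist = train_decoder(m, x, y, cfg)
        assert hist.lr.iloc[0] == pytest.approx(0.2)
        assert len(hist) == 30
        labels, _ = predict(m, x)
        assert (labels == y).mean() >= 0.9  # training-set fit

    def test_seeded_runs_identical(self, small_dataset, tiny_config):
        x, y = small_dataset
        losses = []
        for _ in range(2):
            m = build_decoder(tiny_config, seed=3)
            hist = train_decoder(m, x[:16], y[:16],
                                 TrainConfig(epochs=3, seed=3))
            losses.append(hist.loss.iloc[-1])
        assert losses[0] == pytest.approx(losses[1], abs=1e-9)

    def test_empty_dataset_rejected(self, tiny_config):
        m = build_decoder(tiny_config, seed=0)
        with pytest.raises(ValueError):
            train_decoder(m, np.zeros((0, 1, 8, 1000), np.float32),
                          np.zeros(0, np.int64), TrainConfig(epochs=1))

    def test_checkpoint_roundtrip(self, small_dataset, tiny_config,
                                  tmp_path):
        x, y = small_dataset
        m = build_decoder(tiny_config, seed=0)
        train_decoder(m, x[:16], y[:16], TrainConfig(epochs=2, seed=0))
        path = tmp_path / "ckpt.npz"
        save_decoder(m, path)
        m2 = load_decoder(path)
        a, ea = predict(m, x[:8])
        b, eb = predict(m2, x[:8])
        np.testing.assert_array_equal(a, b)
        np.testing.assert_allclose(ea, eb, atol=1e-6)
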