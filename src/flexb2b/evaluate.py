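"""Decoder and end-to-end scoring: confusion matrices, sweeps, t-SNE."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.manifold import TSNE

__all__ = ["ConfusionMatrix", "confusion", "SweepResult", "sweep",
           "tsne_embed"]


@dataclass
class ConfusionMatrix:
    """Count matrix with rows = true classes, columns = predicted."""

    counts: np.ndarray
    class_names: list[str]
    pred_names: list[str] | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.pred_names is None:
            self.pred_names = list(self.class_names)
        if self.counts.shape != (len(self.class_names),
                                 len(self.pred_names)):
            raise ValueError("count matrix shape does not match class names")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def accuracy(self) -> float:
        """Fraction of trials whose prediction matches the true class."""
        matched = sum(
            self.counts[i, self.pred_names.index(name)]
            for i, name in enumerate(self.class_names)
            if name in self.pred_names
        )
        return matched / self.total if self.total else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_names,
                            columns=self.pred_names)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def confusion(true_labels, pred_labels, class_names) -> ConfusionMatrix:
    """Build a KxK confusion matrix from integer or string labels."""
    true_labels = list(true_labels)
    pred_labels = list(pred_labels)
    if len(true_labels) != len(pred_labels):
        raise ValueError("label lists must have equal length")
    names = list(class_names)
    k = len(names)

    def to_idx(lab):
        if isinstance(lab, str):
            if lab not in names:
                raise ValueError(f"label {lab!r} outside class set")
            return names.index(lab)
        lab = int(lab)
        if not 0 <= lab < k:
            raise ValueError(f"label {lab} outside class set")
        return lab

    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        counts[to_idx(t), to_idx(p)] += 1
    return ConfusionMatrix(counts, names)


@dataclass
class SweepResult:
    """Accuracy as a function of one swept parameter."""

    parameter: str
    grid: list
    mean_accuracy: list[float]
    std_accuracy: list[float]
    n_seeds: int
    failures: list = field(default_factory=list)

    @property
    def single_seed(self) -> bool:
        """Single-seed sweeps carry no dispersion and are flagged."""
        return self.n_seeds == 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.parameter: self.grid,
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
        })


def sweep(train_eval_fn, parameter: str, grid, n_seeds: int = 3,
          base_seed: int = 0) -> SweepResult:
    """Re-train and evaluate at each grid value, averaged over seeds.

    ``train_eval_fn(value, seed) -> accuracy`` regenerates or re-slices
    its data and trains from scratch (no warm starting).  Failed runs are
    recorded in ``failures`` rather than silently dropped.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty grid")
    means, stds, failures = [], [], []
    for value in grid:
        accs = []
        for s in range(n_seeds):
            try:
                accs.append(float(train_eval_fn(value, base_seed + s)))
            except Exception as exc:  # noqa: BLE001 - recorded, not dropped
                failures.append((value, base_seed + s, repr(exc)))
        means.append(float(np.mean(accs)) if accs else float("nan"))
        stds.append(float(np.std(accs)) if accs else float("nan"))
    return SweepResult(parameter, grid, means, stds, n_seeds, failures)


def tsne_embed(embeddings: np.ndarray, seed: int = 0,
               perplexity: float = 30.0) -> np.ndarray:
    """2-D t-SNE layout of decoder feature vectors; deterministic per seed."""
    x = np.asarray(embeddings, dtype=np.float64)
    if x.ndim != 2 or len(x) < 2:
        raise ValueError("need a 2-D array with at least two embeddings")
    perplexity = min(perplexity, (len(x) - 1) / 3)
    if perplexity < 1:
        raise ValueError(
            f"only {len(x)} points; t-SNE needs at least 4 (or lower the "
            "perplexity)")
    return TSNE(n_components=2, perplexity=perplexity, init="pca",
                random_state=seed).fit_transform(x)
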