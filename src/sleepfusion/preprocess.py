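"""Normalization and dataset splitting.

Channels of a PSG recording live on very different physical scales (tens of
microvolts of EEG vs. millivolt-scale EMG tone), so each channel is rescaled
to [0, 1] by min-max normalization, x_N = (x - x_min)/(x_max - x_min), with
the extrema fitted on the training partition only and applied unchanged to
the test partition. The dataset is split 85%/15% train/test, stratified per
stage so each class keeps the same ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .psg_io import EpochSet

__all__ = [
    "NormalizationParams",
    "SplitConfig",
    "DatasetSplit",
    "fit_minmax",
    "apply_minmax",
    "normalize_epochset",
    "split_dataset",
    "class_counts",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NormalizationParams:
    """Per-channel min-max extrema, fitted on the training partition only."""

    channel: str
    xmin: float
    xmax: float

    @property
    def degenerate(self) -> bool:
        """True when the channel is constant (xmax == xmin)."""
        return self.xmax == self.xmin


@dataclass(frozen=True)
class SplitConfig:
    """Train/test split proportions and reproducibility seed."""

    train_fraction: float = 0.85
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError(f"train_fraction must be in (0,1), got {self.train_fraction}")


@dataclass
class DatasetSplit:
    train: EpochSet
    test: EpochSet
    train_indices: np.ndarray
    test_indices: np.ndarray

    def write_manifest(self, path) -> "Path":
        """CSV manifest of the split: epoch index, partition, stage label."""
        import pandas as pd
        from pathlib import Path

        rows = [
            {"epoch_index": int(i), "partition": "train", "label": int(l)}
            for i, l in zip(self.train_indices, self.train.labels)
        ] + [
            {"epoch_index": int(i), "partition": "test", "label": int(l)}
            for i, l in zip(self.test_indices, self.test.labels)
        ]
        frame = pd.DataFrame(rows).sort_values("epoch_index")
        path = Path(path)
        frame.to_csv(path, index=False)
        return path


def fit_minmax(train: EpochSet, channel: str) -> NormalizationParams:
    """Global extrema of one channel over every training epoch and sample."""
    if train.n_epochs == 0:
        raise ValueError("cannot fit normalization on an empty epoch set")
    values = train.signals[:, :, train.channel_index(channel)]
    params = NormalizationParams(channel, float(values.min()), float(values.max()))
    if params.degenerate:
        logger.warning(
            "channel %r is constant (value %g); normalization is degenerate",
            channel,
            params.xmin,
        )
    return params


def apply_minmax(values: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Apply (x - xmin)/(xmax - xmin); no clipping of out-of-range inputs.

    Test-set values outside the fitted training range legitimately map
    outside [0, 1]. A degenerate (constant-channel) fit maps everything to 0
    with a logged warning.
    """
    values = np.asarray(values, dtype=np.float64)
    if params.degenerate:
        logger.warning(
            "degenerate normalization for channel %r: mapping all values to 0",
            params.channel,
        )
        return np.zeros_like(values)
    return (values - params.xmin) / (params.xmax - params.xmin)


def normalize_epochset(
    epochs: EpochSet, params: dict[str, NormalizationParams]
) -> EpochSet:
    """Apply fitted per-channel parameters to every channel of an epoch set."""
    out = epochs.signals.copy()
    for name in epochs.channel_names:
        j = epochs.channel_index(name)
        out[:, :, j] = apply_minmax(out[:, :, j], params[name])
    return EpochSet(
        out, epochs.labels.copy(), list(epochs.channel_names), epochs.epoch_len_s, epochs.sampling_rate
    )


def split_dataset(epochs: EpochSet, config: SplitConfig = SplitConfig()) -> DatasetSplit:
    """Seeded train/test split of epochs; stratified per stage by default.

    Stratified mode draws ``round(train_fraction * n_c)`` training epochs from
    each class c, so a 100-per-class set at the default fraction yields
    exactly 85 training epochs per class. Non-stratified mode rounds on the
    full set. Raises if a class is empty under stratification.
    """
    rng = np.random.default_rng(config.seed)
    n = epochs.n_epochs
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    if config.stratified:
        classes = np.unique(epochs.labels)
        if len(classes) == 0:
            raise ValueError("cannot split an empty epoch set")
        for c in range(5):
            members = np.flatnonzero(epochs.labels == c)
            if len(members) == 0:
                raise ValueError(
                    f"stratified split requires every class present; class {c} is empty"
                )
            perm = rng.permutation(members)
            k = int(round(config.train_fraction * len(members)))
            train_idx.append(perm[:k])
            test_idx.append(perm[k:])
    else:
        perm = rng.permutation(n)
        k = int(round(config.train_fraction * n))
        train_idx.append(perm[:k])
        test_idx.append(perm[k:])
    train_indices = np.sort(np.concatenate(train_idx))
    test_indices = np.sort(np.concatenate(test_idx))
    return DatasetSplit(
        train=epochs.subset(train_indices),
        test=epochs.subset(test_indices),
        train_indices=train_indices,
        test_indices=test_indices,
    )


def class_counts(epochs: EpochSet) -> dict[int, int]:
    """Number of epochs per stage code 0..4; values sum to n_epochs."""
    return {c: int(np.sum(epochs.labels == c)) for c in range(5)}
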