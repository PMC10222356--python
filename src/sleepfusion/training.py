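"""Two-stage training: pre-train dual-channel modules, freeze, fuse, retrain.

Stage one trains each dual-channel module for a fixed number of epochs
(default 80) with Adam (learning rate 0.001), categorical cross-entropy, and
mini-batches of 256, no early stopping — the final-epoch parameters are the
product. Stage two freezes both pre-trained backbones, concatenates their
flatten-level features, and retrains only the fresh five-way fusion head for
a further 40 epochs, completing the 120-epoch schedule. The validation curve
is computed on the held-out test partition after every epoch, mirroring the
common "test accuracy as validation accuracy" practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._nn import Adam, softmax_cross_entropy
from .network import DualModule, FusionModel
from .psg_io import EpochSet

__all__ = [
    "TrainConfig",
    "TrainingHistory",
    "pretrain_dual",
    "freeze",
    "unfreeze",
    "train_fusion",
    "predict",
    "predict_fusion",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyper-parameters for both training stages."""

    optimizer: str = "adam"
    learning_rate: float = 0.001
    batch_size: int = 256
    loss: str = "categorical_crossentropy"
    pretrain_epochs: int = 80
    fusion_epochs: int = 40
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if self.pretrain_epochs < 0 or self.fusion_epochs < 0:
            raise ValueError("epoch counts must be non-negative")
        if self.optimizer.lower() != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss != "categorical_crossentropy":
            raise ValueError(f"unsupported loss {self.loss!r}")


@dataclass
class TrainingHistory:
    """Per-epoch training loss and validation accuracy."""

    loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.loss)

    def to_rows(self) -> list[dict]:
        return [
            {"epoch": e + 1, "loss": l, "val_accuracy": a}
            for e, (l, a) in enumerate(zip(self.loss, self.val_accuracy))
        ]


def _one_hot(labels: np.ndarray, n_classes: int = 5) -> np.ndarray:
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


def _batches(n: int, batch_size: int, rng: np.random.Generator, shuffle: bool):
    order = rng.permutation(n) if shuffle else np.arange(n)
    for start in range(0, n, batch_size):  # last short batch kept
        yield order[start : start + batch_size]


def _epoch_pair(epochs: EpochSet, pair: tuple[str, str]) -> np.ndarray:
    idx = [epochs.channel_index(name) for name in pair]
    return epochs.signals[:, :, idx]


def pretrain_dual(
    module: DualModule,
    train: EpochSet,
    validation: EpochSet,
    config: TrainConfig = TrainConfig(),
) -> tuple[DualModule, TrainingHistory]:
    """Stage one: train a dual-channel module for exactly pretrain_epochs.

    ``train``/``validation`` must contain the module's two channels (extra
    channels are ignored). History records mean mini-batch loss and
    validation accuracy after each epoch; no early stopping is applied and
    the final-epoch parameters are returned in place.
    """
    if train.n_epochs == 0:
        raise ValueError("empty training set")
    pair = module.spec.channel_pair
    x_train = _epoch_pair(train, pair)  # raises on channel mismatch
    for name in pair:  # fail fast on validation channel mismatch too
        validation.channel_index(name)
    y_train = _one_hot(train.labels, module.spec.n_classes)
    rng = np.random.default_rng(config.seed)
    opt = Adam(module.parameters(), learning_rate=config.learning_rate)
    history = TrainingHistory()
    for epoch in range(config.pretrain_epochs):
        losses = []
        for batch in _batches(train.n_epochs, config.batch_size, rng, config.shuffle):
            opt.zero_grad()
            loss = softmax_cross_entropy(
                module.logits(x_train[batch], inference=False), y_train[batch]
            )
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        preds = predict(module, validation)
        acc = float(np.mean(preds == validation.labels))
        history.loss.append(float(np.mean(losses)))
        history.val_accuracy.append(acc)
        logger.info(
            "pretrain %s epoch %d/%d loss %.4f val_acc %.4f",
            "+".join(pair), epoch + 1, config.pretrain_epochs, history.loss[-1], acc,
        )
    return module, history


def freeze(module: DualModule) -> DualModule:
    """Exclude every parameter of a pre-trained module from further updates."""
    module.freeze()
    return module


def unfreeze(module: DualModule) -> DualModule:
    module.unfreeze()
    return module


def train_fusion(
    fused: FusionModel,
    train: EpochSet,
    validation: EpochSet,
    config: TrainConfig = TrainConfig(),
) -> tuple[FusionModel, TrainingHistory]:
    """Stage two: retrain the fusion head for exactly fusion_epochs.

    Only unfrozen parameters (the head, under the default freezing contract)
    receive updates; a warning is logged if backbone parameters are still
    trainable. The epoch sets must contain all channels both modules consume.
    """
    if train.n_epochs == 0:
        raise ValueError("empty training set")
    backbone_trainable = any(
        p.trainable
        for m in (fused.module_I, fused.module_II)
        for p in m.parameters()
    )
    if backbone_trainable:
        logger.warning(
            "fusion backbones are not frozen; pre-trained parameters will change"
        )
    x_I = _epoch_pair(train, fused.module_I.spec.channel_pair)
    x_II = _epoch_pair(train, fused.module_II.spec.channel_pair)
    y_train = _one_hot(train.labels, fused.module_I.spec.n_classes)
    rng = np.random.default_rng(config.seed)
    opt = Adam(fused.parameters(), learning_rate=config.learning_rate)
    history = TrainingHistory()
    frozen = not backbone_trainable
    if frozen:
        # frozen backbones are a fixed transform: extract features once
        feats_train = fused.extract_features(x_I, x_II)
        feats_val = fused.extract_features(
            _epoch_pair(validation, fused.module_I.spec.channel_pair),
            _epoch_pair(validation, fused.module_II.spec.channel_pair),
        )
    for epoch in range(config.fusion_epochs):
        losses = []
        for batch in _batches(train.n_epochs, config.batch_size, rng, config.shuffle):
            opt.zero_grad()
            if frozen:
                logits = fused.head_logits(feats_train[batch])
            else:
                logits = fused.logits(x_I[batch], x_II[batch], inference=False)
            loss = softmax_cross_entropy(logits, y_train[batch])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        if frozen:
            from ._nn import no_grad, softmax

            with no_grad():
                preds = np.argmax(softmax(fused.head_logits(feats_val).data), axis=1)
        else:
            preds = predict_fusion(fused, validation)
        acc = float(np.mean(preds == validation.labels))
        history.loss.append(float(np.mean(losses)))
        history.val_accuracy.append(acc)
        logger.info(
            "fusion epoch %d/%d loss %.4f val_acc %.4f",
            epoch + 1, config.fusion_epochs, history.loss[-1], acc,
        )
    return fused, history


def _argmax_lowest(proba: np.ndarray) -> np.ndarray:
    # np.argmax already breaks ties toward the lowest index
    return np.argmax(proba, axis=1)


def predict(model: DualModule, epochs: EpochSet, batch_size: int = 64) -> np.ndarray:
    """Predicted stage codes (argmax, ties toward the lowest class code)."""
    x = _epoch_pair(epochs, model.spec.channel_pair)
    out = np.empty(epochs.n_epochs, dtype=np.int64)
    for start in range(0, epochs.n_epochs, batch_size):
        proba = model.predict_proba(x[start : start + batch_size], inference=True)
        out[start : start + batch_size] = _argmax_lowest(proba)
    return out


def predict_fusion(
    model: FusionModel, epochs: EpochSet, batch_size: int = 64
) -> np.ndarray:
    """Predicted stage codes from the fused four-channel model."""
    x_I = _epoch_pair(epochs, model.module_I.spec.channel_pair)
    x_II = _epoch_pair(epochs, model.module_II.spec.channel_pair)
    out = np.empty(epochs.n_epochs, dtype=np.int64)
    for start in range(0, epochs.n_epochs, batch_size):
        proba = model.predict_proba(
            x_I[start : start + batch_size],
            x_II[start : start + batch_size],
            inference=True,
        )
        out[start : start + batch_size] = _argmax_lowest(proba)
    return out
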