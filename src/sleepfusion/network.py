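"""The dual-channel convolutional Bi-LSTM module and the four-channel fusion model.

Architecture
------------
Each of the two input channels feeds its own ladder of four Conv Blocks (two
same-padded 1-D convolutions with rectifier activations, a temporal max pool
of size 2, dropout 0.2) with filter counts 32/64/128/256. In parallel, four
Bi-LSTM Blocks (bidirectional LSTM, max pool 2, dropout 0.2) with unit counts
16/32/64/128 extract temporal structure; at every level k the Bi-LSTM input
is the feature-axis concatenation of both channels' level-k conv features
with the pooled level-(k-1) Bi-LSTM output. Both ladders halve the time axis
per level, so lengths stay aligned by construction: conv
3000->1500->750->375->187 and coupled Bi-LSTM outputs 750->375->187->93. The
head flattens the last Bi-LSTM block and maps to the five stage
probabilities. 2u_k = m_k at every level, which is what lets conv and
Bi-LSTM features concatenate into the next level cleanly.

A four-channel fusion model concatenates the flatten-level feature vectors of
two pre-trained dual-channel modules (their backbones frozen) and retrains
only a fresh five-way dense head — transfer learning applied sideways rather
than across datasets.

The LSTM cell follows the standard gate recurrence: with z_t = [h_{t-1}, x_t],
f_t = sigma(w_f z_t + b_f), i_t = sigma(w_i z_t + b_i),
o_t = sigma(w_o z_t + b_o), c_t = f_t*c_{t-1} + i_t*tanh(w_c z_t + b_c),
h_t = o_t*tanh(c_t); the bidirectional output per step is the concatenation
of the forward and backward hidden states (merge activation = identity).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import _nn
from ._nn import (
    BiLSTM,
    Conv1D,
    Dense,
    Module,
    Tensor,
    concat,
    dropout,
    flatten,
    max_pool1d,
    no_grad,
    relu,
    softmax,
)

__all__ = [
    "FeatureMap",
    "ConvBlockSpec",
    "BiLSTMBlockSpec",
    "LSTMCellParams",
    "BiLSTMOutput",
    "DualModuleSpec",
    "FusionModelSpec",
    "DEFAULT_FILTERS",
    "DEFAULT_UNITS",
    "lstm_step",
    "bilstm_sequence",
    "ConvBlock",
    "BiLSTMBlock",
    "conv_block_forward",
    "bilstm_block_forward",
    "DualModule",
    "build_dual_module",
    "dual_forward",
    "FusionModel",
    "build_fusion",
    "count_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

DEFAULT_FILTERS = (32, 64, 128, 256)
DEFAULT_UNITS = (16, 32, 64, 128)

_EEG_PREFIX = "EEG"


@dataclass
class FeatureMap:
    """A (length, width) array of per-time-step features."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"FeatureMap must be 2-D, got shape {self.values.shape}")
        if self.length < 1 or self.width < 1:
            raise ValueError(f"degenerate FeatureMap shape {self.values.shape}")

    @property
    def length(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ConvBlockSpec:
    """Two same-padded 1-D convolutions + max pool 2 + dropout 0.2."""

    filters: int
    kernel_size: int = 5
    pool_size: int = 2
    dropout_rate: float = 0.2


@dataclass(frozen=True)
class BiLSTMBlockSpec:
    """Bidirectional LSTM + max pool 2 + dropout 0.2; output width 2*units."""

    units: int
    pool_size: int = 2
    dropout_rate: float = 0.2


@dataclass
class LSTMCellParams:
    """Explicit gate weights of one LSTM cell, acting on [h_{t-1}, x_t].

    Each matrix has shape (units, units + input_width); sigma is the logistic
    function and the elementwise product combines gate and state vectors.
    """

    w_f: np.ndarray
    w_i: np.ndarray
    w_o: np.ndarray
    w_c: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray

    def __post_init__(self) -> None:
        shapes = {m.shape for m in (self.w_f, self.w_i, self.w_o, self.w_c)}
        if len(shapes) != 1:
            raise ValueError(f"gate weight matrices differ in shape: {shapes}")
        units = self.w_f.shape[0]
        for b in (self.b_f, self.b_i, self.b_o, self.b_c):
            if b.shape != (units,):
                raise ValueError(f"bias shape {b.shape} != ({units},)")

    @property
    def units(self) -> int:
        return self.w_f.shape[0]

    @property
    def input_width(self) -> int:
        return self.w_f.shape[1] - self.units

    @classmethod
    def zeros(cls, units: int, input_width: int) -> "LSTMCellParams":
        w = lambda: np.zeros((units, units + input_width))
        b = lambda: np.zeros(units)
        return cls(w(), w(), w(), w(), b(), b(), b(), b())

    @classmethod
    def random(
        cls, units: int, input_width: int, rng: np.random.Generator, scale: float = 0.5
    ) -> "LSTMCellParams":
        w = lambda: rng.uniform(-scale, scale, (units, units + input_width))
        b = lambda: rng.uniform(-scale, scale, units)
        return cls(w(), w(), w(), w(), b(), b(), b(), b())


@dataclass
class BiLSTMOutput:
    """Per-step forward states, backward states, and their concatenation."""

    forward: FeatureMap
    backward: FeatureMap
    combined: FeatureMap


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def lstm_step(
    params: LSTMCellParams,
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update (h_t, c_t) from the gate recurrence.

    f_t, i_t, o_t are logistic gates of w.[h_prev, x_t] + b; the cell state
    blends the previous state (forget gate) with the tanh candidate (input
    gate); the hidden state is the output gate times tanh(c_t). Every gate
    value lies in (0, 1) and every component of h_t in (-1, 1).
    """
    x_t = np.asarray(x_t, dtype=np.float64)
    h_prev = np.asarray(h_prev, dtype=np.float64)
    c_prev = np.asarray(c_prev, dtype=np.float64)
    if x_t.shape != (params.input_width,) or h_prev.shape != (params.units,):
        raise ValueError(
            f"dimension mismatch: x_t {x_t.shape} (want ({params.input_width},)), "
            f"h_prev {h_prev.shape} (want ({params.units},))"
        )
    z = np.concatenate([h_prev, x_t])
    f = _sigmoid(params.w_f @ z + params.b_f)
    i = _sigmoid(params.w_i @ z + params.b_i)
    o = _sigmoid(params.w_o @ z + params.b_o)
    c_t = f * c_prev + i * np.tanh(params.w_c @ z + params.b_c)
    h_t = o * np.tanh(c_t)
    return h_t, c_t


def bilstm_sequence(
    fwd: LSTMCellParams, bwd: LSTMCellParams, sequence: FeatureMap
) -> BiLSTMOutput:
    """Run a bidirectional LSTM over a full sequence from zero initial state.

    The backward stream is the forward recurrence applied to the
    time-reversed input with its outputs re-reversed; the combined output
    concatenates both streams per step (identity merge), width 2*units.
    """
    if sequence.length < 1:
        raise ValueError("empty sequence")

    def run(params: LSTMCellParams, xs: np.ndarray) -> np.ndarray:
        h = np.zeros(params.units)
        c = np.zeros(params.units)
        out = np.empty((len(xs), params.units))
        for t, x_t in enumerate(xs):
            h, c = lstm_step(params, x_t, h, c)
            out[t] = h
        return out

    h_fwd = run(fwd, sequence.values)
    h_bwd = run(bwd, sequence.values[::-1])[::-1]
    return BiLSTMOutput(
        forward=FeatureMap(h_fwd),
        backward=FeatureMap(h_bwd),
        combined=FeatureMap(np.concatenate([h_fwd, h_bwd], axis=1)),
    )


# =============================================================================
# Blocks
# =============================================================================


class ConvBlock(Module):
    def __init__(self, spec: ConvBlockSpec, in_width: int, rng: np.random.Generator):
        self.spec = spec
        self.conv1 = Conv1D(in_width, spec.filters, spec.kernel_size, rng)
        self.conv2 = Conv1D(spec.filters, spec.filters, spec.kernel_size, rng)

    def __call__(self, x: Tensor, rng: np.random.Generator, inference: bool) -> Tensor:
        if x.data.shape[1] < self.spec.pool_size:
            raise ValueError(
                f"sequence length {x.data.shape[1]} < pool size {self.spec.pool_size}"
            )
        y = relu(self.conv1(x))
        y = relu(self.conv2(y))
        y = max_pool1d(y, self.spec.pool_size)
        return dropout(y, self.spec.dropout_rate, rng, inference)


class BiLSTMBlock(Module):
    def __init__(self, spec: BiLSTMBlockSpec, in_width: int, rng: np.random.Generator):
        self.spec = spec
        self.bilstm = BiLSTM(in_width, spec.units, rng)

    def __call__(self, x: Tensor, rng: np.random.Generator, inference: bool) -> Tensor:
        if x.data.shape[1] < self.spec.pool_size:
            raise ValueError(
                f"sequence length {x.data.shape[1]} < pool size {self.spec.pool_size}"
            )
        y = self.bilstm(x)
        y = max_pool1d(y, self.spec.pool_size)
        return dropout(y, self.spec.dropout_rate, rng, inference)


def conv_block_forward(
    block: ConvBlock, x: FeatureMap, inference: bool = True, rng=None
) -> FeatureMap:
    """Apply one Conv Block to a single (length, width) feature map."""
    rng = rng or np.random.default_rng(0)
    out = block(Tensor(x.values[None]), rng, inference)
    return FeatureMap(out.data[0])


def bilstm_block_forward(
    block: BiLSTMBlock, x: FeatureMap, inference: bool = True, rng=None
) -> FeatureMap:
    """Apply one Bi-LSTM Block to a single (length, width) feature map."""
    rng = rng or np.random.default_rng(0)
    out = block(Tensor(x.values[None]), rng, inference)
    return FeatureMap(out.data[0])


# =============================================================================
# Specs for the dual module and the fusion model
# =============================================================================


@dataclass(frozen=True)
class DualModuleSpec:
    """Architecture of one dual-channel convolutional Bi-LSTM module.

    The coupling constraint 2*u_k = m_k must hold at every level, and the
    channel pair may not be two EEG derivations (same-family signals carry
    redundant information) unless explicitly overridden.
    """

    channel_pair: tuple[str, str]
    filters: tuple[int, ...] = DEFAULT_FILTERS
    units: tuple[int, ...] = DEFAULT_UNITS
    kernel_size: int = 5
    pool_size: int = 2
    dropout_rate: float = 0.2
    epoch_samples: int = 3000
    n_classes: int = 5
    allow_same_family: bool = False

    def __post_init__(self) -> None:
        if len(self.channel_pair) != 2:
            raise ValueError("channel_pair must name exactly two channels")
        if len(self.filters) != len(self.units):
            raise ValueError("filters and units ladders must have equal depth")
        for k, (m, u) in enumerate(zip(self.filters, self.units), start=1):
            if 2 * u != m:
                raise ValueError(
                    f"coupling requires 2*units == filters at every level; "
                    f"level {k} has units {u}, filters {m}"
                )
        a, b = self.channel_pair
        if (
            a.startswith(_EEG_PREFIX)
            and b.startswith(_EEG_PREFIX)
            and not self.allow_same_family
        ):
            raise ValueError(
                f"channel pair {self.channel_pair} is two EEG derivations; "
                "same-family pairs are avoided (set allow_same_family to override)"
            )

    @property
    def levels(self) -> int:
        return len(self.filters)

    def conv_specs(self) -> list[ConvBlockSpec]:
        return [
            ConvBlockSpec(m, self.kernel_size, self.pool_size, self.dropout_rate)
            for m in self.filters
        ]

    def bilstm_specs(self) -> list[BiLSTMBlockSpec]:
        return [
            BiLSTMBlockSpec(u, self.pool_size, self.dropout_rate) for u in self.units
        ]

    def scaled(self, factor: float) -> "DualModuleSpec":
        """Uniformly rescale the filter/unit ladders (e.g. 0.25 for tests)."""
        filters = tuple(max(2, int(round(m * factor))) for m in self.filters)
        units = tuple(f // 2 for f in filters)
        return replace(self, filters=filters, units=units)

    def shape_ladder(self) -> dict[str, list[int]]:
        """Expected time lengths per level for conv and coupled Bi-LSTM paths."""
        conv_lengths, t = [], self.epoch_samples
        for _ in self.filters:
            t //= self.pool_size
            conv_lengths.append(t)
        bilstm_lengths = [t // self.pool_size for t in conv_lengths]
        return {"conv": conv_lengths, "bilstm": bilstm_lengths}

    def to_dict(self) -> dict:
        return {
            "channel_pair": list(self.channel_pair),
            "filters": list(self.filters),
            "units": list(self.units),
            "kernel_size": self.kernel_size,
            "pool_size": self.pool_size,
            "dropout_rate": self.dropout_rate,
            "epoch_samples": self.epoch_samples,
            "n_classes": self.n_classes,
            "allow_same_family": self.allow_same_family,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DualModuleSpec":
        d = dict(d)
        d["channel_pair"] = tuple(d["channel_pair"])
        d["filters"] = tuple(d["filters"])
        d["units"] = tuple(d["units"])
        return cls(**d)


@dataclass(frozen=True)
class FusionModelSpec:
    """Two pre-trained dual modules plus a fresh head over their features."""

    module_spec_I: DualModuleSpec
    module_spec_II: DualModuleSpec
    frozen: bool = True

    @property
    def channels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for name in self.module_spec_I.channel_pair + self.module_spec_II.channel_pair:
            if name not in seen:
                seen.append(name)
        return tuple(seen)


# =============================================================================
# Dual-channel module
# =============================================================================


class DualModule(Module):
    """Two conv ladders coupled level-wise into a Bi-LSTM ladder, plus head.

    Per channel c, C_k^c = ConvBlock_k(C_{k-1}^c) with C_0^c the (3000, 1)
    input. The Bi-LSTM ladder consumes
    B_1 = BiLSTMBlock_1(concat[C_1^1, C_1^2]) and, for k >= 2,
    B_k = BiLSTMBlock_k(concat[C_k^1, C_k^2, B_{k-1}]); both ladders halve
    time per level so lengths align by construction. The head flattens B_last
    into a dense five-way probability layer.
    """

    def __init__(self, spec: DualModuleSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.seed = seed
        conv_specs = spec.conv_specs()
        bilstm_specs = spec.bilstm_specs()

        self.streams: list[list[ConvBlock]] = []
        for _channel in range(2):
            blocks, width = [], 1
            for cs in conv_specs:
                blocks.append(ConvBlock(cs, width, rng))
                width = cs.filters
            self.streams.append(blocks)

        self.bilstm_blocks: list[BiLSTMBlock] = []
        prev_out = 0
        for k, bs in enumerate(bilstm_specs):
            in_width = 2 * conv_specs[k].filters + prev_out
            self.bilstm_blocks.append(BiLSTMBlock(bs, in_width, rng))
            prev_out = 2 * bs.units

        ladder = spec.shape_ladder()
        self._assert_ladder(ladder)
        self.feature_width = ladder["bilstm"][-1] * prev_out
        self.head = Dense(self.feature_width, spec.n_classes, rng)
        self._dropout_rng = np.random.default_rng(np.random.default_rng(seed + 1).integers(2**31))

    def _assert_ladder(self, ladder: dict[str, list[int]]) -> None:
        for lengths in ladder.values():
            if any(t < 1 for t in lengths):
                raise ValueError(
                    f"epoch of {self.spec.epoch_samples} samples is too short for "
                    f"{self.spec.levels} pooling levels (ladder {ladder})"
                )

    def named_parameters(self, prefix: str = "") -> dict:
        out = {}
        for c, blocks in enumerate(self.streams):
            for k, blk in enumerate(blocks):
                out.update(blk.named_parameters(f"{prefix}stream{c}.conv{k}."))
        for k, blk in enumerate(self.bilstm_blocks):
            out.update(blk.named_parameters(f"{prefix}bilstm{k}."))
        out.update(self.head.named_parameters(f"{prefix}head."))
        return out

    def backbone_parameters(self) -> dict:
        return {
            k: v for k, v in self.named_parameters().items() if not k.startswith("head.")
        }

    def backbone_checksum(self) -> float:
        return float(
            sum(np.sum(p.data) + np.sum(p.data**2) for p in self.backbone_parameters().values())
        )

    def features(self, x: np.ndarray | Tensor, inference: bool = True) -> Tensor:
        """Flatten-level feature vector; x is (batch, epoch_samples, 2)."""
        data = x.data if isinstance(x, Tensor) else np.asarray(x)
        if data.ndim != 3 or data.shape[1] != self.spec.epoch_samples or data.shape[2] != 2:
            raise ValueError(
                f"expected input (batch, {self.spec.epoch_samples}, 2), got {data.shape}"
            )
        data = data.astype(_nn.DTYPE, copy=False)
        rng = self._dropout_rng
        conv_feats: list[list[Tensor]] = [[], []]
        for c in range(2):
            h = Tensor(np.ascontiguousarray(data[:, :, c : c + 1]))
            for blk in self.streams[c]:
                h = blk(h, rng, inference)
                conv_feats[c].append(h)
        b = None
        for k, blk in enumerate(self.bilstm_blocks):
            parts = [conv_feats[0][k], conv_feats[1][k]]
            if b is not None:
                parts.append(b)
            b = blk(concat(parts, axis=-1), rng, inference)
        return flatten(b)

    def summary(self) -> str:
        """Plain-text architecture summary (shapes, widths, parameter counts)."""
        spec = self.spec
        ladder = spec.shape_ladder()
        lines = [
            f"DualModule channels={spec.channel_pair}",
            f"  input per channel: ({spec.epoch_samples}, 1)",
        ]
        for k in range(spec.levels):
            lines.append(
                f"  level {k + 1}: ConvBlock x2 (m={spec.filters[k]}, "
                f"k={spec.kernel_size}) -> len {ladder['conv'][k]}; "
                f"BiLSTMBlock (u={spec.units[k]}) -> "
                f"({ladder['bilstm'][k]}, {2 * spec.units[k]})"
            )
        lines.append(
            f"  head: flatten ({self.feature_width}) -> dense {spec.n_classes} (softmax)"
        )
        lines.append(f"  parameters: {self.count_parameters():,}")
        return "\n".join(lines)

    def logits(self, x, inference: bool = True) -> Tensor:
        return self.head(self.features(x, inference))

    def predict_proba(self, x: np.ndarray, inference: bool = True) -> np.ndarray:
        """Five-class probabilities (rows on the simplex)."""
        if inference:
            with no_grad():
                return softmax(self.logits(x, True).data)
        return softmax(self.logits(x, inference).data)


def build_dual_module(spec: DualModuleSpec, seed: int = 0) -> DualModule:
    """Build a dual-channel module with seeded parameter initialization."""
    return DualModule(spec, seed)


def dual_forward(module: DualModule, epoch_pair: np.ndarray, inference: bool = True) -> np.ndarray:
    """Probability vectors for a batch of (epoch_samples, 2) channel pairs."""
    epoch_pair = np.asarray(epoch_pair, dtype=np.float64)
    if epoch_pair.ndim == 2:
        epoch_pair = epoch_pair[None]
    return module.predict_proba(epoch_pair, inference)


# =============================================================================
# Fusion model
# =============================================================================


class FusionModel(Module):
    """Concatenated features of two (frozen) dual modules under a new head."""

    def __init__(
        self,
        module_I: DualModule,
        module_II: DualModule,
        freeze: bool = True,
        seed: int = 0,
    ):
        if module_I.spec.channel_pair == module_II.spec.channel_pair:
            warnings.warn(
                "both modules consume the same channel pair "
                f"{module_I.spec.channel_pair}; fusion adds no new channels",
                stacklevel=2,
            )
        n_distinct = len(set(module_I.spec.channel_pair) | set(module_II.spec.channel_pair))
        if n_distinct < 3:
            warnings.warn(
                f"fusion covers only {n_distinct} distinct channels", stacklevel=2
            )
        if module_I.spec.n_classes != module_II.spec.n_classes:
            raise ValueError("modules disagree on class count")
        self.module_I = module_I
        self.module_II = module_II
        self.frozen = bool(freeze)
        if freeze:
            module_I.freeze()
            module_II.freeze()
        rng = np.random.default_rng(seed)
        in_width = module_I.feature_width + module_II.feature_width
        self.head = Dense(in_width, module_I.spec.n_classes, rng)

    @property
    def channels(self) -> tuple[str, ...]:
        seen: list[str] = []
        for name in self.module_I.spec.channel_pair + self.module_II.spec.channel_pair:
            if name not in seen:
                seen.append(name)
        return tuple(seen)

    def named_parameters(self, prefix: str = "") -> dict:
        out = {}
        out.update(self.module_I.named_parameters(f"{prefix}module_I."))
        out.update(self.module_II.named_parameters(f"{prefix}module_II."))
        out.update(self.head.named_parameters(f"{prefix}head."))
        return out

    def backbone_checksum(self) -> float:
        return self.module_I.backbone_checksum() + self.module_II.backbone_checksum() + float(
            sum(np.sum(p.data) + np.sum(p.data**2) for p in self.module_I.head.parameters())
        ) + float(
            sum(np.sum(p.data) + np.sum(p.data**2) for p in self.module_II.head.parameters())
        )

    def extract_features(
        self, x_I: np.ndarray, x_II: np.ndarray, batch_size: int = 64
    ) -> np.ndarray:
        """Concatenated backbone features, graph-free (frozen-path shortcut).

        With both backbones frozen and dropout inactive these features are a
        fixed transform of the input, so the fusion head can be trained on
        them directly without re-running the backbones every step.
        """
        n = np.asarray(x_I).shape[0]
        out = None
        with no_grad():
            for start in range(0, n, batch_size):
                f_I = self.module_I.features(x_I[start : start + batch_size], True)
                f_II = self.module_II.features(x_II[start : start + batch_size], True)
                block = np.concatenate([f_I.data, f_II.data], axis=1)
                if out is None:
                    out = np.empty((n, block.shape[1]), dtype=block.dtype)
                out[start : start + batch_size] = block
        return out

    def logits(self, x_I: np.ndarray, x_II: np.ndarray, inference: bool = True) -> Tensor:
        if self.frozen:
            # frozen backbones act as fixed inference-mode feature extractors
            with no_grad():
                f_I = self.module_I.features(x_I, True)
                f_II = self.module_II.features(x_II, True)
        else:
            f_I = self.module_I.features(x_I, inference)
            f_II = self.module_II.features(x_II, inference)
        return self.head(concat([f_I, f_II], axis=-1))

    def head_logits(self, features: np.ndarray) -> Tensor:
        """Head forward on precomputed backbone features."""
        return self.head(Tensor(features))

    def predict_proba(self, x_I: np.ndarray, x_II: np.ndarray, inference: bool = True) -> np.ndarray:
        if inference:
            with no_grad():
                return softmax(self.logits(x_I, x_II, True).data)
        return softmax(self.logits(x_I, x_II, inference).data)


def build_fusion(
    module_I: DualModule, module_II: DualModule, freeze: bool = True, seed: int = 0
) -> FusionModel:
    """Fuse two pre-trained dual modules under a fresh five-way head."""
    return FusionModel(module_I, module_II, freeze, seed)


def count_parameters(model: Module, trainable_only: bool = False) -> int:
    """Exact parameter count; frozen backbones excluded when trainable_only."""
    return model.count_parameters(trainable_only)


# =============================================================================
# Checkpoints
# =============================================================================


def save_checkpoint(path: str | Path, module: DualModule, stage: str = "pretrained") -> Path:
    """Serialize parameters (.npz) with a JSON manifest (spec, seed, stage)."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **module.state_dict())
    manifest = {"spec": module.spec.to_dict(), "seed": module.seed, "stage": stage}
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))
    return path.with_suffix(".npz")


def load_checkpoint(path: str | Path) -> DualModule:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    module = DualModule(DualModuleSpec.from_dict(manifest["spec"]), manifest["seed"])
    with np.load(path.with_suffix(".npz")) as data:
        module.load_state_dict({k: data[k] for k in data.files})
    return module
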