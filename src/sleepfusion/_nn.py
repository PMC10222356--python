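"""Minimal reverse-mode autodiff engine backing the convolutional Bi-LSTM.

The graph is built from a handful of coarse operations — batched dense
products, same-padded 1-D convolution, temporal max pooling, dropout, and a
whole-sequence bidirectional LSTM whose backward pass is hand-derived
backpropagation through time — which keeps the Python overhead per training
step small while leaving the network wiring free-form (the level-wise
Conv/Bi-LSTM coupling is an arbitrary DAG).

Numerical conventions: batched sequence tensors are (batch, time, width);
compute happens in single precision by default (``DTYPE``; flip to float64
for high-precision verification); convolution is evaluated as a sum of k
time-shifted dense products, so all heavy lifting is large GEMMs; LSTM gate
pre-activations are packed in one matrix in the order forget, input,
output, candidate; parameters are initialized fan-based uniform
(Glorot/Xavier) from a seeded generator, with the forget-gate bias at 1.
Inside :func:`no_grad`, operations return detached tensors and skip every
cache, which is how frozen backbones and validation passes stay cheap.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

__all__ = [
    "DTYPE",
    "no_grad",
    "Tensor",
    "Parameter",
    "Module",
    "Dense",
    "Conv1D",
    "LSTM",
    "BiLSTM",
    "Adam",
    "concat",
    "relu",
    "max_pool1d",
    "dropout",
    "flatten",
    "softmax",
    "softmax_cross_entropy",
    "conv1d_same",
    "lstm_sequence",
    "bilstm_sequence_op",
    "reverse_time",
]

#: Compute precision for parameters and activations. Single precision is the
#: working default (it halves memory traffic, which dominates on CPU);
#: switch to np.float64 before building a model when verifying gradients.
DTYPE = np.float32

_GRAD_ENABLED = [True]


@contextmanager
def no_grad():
    """Disable graph construction: ops return detached, cache-free tensors."""
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


# =============================================================================
# Autodiff core
# =============================================================================


class Tensor:
    """An ndarray plus the closure that routes its gradient to its parents."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def backward(self, grad=None):
        """Reverse-accumulate gradients from this tensor through the graph."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: sequence graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        for node in topo:
            node.grad = None
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accumulate(self, grad):
        # Ownership contract: ops pass freshly allocated arrays (safe to
        # adopt by reference); only views get copied. No op passes the same
        # owning array to two different parents.
        if self.grad is None:
            if grad.base is not None or not grad.flags.owndata:
                grad = grad.copy()
            self.grad = grad
        else:
            self.grad += grad


class Parameter(Tensor):
    """A learnable tensor; ``trainable=False`` freezes it for the optimizer."""

    __slots__ = ("trainable",)

    def __init__(self, data, trainable=True):
        super().__init__(np.asarray(data, dtype=DTYPE), requires_grad=True)
        self.trainable = trainable


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=DTYPE))


def _make(out_data, parents, backward) -> Tensor:
    if not grad_enabled():
        return Tensor(out_data)
    return Tensor(out_data, parents=parents, backward=backward)


# =============================================================================
# Operations
# =============================================================================


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data @ b.data
    if not grad_enabled():
        return Tensor(out_data)

    def backward(grad):
        a._accumulate(grad @ b.data.T)
        b._accumulate(a.data.T @ grad)

    return Tensor(out_data, parents=(a, b), backward=backward)


def add_bias(x: Tensor, b: Tensor) -> Tensor:
    """x + b with b broadcast over every leading axis."""

    def backward(grad):
        x._accumulate(grad)
        axes = tuple(range(grad.ndim - b.data.ndim))
        b._accumulate(grad.sum(axis=axes) if axes else grad)

    return _make(x.data + b.data, (x, b), backward)


def relu(x: Tensor) -> Tensor:
    if not grad_enabled():
        return Tensor(np.maximum(x.data, 0))
    mask = x.data > 0
    out_data = x.data * mask

    def backward(grad):
        x._accumulate(grad * mask)

    return Tensor(out_data, parents=(x,), backward=backward)


def concat(tensors, axis=-1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    if not grad_enabled():
        return Tensor(out_data)
    splits = np.cumsum([t.data.shape[axis] for t in tensors])[:-1]

    def backward(grad):
        for t, g in zip(tensors, np.split(grad, splits, axis=axis)):
            t._accumulate(g)

    return Tensor(out_data, parents=tuple(tensors), backward=backward)


def flatten(x: Tensor) -> Tensor:
    """(batch, ...) -> (batch, prod(...))."""
    shape = x.data.shape

    def backward(grad):
        x._accumulate(grad.reshape(shape))

    return _make(x.data.reshape(shape[0], -1), (x,), backward)


def max_pool1d(x: Tensor, pool_size: int = 2) -> Tensor:
    """Temporal max pool over axis 1, stride = pool_size, floor semantics."""
    b, t, c = x.data.shape
    t_out = t // pool_size
    if t_out < 1:
        raise ValueError(f"sequence length {t} shorter than pool size {pool_size}")
    windows = x.data[:, : t_out * pool_size, :].reshape(b, t_out, pool_size, c)
    if not grad_enabled():
        return Tensor(windows.max(axis=2))
    if pool_size == 2:  # pairwise max avoids the (slow) generic argmax
        w0 = windows[:, :, 0, :]
        w1 = windows[:, :, 1, :]
        first_wins = w0 >= w1  # ties route to the earlier sample
        out_data = np.where(first_wins, w0, w1)

        def backward(grad):
            gx = np.zeros_like(x.data)
            gw = gx[:, : t_out * pool_size, :].reshape(b, t_out, pool_size, c)
            gw[:, :, 0, :] = np.where(first_wins, grad, 0.0)
            gw[:, :, 1, :] = np.where(first_wins, 0.0, grad)
            x._accumulate(gx)

        return Tensor(out_data, parents=(x,), backward=backward)

    argmax = windows.argmax(axis=2)
    out_data = np.take_along_axis(windows, argmax[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(grad):
        gx = np.zeros_like(x.data)
        gw = gx[:, : t_out * pool_size, :].reshape(b, t_out, pool_size, c)
        np.put_along_axis(gw, argmax[:, :, None, :], grad[:, :, None, :], axis=2)
        x._accumulate(gx)

    return Tensor(out_data, parents=(x,), backward=backward)


def dropout(x: Tensor, rate: float, rng: np.random.Generator, inference: bool) -> Tensor:
    """Inverted dropout: scales kept units by 1/(1-rate); identity at inference."""
    if inference or rate <= 0.0:
        return x
    keep = 1.0 - rate
    u = rng.random(x.data.shape, dtype=np.float32)
    mask = (u < keep).astype(x.data.dtype)
    mask *= 1.0 / keep
    out_data = x.data * mask

    def backward(grad):
        x._accumulate(grad * mask)

    return _make(out_data, (x,), backward)


def conv1d_same(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded stride-1 1-D convolution as k time-shifted dense products.

    x: (batch, time, c_in); w: (k, c_in, c_out); b: (c_out,). Zero padding
    k//2 left and k-1-k//2 right keeps the output length equal to the input
    length, so pooling alone controls the length ladder. Evaluating the
    kernel tap-by-tap turns the whole operation into k large GEMMs.
    """
    batch, t, c_in = x.data.shape
    k, c_in_w, c_out = w.data.shape
    if c_in_w != c_in:
        raise ValueError(f"conv input width {c_in} != kernel width {c_in_w}")
    pl = k // 2
    pr = k - 1 - pl
    xp = np.pad(x.data, ((0, 0), (pl, pr), (0, 0)))
    n_pad = xp.shape[1]
    flat = xp.reshape(-1, c_in)
    n_rows = flat.shape[0]
    # Work in flattened (batch*n_pad) coordinates so every tap is one
    # contiguous GEMM plus one contiguous shifted add. Rows that bleed
    # across a batch boundary land in the discarded pad region (r >= t).
    buf = np.zeros((n_rows, c_out), dtype=x.data.dtype)
    for j in range(k):
        z = flat @ w.data[j]
        if j == 0:
            buf += z
        else:
            buf[:-j] += z[j:]
    out_data = buf.reshape(batch, n_pad, c_out)[:, :t, :] + b.data
    if not grad_enabled():
        return Tensor(out_data)

    def backward(grad):
        gpad = np.zeros((n_rows, c_out), dtype=grad.dtype)
        gpad.reshape(batch, n_pad, c_out)[:, :t, :] = grad
        gw = np.empty_like(w.data)
        dflat = np.zeros_like(flat)
        for j in range(k):
            if j == 0:
                gw[0] = flat.T @ gpad
                dflat += gpad @ w.data[0].T
            else:
                gw[j] = flat[j:].T @ gpad[:-j]
                dflat[j:] += gpad[:-j] @ w.data[j].T
        w._accumulate(gw)
        b._accumulate(grad.sum(axis=(0, 1)))
        x._accumulate(
            np.ascontiguousarray(
                dflat.reshape(batch, n_pad, c_in)[:, pl : pl + t, :]
            )
        )

    return Tensor(out_data, parents=(x, w, b), backward=backward)


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def lstm_sequence(x: Tensor, w: Tensor, b: Tensor, units: int) -> Tensor:
    """Single-direction full-sequence LSTM from zero state (reference path).

    x: (batch, time, c_in); w: (units + c_in, 4*units) packing the forget,
    input, output, and candidate gate weights acting on [h_{t-1}, x_t];
    b: (4*units,). Returns per-step hidden states (batch, time, units).
    The production path is :func:`bilstm_sequence_op`, which fuses both
    directions; this op exists for one-directional use and cross-checks.
    """
    out = bilstm_sequence_op(x, w, b, w, b, units, _single=True)
    return out


def bilstm_sequence_op(
    x: Tensor,
    w_fwd: Tensor,
    b_fwd: Tensor,
    w_bwd: Tensor,
    b_bwd: Tensor,
    units: int,
    _single: bool = False,
) -> Tensor:
    """Bidirectional LSTM over a full sequence in one fused time loop.

    The two directions share each per-step matmul (weights stacked along a
    leading direction axis; the backward stream sees the time-reversed
    input), which halves the Python-level loop overhead relative to two
    independent passes. Output is (batch, time, 2*units): forward states
    then re-reversed backward states. Gradients by hand-derived BPTT.

    Per step, with z_t = [h_{t-1}, x_t]: the forget, input, and output gates
    are logistic in their pre-activations, the candidate is tanh;
    c_t = f*c_{t-1} + i*g and h_t = o*tanh(c_t).
    """
    batch, t, c_in = x.data.shape
    u = units
    dt = x.data.dtype
    record = grad_enabled()
    if _single:
        xs = x.data[None]
        wd = w_fwd.data[None]
        bd = b_fwd.data[None, None, :]
        ndir = 1
    else:
        xs = np.stack([x.data, x.data[:, ::-1, :]])  # (2, batch, t, c_in)
        wd = np.stack([w_fwd.data, w_bwd.data])  # (2, u + c_in, 4u)
        bd = np.stack([b_fwd.data, b_bwd.data])[:, None, :]
        ndir = 2
    wh = np.ascontiguousarray(wd[:, :u, :])  # recurrent block (ndir, u, 4u)
    wx = wd[:, u:, :]  # input block (ndir, c_in, 4u)
    # hoist the input projection out of the time loop: one GEMM for all steps
    xw = xs @ wx[:, None] + bd[:, :, None, :]  # (ndir, batch, t, 4u)
    h = np.zeros((ndir, batch, u), dtype=dt)
    c = np.zeros((ndir, batch, u), dtype=dt)
    hs = np.empty((ndir, batch, t, u), dtype=dt)
    if record:
        cache_fio = np.empty((t, ndir, batch, 3 * u), dtype=dt)
        cache_g = np.empty((t, ndir, batch, u), dtype=dt)
        cache_c = np.empty((t, ndir, batch, u), dtype=dt)
        cache_tc = np.empty((t, ndir, batch, u), dtype=dt)
        cache_hp = np.empty((t, ndir, batch, u), dtype=dt)
    for step in range(t):
        a = h @ wh
        a += xw[:, :, step, :]
        fio = _sigmoid(a[:, :, : 3 * u])
        g = np.tanh(a[:, :, 3 * u :])
        f = fio[:, :, :u]
        i = fio[:, :, u : 2 * u]
        o = fio[:, :, 2 * u :]
        if record:
            cache_hp[step] = h
            cache_fio[step] = fio
            cache_g[step] = g
        c = f * c + i * g
        tc = np.tanh(c)
        h = o * tc
        hs[:, :, step, :] = h
        if record:
            cache_c[step] = c
            cache_tc[step] = tc
    if _single:
        out_data = hs[0]
    else:
        out_data = np.concatenate([hs[0], hs[1][:, ::-1, :]], axis=-1)
    if not record:
        return Tensor(out_data)

    def backward(grad):
        if _single:
            gh = np.ascontiguousarray(grad[None])
        else:  # per-direction output grads back in loop-time order
            gh = np.stack([grad[:, :, :u], grad[:, :, u:][:, ::-1, :]])
        dWh = np.zeros_like(wh)
        das = np.empty((t, ndir, batch, 4 * u), dtype=dt)
        dh_next = np.zeros((ndir, batch, u), dtype=dt)
        dc_next = np.zeros((ndir, batch, u), dtype=dt)
        whT = wh.transpose(0, 2, 1)
        for step in range(t - 1, -1, -1):
            fio = cache_fio[step]
            f = fio[:, :, :u]
            i = fio[:, :, u : 2 * u]
            o = fio[:, :, 2 * u :]
            g = cache_g[step]
            tc = cache_tc[step]
            dh = gh[:, :, step, :] + dh_next
            dc = dc_next + dh * o * (1.0 - tc * tc)
            c_prev = cache_c[step - 1] if step > 0 else 0.0
            da = das[step]
            da[:, :, :u] = dc * c_prev * f * (1.0 - f)
            da[:, :, u : 2 * u] = dc * g * i * (1.0 - i)
            da[:, :, 2 * u : 3 * u] = dh * tc * o * (1.0 - o)
            da[:, :, 3 * u :] = dc * i * (1.0 - g * g)
            dc_next = dc * f
            dWh += cache_hp[step].transpose(0, 2, 1) @ da
            dh_next = da @ whT
        # input-side gradients as whole-sequence GEMMs
        dd = das.transpose(1, 0, 2, 3).reshape(ndir, t * batch, 4 * u)
        xs_r = xs.transpose(0, 2, 1, 3).reshape(ndir, t * batch, c_in)
        dWx = xs_r.transpose(0, 2, 1) @ dd  # (ndir, c_in, 4u)
        db = dd.sum(axis=1)
        dxs = (
            (dd @ wx.transpose(0, 2, 1))
            .reshape(ndir, t, batch, c_in)
            .transpose(0, 2, 1, 3)
        )
        dW_full = np.concatenate([dWh, dWx], axis=1)  # (ndir, u+c_in, 4u)
        if _single:
            w_fwd._accumulate(dW_full[0])
            b_fwd._accumulate(db[0])
            x._accumulate(np.ascontiguousarray(dxs[0]))
        else:
            w_fwd._accumulate(dW_full[0])
            w_bwd._accumulate(dW_full[1])
            b_fwd._accumulate(db[0])
            b_bwd._accumulate(db[1])
            x._accumulate(dxs[0] + dxs[1][:, ::-1, :])

    parents = (x, w_fwd, b_fwd) if _single else (x, w_fwd, b_fwd, w_bwd, b_bwd)
    return Tensor(out_data, parents=parents, backward=backward)


def reverse_time(x: Tensor) -> Tensor:
    def backward(grad):
        x._accumulate(grad[:, ::-1, :])

    return _make(x.data[:, ::-1, :].copy(), (x,), backward)


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax of a plain array (inference-side probabilities)."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy with a fused softmax gradient."""
    probs = softmax(logits.data)
    n = logits.data.shape[0]
    onehot = np.asarray(onehot, dtype=logits.data.dtype)
    loss = -np.sum(onehot * np.log(probs + 1e-12)) / n

    def backward(grad):
        logits._accumulate(grad * (probs - onehot) / n)

    return _make(loss, (logits,), backward)


# =============================================================================
# Modules
# =============================================================================


class Module:
    """Named-parameter container with freezing and flat state dicts."""

    def named_parameters(self, prefix: str = "") -> dict[str, Parameter]:
        out: dict[str, Parameter] = {}
        for name, value in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(value, Parameter):
                out[key] = value
            elif isinstance(value, Module):
                out.update(value.named_parameters(f"{key}."))
            elif isinstance(value, (list, tuple)):
                for idx, item in enumerate(value):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{key}.{idx}."))
        return out

    def parameters(self) -> list[Parameter]:
        return list(self.named_parameters().values())

    def count_parameters(self, trainable_only: bool = False) -> int:
        return sum(
            p.data.size
            for p in self.parameters()
            if p.trainable or not trainable_only
        )

    def freeze(self) -> "Module":
        for p in self.parameters():
            p.trainable = False
        return self

    def unfreeze(self) -> "Module":
        for p in self.parameters():
            p.trainable = True
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(
                    f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}"
                )
            p.data = state[k].astype(p.data.dtype).copy()

    def checksum(self) -> float:
        """Deterministic scalar fingerprint of all parameter values."""
        return float(
            sum(
                np.sum(p.data, dtype=np.float64)
                + np.sum(p.data * p.data, dtype=np.float64)
                for p in self.parameters()
            )
        )


def glorot_uniform(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Module):
    def __init__(self, in_width: int, out_width: int, rng: np.random.Generator):
        self.w = Parameter(glorot_uniform(rng, (in_width, out_width), in_width, out_width))
        self.b = Parameter(np.zeros(out_width))

    def __call__(self, x: Tensor) -> Tensor:
        return add_bias(matmul(x, self.w), self.b)


class Conv1D(Module):
    def __init__(self, in_width: int, filters: int, kernel_size: int, rng: np.random.Generator):
        fan_in = kernel_size * in_width
        self.w = Parameter(
            glorot_uniform(rng, (kernel_size, in_width, filters), fan_in, filters)
        )
        self.b = Parameter(np.zeros(filters))

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d_same(x, self.w, self.b)


class LSTM(Module):
    """One direction; forget-gate bias initialized to 1."""

    def __init__(self, in_width: int, units: int, rng: np.random.Generator):
        self.units = units
        fan_in = units + in_width
        self.w = Parameter(glorot_uniform(rng, (fan_in, 4 * units), fan_in, units))
        bias = np.zeros(4 * units)
        bias[:units] = 1.0
        self.b = Parameter(bias)

    def __call__(self, x: Tensor) -> Tensor:
        return lstm_sequence(x, self.w, self.b, self.units)


class BiLSTM(Module):
    """Forward and backward LSTMs; per-step outputs concatenated (width 2u).

    The backward stream is, definitionally, a forward LSTM applied to the
    time-reversed sequence with its outputs re-reversed. Both directions run
    in one fused loop (see :func:`bilstm_sequence_op`).
    """

    def __init__(self, in_width: int, units: int, rng: np.random.Generator):
        self.fwd = LSTM(in_width, units, rng)
        self.bwd = LSTM(in_width, units, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return bilstm_sequence_op(
            x, self.fwd.w, self.fwd.b, self.bwd.w, self.bwd.b, self.fwd.units
        )


# =============================================================================
# Optimizer
# =============================================================================


class Adam:
    """Adaptive-moment optimizer; skips frozen (non-trainable) parameters."""

    def __init__(self, params, learning_rate=0.001, beta1=0.9, beta2=0.999, eps=1e-7):
        self.params = list(params)
        self.lr = learning_rate
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if not p.trainable or p.grad is None:
                continue
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad * p.grad
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
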