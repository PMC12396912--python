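"""Channel attention gate (CAG).

The gate takes a pair of equally shaped feature maps — shallow *appearance*
features ``x`` from an encoder level and deep *semantic* features ``y`` from
the adjacent decoder level (already upsampled by the caller) — and recalibrates
``x`` channel-wise before the usual skip merge:

1. project both maps through learned 1x1x1 convolutions and a leaky ReLU,
   giving ``f`` and ``g``;
2. correlate the channels of ``f`` against those of ``g`` over all voxels,
   giving a C x C matrix ``delta``;
3. soften ``delta`` row-wise into attention coefficients ``alpha`` (each row
   sums to 1);
4. fuse ``f + g`` and mix it through a third 1x1x1 projection into the gate
   signal ``h``;
5. form the per-voxel response ``r_i = sum_j alpha[i, j] * h_j`` and squash it
   through a sigmoid into gate weights ``omega`` in (0, 1);
6. multiply ``f`` by ``omega`` and merge the result with ``y`` (channel
   concatenation by default, summation optionally).

Because 0 < omega < 1, gating only ever attenuates: |f~| <= |f| everywhere.

All functions accept either numpy arrays or autodiff Tensors and return the
same kind; inside the network they run on Tensors so gradients flow through
every projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, concat
from . import nn

__all__ = [
    "CAGParams", "make_cag_params", "project_features", "channel_correlation",
    "channel_softmax", "gate_signal", "attention_response", "gate_weights",
    "apply_gate_and_merge", "cag_forward", "CAGGate", "SpatialAttentionGate",
    "PlainMerge",
]


@dataclass
class CAGParams:
    """Weights of one gate: three C->C channel projections (realised as
    1x1x1 convolutions) with biases, plus the leaky-ReLU leakage ``mu``."""

    w_f: np.ndarray
    w_g: np.ndarray
    w_h: np.ndarray
    b_f: np.ndarray = None
    b_g: np.ndarray = None
    b_h: np.ndarray = None
    mu: float = 0.01

    def __post_init__(self):
        c = np.asarray(self.w_f).shape[0]
        for name in ("b_f", "b_g", "b_h"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(c, dtype=np.float32))
        if self.mu < 0:
            raise ValueError(f"leakage mu must be >= 0, got {self.mu}")


def make_cag_params(channels: int, rng: np.random.Generator,
                    mu: float = 0.01) -> CAGParams:
    """Fan-in initialised parameters for a C-channel gate."""
    w = lambda: nn.he_init(rng, (channels, channels), channels)
    return CAGParams(w_f=w(), w_g=w(), w_h=w(), mu=mu)


def _check_same_shape(a, b, what: str):
    if tuple(a.shape) != tuple(b.shape):
        raise ValueError(f"{what}: shapes {tuple(a.shape)} and {tuple(b.shape)} differ")


def _unwrap(result, was_numpy: bool):
    if not was_numpy:
        return result
    if isinstance(result, tuple):
        return tuple(r.numpy() for r in result)
    return result.numpy()


def _project(x: Tensor, w, b) -> Tensor:
    """1x1x1 convolution = per-voxel channel mixing."""
    c = x.shape[0]
    flat = x.reshape(c, -1)
    w = w if isinstance(w, Tensor) else Tensor(np.asarray(w, dtype=np.float32))
    b = b if isinstance(b, Tensor) else Tensor(np.asarray(b, dtype=np.float32))
    out = w @ flat + b.reshape(c, 1)
    return out.reshape(x.shape)


def project_features(x, y, params: CAGParams):
    """Project appearance/semantic maps into the feature spaces F, G:
    f = LReLU(W_F * x), g = LReLU(W_G * y)."""
    was_numpy = not isinstance(x, Tensor)
    x, y = as_tensor(x), as_tensor(y)
    _check_same_shape(x, y, "project_features")
    f = _project(x, params.w_f, params.b_f).leaky_relu(params.mu)
    g = _project(y, params.w_g, params.b_g).leaky_relu(params.mu)
    return _unwrap((f, g), was_numpy)


def channel_correlation(f, g):
    """delta[i, j] = <f_i, g_j> over all voxels — a C x C channel Gram
    matrix between the two projected maps."""
    was_numpy = not isinstance(f, Tensor)
    f, g = as_tensor(f), as_tensor(g)
    _check_same_shape(f, g, "channel_correlation")
    c = f.shape[0]
    delta = f.reshape(c, -1) @ g.reshape(c, -1).transpose()
    return _unwrap(delta, was_numpy)


def channel_softmax(delta):
    """Row-wise softmax of the correlation matrix (max-subtracted for
    numerical stability); rows sum to 1."""
    was_numpy = not isinstance(delta, Tensor)
    delta = as_tensor(delta)
    shift = delta.data.max(axis=-1, keepdims=True)  # constant w.r.t. the tape
    e = (delta - Tensor(shift)).exp()
    alpha = e * e.sum(axis=-1, keepdims=True).pow(-1.0)
    return _unwrap(alpha, was_numpy)


def gate_signal(f, g, params: CAGParams):
    """Gate-signal source h = W_h * (f + g): spatial fusion of the two
    projected maps followed by a channel mixing."""
    was_numpy = not isinstance(f, Tensor)
    f, g = as_tensor(f), as_tensor(g)
    _check_same_shape(f, g, "gate_signal")
    h = _project(f + g, params.w_h, params.b_h)
    return _unwrap(h, was_numpy)


def attention_response(alpha, h):
    """r_i = sum_j alpha[i, j] h_j — each output channel is a convex
    combination of the fused maps; returned flattened as C x N."""
    was_numpy = not isinstance(h, Tensor)
    alpha, h = as_tensor(alpha), as_tensor(h)
    c = h.shape[0]
    if alpha.shape != (c, c):
        raise ValueError(
            f"alpha is {tuple(alpha.shape)} but h has {c} channels")
    r = alpha @ h.reshape(c, -1)
    return _unwrap(r, was_numpy)


def gate_weights(r):
    """omega = sigmoid(r), strictly inside (0, 1) for finite input."""
    was_numpy = not isinstance(r, Tensor)
    omega = as_tensor(r).sigmoid()
    return _unwrap(omega, was_numpy)


def apply_gate_and_merge(f, omega, y, merge_mode: str = "concat"):
    """Gate the appearance features, f~ = f * omega, then merge the semantic
    map back in: channel concatenation (default, giving 2C channels) or
    elementwise summation (C channels)."""
    was_numpy = not isinstance(f, Tensor)
    f, omega, y = as_tensor(f), as_tensor(omega), as_tensor(y)
    if omega.size != f.size:
        raise ValueError(
            f"omega has {omega.size} entries but f has shape {tuple(f.shape)}")
    gated = f * omega.reshape(f.shape)
    if merge_mode == "concat":
        out = concat([gated, y], axis=0)
    elif merge_mode == "sum":
        _check_same_shape(f, y, "apply_gate_and_merge(sum)")
        out = gated + y
    else:
        raise ValueError(f"unknown merge mode {merge_mode!r}")
    return _unwrap(out, was_numpy)


def cag_forward(x, y, params: CAGParams, merge_mode: str = "concat"):
    """Full gate: project, correlate, soften, fuse, respond, squash, merge."""
    was_numpy = not isinstance(x, Tensor)
    x, y = as_tensor(x), as_tensor(y)
    _check_same_shape(x, y, "cag_forward")
    f, g = project_features(x, y, params)
    delta = channel_correlation(f, g)
    alpha = channel_softmax(delta)
    h = gate_signal(f, g, params)
    r = attention_response(alpha, h)
    omega = gate_weights(r)
    out = apply_gate_and_merge(f, omega, y, merge_mode=merge_mode)
    return _unwrap(out, was_numpy)


class CAGGate(nn.Module):
    """Trainable channel attention gate for one skip connection."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 mu: float = 0.01, merge_mode: str = "concat"):
        super().__init__()
        self.channels = channels
        self.merge_mode = merge_mode
        self.mu = mu
        for name in ("w_f", "w_g", "w_h"):
            self.register(name, nn.he_init(rng, (channels, channels), channels))
        for name in ("b_f", "b_g", "b_h"):
            self.register(name, np.zeros(channels, dtype=np.float32))

    @property
    def out_channels(self) -> int:
        return 2 * self.channels if self.merge_mode == "concat" else self.channels

    def gate_params(self) -> CAGParams:
        p = CAGParams.__new__(CAGParams)  # keep Tensors, skip ndarray coercion
        p.w_f, p.w_g, p.w_h = self.w_f, self.w_g, self.w_h
        p.b_f, p.b_g, p.b_h = self.b_f, self.b_g, self.b_h
        p.mu = self.mu
        return p

    def __call__(self, x: Tensor, y: Tensor) -> Tensor:
        return cag_forward(x, y, self.gate_params(), merge_mode=self.merge_mode)


class SpatialAttentionGate(nn.Module):
    """Classical additive attention gate (spatial, single-channel psi map):
    psi = sigmoid(W_psi . LReLU(W_x x + W_g y)), output = merge(x * psi, y).
    Kept as an ablation arm alongside the channel gate."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 mu: float = 0.01, merge_mode: str = "concat"):
        super().__init__()
        self.channels = channels
        self.merge_mode = merge_mode
        self.mu = mu
        self.proj_x = nn.Conv3d(channels, channels, 1, rng)
        self.proj_y = nn.Conv3d(channels, channels, 1, rng)
        self.psi = nn.Conv3d(channels, 1, 1, rng)

    @property
    def out_channels(self) -> int:
        return 2 * self.channels if self.merge_mode == "concat" else self.channels

    def __call__(self, x: Tensor, y: Tensor) -> Tensor:
        x, y = as_tensor(x), as_tensor(y)
        _check_same_shape(x, y, "SpatialAttentionGate")
        att = (self.proj_x(x) + self.proj_y(y)).leaky_relu(self.mu)
        psi = self.psi(att).sigmoid()  # 1 x D x H x W, broadcast over channels
        gated = x * psi
        if self.merge_mode == "concat":
            return concat([gated, y], axis=0)
        return gated + y


class PlainMerge(nn.Module):
    """Ungated skip merge (the gate_type='none' arm)."""

    def __init__(self, channels: int, merge_mode: str = "concat"):
        super().__init__()
        self.channels = channels
        self.merge_mode = merge_mode

    @property
    def out_channels(self) -> int:
        return 2 * self.channels if self.merge_mode == "concat" else self.channels

    def __call__(self, x: Tensor, y: Tensor) -> Tensor:
        if self.merge_mode == "concat":
            return concat([as_tensor(x), as_tensor(y)], axis=0)
        return as_tensor(x) + as_tensor(y)
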