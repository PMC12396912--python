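"""Trainable layers for volumetric networks, built on :mod:`cagsnet.autodiff`.

Single-sample (no batch axis) convention throughout: feature maps are
(C, D, H, W) arrays. Group normalisation therefore normalises over all voxels
of one sample, which is exactly the batch-size-1 regime it is designed for.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = [
    "Module", "ModuleList", "Conv3d", "GroupNorm", "ChannelDropout",
    "Upsample3d", "Adam",
]


class Module:
    """Base class: parameter registry plus train/eval mode flag."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def register(self, name: str, array: np.ndarray) -> Tensor:
        p = Tensor(array)
        p.requires_grad = True
        self._params[name] = p
        object.__setattr__(self, name, p)
        return p

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + name, p) for name, p in self._params.items()]
        for cname, child in self._children.items():
            out.extend(child.named_parameters(prefix + cname + "."))
        return out

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) ^ set(state)
        if missing:
            raise ValueError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(
                    f"shape mismatch for {name}: {p.data.shape} vs {state[name].shape}")
            p.data = np.asarray(state[name], dtype=np.float32).copy()


class ModuleList(Module):
    """Ordered container whose items participate in parameter discovery."""

    def __init__(self, modules=()):
        super().__init__()
        self._items: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, module: Module):
        self._children[str(len(self._items))] = module
        self._items.append(module)
        return self

    def __iter__(self):
        return iter(self._items)

    def __len__(self):
        return len(self._items)

    def __getitem__(self, i):
        return self._items[i]


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv3d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None, bias: bool = True):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.padding = kernel // 2 if padding is None else padding
        fan_in = in_ch * kernel ** 3
        self.register("weight", he_init(rng, (out_ch, in_ch, kernel, kernel, kernel), fan_in))
        if bias:
            self.register("bias", np.zeros(out_ch, dtype=np.float32))
        else:
            self.bias = None

    def __call__(self, x: Tensor) -> Tensor:
        return as_tensor(x).conv3d(self.weight, self.bias,
                                   stride=self.stride, padding=self.padding)


class GroupNorm(Module):
    """Normalise over (channel-group, all voxels) of a single sample."""

    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        super().__init__()
        groups = min(groups, channels)
        if channels % groups != 0:
            raise ValueError(
                f"group count {groups} does not divide channel count {channels}")
        self.channels, self.groups, self.eps = channels, groups, eps
        self.register("gamma", np.ones(channels, dtype=np.float32))
        self.register("beta", np.zeros(channels, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        c, spatial = x.shape[0], x.shape[1:]
        g = self.groups
        xg = x.reshape(g, (c // g) * int(np.prod(spatial)))
        mu = xg.mean(axis=1, keepdims=True)
        centered = xg - mu
        var = (centered * centered).mean(axis=1, keepdims=True)
        norm = centered * (var + self.eps).pow(-0.5)
        norm = norm.reshape((c,) + spatial)
        gamma = self.gamma.reshape((c,) + (1,) * len(spatial))
        beta = self.beta.reshape((c,) + (1,) * len(spatial))
        return norm * gamma + beta


class ChannelDropout(Module):
    """Zero whole feature channels with probability `rate` (train mode only),
    rescaling survivors by 1/(1-rate)."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return as_tensor(x)
        x = as_tensor(x)
        keep = (self.rng.random(x.shape[0]) >= self.rate).astype(np.float32)
        mask = keep[:, None, None, None] / (1.0 - self.rate)
        return x * Tensor(mask)


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Linear-interpolation matrix mapping length n_in to n_out
    (half-voxel aligned, edges clamped)."""
    m = np.zeros((n_out, n_in), dtype=np.float32)
    scale = n_in / n_out
    for j in range(n_out):
        pos = (j + 0.5) * scale - 0.5
        lo = int(np.floor(pos))
        frac = pos - lo
        lo_c = min(max(lo, 0), n_in - 1)
        hi_c = min(max(lo + 1, 0), n_in - 1)
        m[j, lo_c] += 1.0 - frac
        m[j, hi_c] += frac
    return m


class Upsample3d(Module):
    """Trilinear upsampling to a target spatial shape (default 2x), or
    nearest-neighbour repetition when mode='nearest'."""

    def __init__(self, mode: str = "trilinear"):
        super().__init__()
        if mode not in ("trilinear", "nearest"):
            raise ValueError(f"unknown upsampling mode {mode!r}")
        self.mode = mode

    def __call__(self, x: Tensor, target_shape: tuple) -> Tensor:
        x = as_tensor(x)
        if tuple(x.shape[1:]) == tuple(target_shape):
            return x
        if self.mode == "nearest":
            mats = []
            for n_in, n_out in zip(x.shape[1:], target_shape):
                idx = (np.arange(n_out) * n_in // n_out)
                m = np.zeros((n_out, n_in), dtype=np.float32)
                m[np.arange(n_out), idx] = 1.0
                mats.append(m)
        else:
            mats = [_interp_matrix(n_in, n_out)
                    for n_in, n_out in zip(x.shape[1:], target_shape)]
        return x.interp_axes(mats)


class Adam:
    """Standard Adam with bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 4e-5,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
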