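"""Adjacent-context encoder-decoder for 3D tumor segmentation.

The encoder is a 5-level (configurable) hierarchy of *context blocks* —
serial Conv3x3x3 + LeakyReLU + GroupNorm units with an identity residual
path, with per-level depths n = (2, 2, 3, 3, 4). Adjacent levels are linked
by the *adjacent-context* fusion: the shallower level's output is downsampled
and projected to the current width, fused by elementwise summation with the
current context features, and passed through two serial 3x3x3 convolutions.
This builds global correlation layer by layer instead of treating each
resolution in isolation.

Each skip connection carries a gate (channel attention gate by default, a
classical spatial attention gate or no gate as ablation arms) whose semantic
input is the decoder feature of the adjacent deeper level, upsampled to the
skip's resolution. The final prediction fuses the logits of the top three
decoder levels (deep supervision, summation after upsampling) through a
single sigmoid, yielding one probability map per class in [0, 1].
"""

from __future__ import annotations

import numpy as np

from . import nn
from .attention import CAGGate, SpatialAttentionGate, PlainMerge
from .autodiff import Tensor, as_tensor
from .config import NetworkConfig

__all__ = ["ConvUnit", "ContextBlock", "AdjContextFuse", "CAGsNet",
           "build_cagsnet", "network_forward"]


class ConvUnit(nn.Module):
    """One Conv3x3x3 (stride/padding configurable) + LReLU + GN unit."""

    def __init__(self, in_ch: int, out_ch: int, rng, kernel: int = 3,
                 stride: int = 1, gn_groups: int = 8, mu: float = 0.01):
        super().__init__()
        self.conv = nn.Conv3d(in_ch, out_ch, kernel, rng, stride=stride)
        self.norm = nn.GroupNorm(out_ch, gn_groups)
        self.mu = mu

    def __call__(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(x).leaky_relu(self.mu))


class ContextBlock(nn.Module):
    """`depth` serial ConvUnits at constant width with an identity residual
    path around the whole block (1x1x1 projection when widths differ)."""

    def __init__(self, in_ch: int, channels: int, depth: int, rng,
                 gn_groups: int = 8, mu: float = 0.01):
        super().__init__()
        if depth < 1:
            raise ValueError(f"context depth must be >= 1, got {depth}")
        self.units = nn.ModuleList(
            ConvUnit(in_ch if i == 0 else channels, channels, rng,
                     gn_groups=gn_groups, mu=mu)
            for i in range(depth))
        self.proj = (nn.Conv3d(in_ch, channels, 1, rng)
                     if in_ch != channels else None)

    def __call__(self, x: Tensor) -> Tensor:
        x = as_tensor(x)
        out = x
        for unit in self.units:
            out = unit(out)
        skip = self.proj(x) if self.proj is not None else x
        return out + skip


class AdjContextFuse(nn.Module):
    """Link two adjacent encoder levels: downsample + project the shallower
    level's map to the current grid, fuse by summation, then two serial
    3x3x3 convolutions."""

    def __init__(self, prev_ch: int, cur_ch: int, rng,
                 gn_groups: int = 8, mu: float = 0.01):
        super().__init__()
        self.down = nn.Conv3d(prev_ch, cur_ch, 3, rng, stride=2)
        self.post = nn.ModuleList([
            ConvUnit(cur_ch, cur_ch, rng, gn_groups=gn_groups, mu=mu),
            ConvUnit(cur_ch, cur_ch, rng, gn_groups=gn_groups, mu=mu),
        ])

    def __call__(self, prev: Tensor, current: Tensor) -> Tensor:
        prev, current = as_tensor(prev), as_tensor(current)
        want = tuple(2 * s for s in current.shape[1:])
        if tuple(prev.shape[1:]) != want:
            raise ValueError(
                f"adjacent-context fusion expects the shallower map at exactly "
                f"2x resolution: got {tuple(prev.shape[1:])}, "
                f"need {want} for current {tuple(current.shape[1:])}")
        out = self.down(prev) + current
        for unit in self.post:
            out = unit(out)
        return out


def _make_gate(gate_type: str, channels: int, rng, mu: float, merge_mode: str):
    if gate_type == "cag":
        return CAGGate(channels, rng, mu=mu, merge_mode=merge_mode)
    if gate_type == "ag":
        return SpatialAttentionGate(channels, rng, mu=mu, merge_mode=merge_mode)
    return PlainMerge(channels, merge_mode=merge_mode)


class CAGsNet(nn.Module):
    """The full encoder-decoder with gated skips and deep supervision."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self._dropout_rng = np.random.default_rng(
            rng.integers(0, 2 ** 31))  # decoupled from weight init
        ch = config.channel_widths()
        L = config.levels
        g, mu = config.gn_groups, config.mu

        self.stem = nn.Conv3d(config.in_channels, ch[0], 3, rng)
        self.context = nn.ModuleList(
            ContextBlock(ch[k], ch[k], config.context_depths[k], rng,
                         gn_groups=g, mu=mu) for k in range(L))
        if config.downsample == "conv":
            self.down = nn.ModuleList(
                nn.Conv3d(ch[k - 1], ch[k], 3, rng, stride=2) for k in range(1, L))
        else:  # max-pool then 1x1x1 projection
            self.down = nn.ModuleList(
                nn.Conv3d(ch[k - 1], ch[k], 1, rng) for k in range(1, L))
        self.adj = nn.ModuleList(
            AdjContextFuse(ch[k - 1], ch[k], rng, gn_groups=g, mu=mu)
            for k in range(1, L))
        self.drop = nn.ModuleList(
            nn.ChannelDropout(config.dropout_rate, self._dropout_rng)
            for _ in range(L))

        self.upsample = nn.Upsample3d(config.upsample)
        self.up_proj = nn.ModuleList(
            nn.Conv3d(ch[k + 1], ch[k], 1, rng) for k in range(L - 1))
        self.gates = nn.ModuleList(
            _make_gate(config.gate_type, ch[k], rng, mu, config.merge_mode)
            for k in range(L - 1))
        self.dec = nn.ModuleList(
            nn.ModuleList([
                ConvUnit(self.gates[k].out_channels, ch[k], rng,
                         gn_groups=g, mu=mu),
                ConvUnit(ch[k], ch[k], rng, gn_groups=g, mu=mu),
            ]) for k in range(L - 1))

        self.heads = nn.ModuleList(
            nn.Conv3d(ch[k], config.num_classes, 1, rng)
            for k in range(config.deep_supervision))
        for head in self.heads:
            head.bias.data[:] = config.head_bias_init

    # ------------------------------------------------------------------
    def _encode(self, x: Tensor) -> list:
        cfg = self.config
        feats = []
        e = self.drop[0](self.context[0](self.stem(x)))
        feats.append(e)
        for k in range(1, cfg.levels):
            if cfg.downsample == "conv":
                cur = self.down[k - 1](feats[-1])
            else:
                cur = self.down[k - 1](feats[-1].maxpool2())
            ctx = self.context[k](cur)
            fused = self.adj[k - 1](feats[-1], ctx)
            feats.append(self.drop[k](fused))
        return feats

    def _decode(self, feats: list) -> list:
        cfg = self.config
        decs = [None] * cfg.levels
        decs[-1] = feats[-1]
        for k in range(cfg.levels - 2, -1, -1):
            target = tuple(feats[k].shape[1:])
            y = self.up_proj[k](self.upsample(decs[k + 1], target))
            merged = self.gates[k](feats[k], y)
            out = merged
            for unit in self.dec[k]:
                out = unit(out)
            decs[k] = out
        return decs

    def __call__(self, volume, active_heads=None, return_logits: bool = False):
        """Forward pass on a (in_channels, D, H, W) volume; spatial dims must
        be divisible by 2^(levels-1). Returns per-class sigmoid probability
        maps (num_classes, D, H, W); the final logits are the sum of the top
        ``deep_supervision`` decoder heads, shallower-resolution heads
        upsampled to full resolution before summation, sigmoid applied once
        at the end."""
        x = as_tensor(volume)
        cfg = self.config
        if x.shape[0] != cfg.in_channels:
            raise ValueError(
                f"expected {cfg.in_channels} input channels, got {x.shape[0]}")
        div = cfg.spatial_divisor
        bad = [s for s in x.shape[1:] if s % div]
        if bad:
            raise ValueError(
                f"spatial dims {tuple(x.shape[1:])} must be divisible by {div}")
        if active_heads is None:
            active_heads = tuple(range(len(self.heads)))
        feats = self._encode(x)
        decs = self._decode(feats)
        full = tuple(x.shape[1:])
        logits = None
        for k in active_heads:
            head_out = self.heads[k](decs[k])
            head_out = self.upsample(head_out, full)
            logits = head_out if logits is None else logits + head_out
        if return_logits:
            return logits
        return logits.sigmoid()

    def parameter_count(self) -> int:
        return int(sum(p.size for p in self.parameters()))


def build_cagsnet(config: NetworkConfig, seed: int = 0) -> CAGsNet:
    """Deterministically construct the network: same config and seed give
    bit-identical parameters."""
    return CAGsNet(config, seed=seed)


def network_forward(net: CAGsNet, volume: np.ndarray, **kw) -> np.ndarray:
    """Inference convenience: numpy in, numpy probability maps out."""
    from .autodiff import no_grad
    net.eval()
    with no_grad():
        out = net(np.asarray(volume, dtype=np.float32), **kw)
    return out.numpy()
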