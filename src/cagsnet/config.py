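"""Configuration dataclasses and their YAML (de)serialisation.

A single YAML file with ``network:`` and ``training:`` sections fully
describes an experiment; the same dict representation is embedded in
checkpoints so a saved model can be rebuilt without the original file.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

__all__ = ["NetworkConfig", "TrainingConfig", "load_config", "save_config",
           "config_from_dict"]


@dataclass
class NetworkConfig:
    """Architecture hyper-parameters.

    ``context_depths`` gives the number of serial Conv+LReLU+GN units in the
    context block of each resolution level, default (2, 2, 3, 3, 4) from
    shallow to deep. Channel widths double per level from ``base_channels``,
    capped at ``max_channels``.
    """

    in_channels: int = 4
    num_classes: int = 3
    levels: int = 5
    context_depths: tuple = (2, 2, 3, 3, 4)
    base_channels: int = 16
    max_channels: int = 256
    dropout_rate: float = 0.2
    gn_groups: int = 8
    gate_type: str = "cag"          # {cag, ag, none}
    merge_mode: str = "concat"      # {concat, sum}
    mu: float = 0.01                # LReLU leakage
    downsample: str = "conv"        # {conv, pool}
    upsample: str = "trilinear"     # {trilinear, nearest}
    deep_supervision: int = 3       # number of top decoder levels fused
    head_bias_init: float = -2.0    # background-leaning logit bias

    def __post_init__(self):
        self.context_depths = tuple(int(d) for d in self.context_depths)
        if len(self.context_depths) != self.levels:
            raise ValueError(
                f"context_depths has {len(self.context_depths)} entries "
                f"for {self.levels} levels")
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValueError(f"dropout_rate must be in [0,1], got {self.dropout_rate}")
        if self.gate_type not in ("cag", "ag", "none"):
            raise ValueError(f"gate_type must be cag/ag/none, got {self.gate_type!r}")
        if self.merge_mode not in ("concat", "sum"):
            raise ValueError(f"merge_mode must be concat/sum, got {self.merge_mode!r}")
        if self.downsample not in ("conv", "pool"):
            raise ValueError(f"downsample must be conv/pool, got {self.downsample!r}")
        if not 1 <= self.deep_supervision <= self.levels:
            raise ValueError("deep_supervision must be in [1, levels]")
        for c in self.channel_widths():
            g = min(self.gn_groups, c)
            if c % g != 0:
                raise ValueError(
                    f"gn_groups={self.gn_groups} incompatible with width {c}")

    def channel_widths(self) -> list:
        return [min(self.base_channels * 2 ** k, self.max_channels)
                for k in range(self.levels)]

    @property
    def spatial_divisor(self) -> int:
        return 2 ** (self.levels - 1)


@dataclass
class TrainingConfig:
    """Optimisation hyper-parameters.

    The learning rate starts at ``lr0`` and is multiplied by ``decay_rate``
    R each time validation loss fails to improve for ``patience`` epochs
    (plateau mode), or every ``tau`` epochs (periodic mode); either way the
    rate visits exactly the values lr0 * R^k.
    """

    lr0: float = 4e-5
    decay_rate: float = 0.5
    patience: int = 100
    tau: int = 100
    schedule_mode: str = "plateau"  # {plateau, periodic}
    max_epochs: int = 100
    steps_per_epoch: int = 1
    batch_size: int = 1
    betas: tuple = (0.9, 0.999)
    seed: int = 0
    val_fraction: float = 0.2       # 80/20 split
    threshold: float = 0.5          # sigmoid cut at inference
    min_lr: float = 0.0

    def __post_init__(self):
        if not 0.0 < self.decay_rate < 1.0:
            raise ValueError(f"decay_rate must be in (0,1), got {self.decay_rate}")
        if self.lr0 <= 0:
            raise ValueError(f"lr0 must be positive, got {self.lr0}")
        if self.patience < 1:
            raise ValueError(f"patience must be >= 1, got {self.patience}")
        if self.schedule_mode not in ("plateau", "periodic"):
            raise ValueError(f"unknown schedule_mode {self.schedule_mode!r}")
        self.betas = tuple(float(b) for b in self.betas)


def _to_dict(net: NetworkConfig, train: TrainingConfig | None) -> dict:
    out = {"network": asdict(net)}
    out["network"]["context_depths"] = list(net.context_depths)
    if train is not None:
        out["training"] = asdict(train)
        out["training"]["betas"] = list(train.betas)
    return out


def save_config(path, net: NetworkConfig, train: TrainingConfig | None = None):
    Path(path).write_text(yaml.safe_dump(_to_dict(net, train), sort_keys=False))


def load_config(path) -> tuple[NetworkConfig, TrainingConfig]:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> tuple[NetworkConfig, TrainingConfig]:
    net = NetworkConfig(**raw.get("network", {}))
    train = TrainingConfig(**raw.get("training", {}))
    return net, train
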