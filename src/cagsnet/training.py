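"""Training and inference.

Adam at an initial rate of 4e-5 with multiplicative decay (factor R = 0.5)
drives the hybrid GDL+BCE loss. Two decay triggers are available: *plateau*
(default) multiplies the rate by R whenever validation loss has not improved
for `patience` epochs; *periodic* uses lr_t = lr0 * R^floor(t / tau). Either
way the rate visits exactly the geometric sequence lr0 * R^k.

Inference thresholds each class's sigmoid map at 0.5 and resolves overlaps
by nested-region priority (enhancing tumor over necrotic core over edema),
then pastes the labels back onto the native grid through the recorded crop
offset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import metrics as metrics_mod
from .autodiff import Tensor, no_grad
from .backbone import CAGsNet, build_cagsnet
from .config import NetworkConfig, TrainingConfig
from .losses import hybrid_loss
from .nn import Adam
from .preprocessing import PreprocessedCase, one_hot_decode, uncrop

__all__ = [
    "TrainState", "lr_schedule", "fit", "predict", "predict_probabilities",
    "decode_probabilities", "save_checkpoint", "load_checkpoint",
]

# overlap resolution at inference: later labels overwrite earlier ones
_PRIORITY = (2, 1, 4)  # ED < NCR/NET < ET


@dataclass
class TrainState:
    """Mutable schedule/bookkeeping state carried across epochs."""

    epoch: int = 0
    lr: float = 4e-5
    best_val: float = float("inf")
    epochs_since_improve: int = 0
    decay_events: int = 0
    history: list = field(default_factory=list)


def lr_schedule(state: TrainState, config: TrainingConfig,
                val_loss: float | None = None) -> float:
    """Advance the learning-rate schedule by one epoch and return the new
    rate. Plateau mode consumes `val_loss`; periodic mode depends only on
    the epoch counter. Both yield lr = lr0 * R^k after k decay events."""
    if config.schedule_mode == "periodic":
        k = state.epoch // config.tau
        state.decay_events = k
        state.lr = max(config.lr0 * config.decay_rate ** k, config.min_lr)
        return state.lr
    if val_loss is not None:
        if val_loss < state.best_val - 1e-12:
            state.best_val = val_loss
            state.epochs_since_improve = 0
        else:
            state.epochs_since_improve += 1
            if state.epochs_since_improve >= config.patience:
                state.decay_events += 1
                state.epochs_since_improve = 0
    state.lr = max(config.lr0 * config.decay_rate ** state.decay_events,
                   config.min_lr)
    return state.lr


def decode_probabilities(probs: np.ndarray, classes=(1, 2, 4),
                         threshold: float = 0.5) -> np.ndarray:
    """Threshold per-class sigmoid maps and resolve overlaps by nested
    priority: ET (4) beats NCR/NET (1) beats ED (2)."""
    probs = np.asarray(probs)
    classes = tuple(classes)
    order = [c for c in _PRIORITY if c in classes]
    order += [c for c in sorted(classes) if c not in order]
    labels = np.zeros(probs.shape[1:], dtype=np.int16)
    for c in order:
        labels[probs[classes.index(c)] > threshold] = c
    return labels


def _case_dsc(net: CAGsNet, case: PreprocessedCase, threshold: float) -> dict:
    """Per-region DSC of the thresholded prediction on the crop grid."""
    net.eval()
    with no_grad():
        probs = net(case.image).numpy()
    pred = decode_probabilities(probs, case.classes, threshold)
    truth = one_hot_decode(case.onehot, case.classes)
    out = {}
    pred_regions = metrics_mod.region_masks(pred)
    truth_regions = metrics_mod.region_masks(truth)
    for region in metrics_mod.REGIONS:
        c = metrics_mod.confusion_counts(pred_regions[region],
                                         truth_regions[region])
        out[region] = metrics_mod.overlap_metrics(c)[0]
    return out


def fit(cases: list, net_config: NetworkConfig, train_config: TrainingConfig,
        checkpoint_path=None, target_dsc: float | None = None,
        dsc_every: int = 5, log=None) -> tuple[CAGsNet, TrainState]:
    """Train a network on preprocessed cases.

    A single case trains and validates on itself (the overfit regime);
    otherwise cases are split train/validation by `val_fraction` under the
    config seed. Stops at `max_epochs`, or earlier when `target_dsc` is
    reached on every region of the validation set. A NaN loss aborts,
    restoring the best parameters seen so far. Returns the trained network
    (best-validation weights) and the final state with per-epoch history."""
    if not cases:
        raise ValueError("fit() needs at least one case")
    cfg = train_config
    rng = np.random.default_rng(cfg.seed)
    if len(cases) == 1:
        train_cases = val_cases = list(cases)
    else:
        idx = rng.permutation(len(cases))
        n_val = max(1, int(round(cfg.val_fraction * len(cases))))
        val_cases = [cases[i] for i in idx[:n_val]]
        train_cases = [cases[i] for i in idx[n_val:]] or val_cases

    net = build_cagsnet(net_config, seed=cfg.seed)
    opt = Adam(net.parameters(), lr=cfg.lr0, betas=cfg.betas)
    state = TrainState(lr=cfg.lr0)
    best_state_dict = net.state_dict()

    for epoch in range(cfg.max_epochs):
        state.epoch = epoch
        net.train()
        order = rng.permutation(len(train_cases))
        train_losses, train_bces, train_gdls = [], [], []
        for i in order:
            case = train_cases[i]
            probs = net(case.image)
            loss = hybrid_loss(probs, Tensor(case.onehot.astype(np.float32)))
            value = float(loss.value.data)
            if not np.isfinite(value):
                net.load_state_dict(best_state_dict)
                raise FloatingPointError(
                    f"loss diverged (got {value}) at epoch {epoch}; "
                    "best checkpoint restored")
            opt.zero_grad()
            loss.value.backward()
            opt.step()
            train_losses.append(value)
            train_bces.append(float(loss.bce.data))
            train_gdls.append(float(loss.gdl.data))

        net.eval()
        with no_grad():
            val_losses = []
            for case in val_cases:
                probs = net(case.image)
                val_losses.append(float(hybrid_loss(
                    probs, Tensor(case.onehot.astype(np.float32))).value.data))
        val_loss = float(np.mean(val_losses))

        record = {
            "epoch": epoch, "lr": state.lr,
            "train_loss": float(np.mean(train_losses)),
            "train_bce": float(np.mean(train_bces)),
            "train_gdl": float(np.mean(train_gdls)),
            "val_loss": val_loss,
        }
        improved = val_loss < min(
            (h["val_loss"] for h in state.history), default=float("inf"))
        if improved:
            best_state_dict = net.state_dict()
            if checkpoint_path is not None:
                save_checkpoint(checkpoint_path, net, net_config,
                                extra={"epoch": epoch, "val_loss": val_loss})

        check_dsc = (target_dsc is not None
                     and (epoch % dsc_every == dsc_every - 1
                          or epoch == cfg.max_epochs - 1))
        if check_dsc:
            dscs = [_case_dsc(net, case, cfg.threshold) for case in val_cases]
            mean_dsc = {r: float(np.mean([d[r] for d in dscs]))
                        for r in metrics_mod.REGIONS}
            record["val_dsc"] = mean_dsc
        state.history.append(record)
        if log is not None:
            log(record)
        lr_schedule(state, cfg, val_loss=val_loss)
        opt.lr = state.lr
        if check_dsc and all(v > target_dsc for v in record["val_dsc"].values()):
            break

    net.load_state_dict(best_state_dict)
    if checkpoint_path is not None and not Path(checkpoint_path).exists():
        save_checkpoint(checkpoint_path, net, net_config,
                        extra={"epoch": state.epoch})
    return net, state


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, net: CAGsNet, net_config: NetworkConfig,
                    extra: dict | None = None):
    """Single-file checkpoint (.npz) with the architecture config embedded."""
    from dataclasses import asdict

    cfg = asdict(net_config)
    cfg["context_depths"] = list(net_config.context_depths)
    meta = json.dumps({"network": cfg, "extra": extra or {}})
    arrays = {f"param/{k}": v for k, v in net.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> tuple[CAGsNet, NetworkConfig, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("param/"):]: data[k] for k in data.files
                 if k.startswith("param/")}
    net_config = NetworkConfig(**meta["network"])
    net = build_cagsnet(net_config, seed=0)
    net.load_state_dict(state)
    net.eval()
    return net, net_config, meta.get("extra", {})


# ---------------------------------------------------------------------------
# Inference
# ---------------------------------------------------------------------------

def predict_probabilities(net: CAGsNet, case: PreprocessedCase) -> np.ndarray:
    net.eval()
    with no_grad():
        return net(case.image).numpy()


def predict(net: CAGsNet, case: PreprocessedCase, threshold: float = 0.5,
            classes=(1, 2, 4)) -> np.ndarray:
    """Segment one preprocessed case and return integer labels on the
    *native* grid (crop inverted through the stored offset)."""
    if net.config.in_channels != case.image.shape[0]:
        raise ValueError(
            f"checkpoint expects {net.config.in_channels} input channels, "
            f"case has {case.image.shape[0]}")
    probs = predict_probabilities(net, case)
    labels = decode_probabilities(probs, classes=classes, threshold=threshold)
    return uncrop(labels, case.crop_offset, case.native_shape)
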