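"""Hybrid segmentation loss: binary cross-entropy + generalized Dice.

Predictions ``P`` are per-class sigmoid maps in [0, 1]; targets ``T`` are the
matching one-hot binary maps (class channel first, any spatial layout — both
are flattened to M x N internally).

The generalized Dice loss weights each class by the inverse square of its
voxel count, w_j = 1 / (sum_i T_ij)^2, so small structures (enhancing tumor,
necrotic core) contribute on equal footing with bulky ones (edema); BCE keeps
per-voxel calibration so the Dice term is not biased toward large regions.
The training loss is their unweighted sum.

Functions accept numpy arrays (returning floats) or autodiff Tensors
(returning Tensors, for training). Class counts derive from the ground truth
only, so they are constants on the gradient tape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor

__all__ = ["LossValue", "bce_loss", "gdl_weights", "gdl_loss", "hybrid_loss"]

_EPS_CLAMP = 1e-7    # probability clamp for the log terms
_EPS_COUNT = 1e-5    # stabiliser added to class voxel counts


@dataclass
class LossValue:
    """Total loss and its two components (floats, or Tensors in training)."""

    value: object
    bce: object
    gdl: object


def _pair(P, T):
    was_numpy = not isinstance(P, Tensor)
    Pt, Tt = as_tensor(P), as_tensor(T)
    if Pt.shape != Tt.shape:
        raise ValueError(
            f"prediction shape {tuple(Pt.shape)} != target shape {tuple(Tt.shape)}")
    return Pt, Tt, was_numpy


def bce_loss(P, T):
    """Mean binary cross-entropy over all class-voxel entries, with P clamped
    to [1e-7, 1 - 1e-7] before the logs."""
    Pt, Tt, was_numpy = _pair(P, T)
    Pc = Pt.clip(_EPS_CLAMP, 1.0 - _EPS_CLAMP)
    loss = -(Tt * Pc.log() + (1.0 - Tt) * (1.0 - Pc).log()).mean()
    return loss.item() if was_numpy else loss


def gdl_weights(T) -> np.ndarray:
    """Inverse-square class weights w_j = 1 / (count_j + eps)^2; the eps keeps
    empty classes finite."""
    T = T.numpy() if isinstance(T, Tensor) else np.asarray(T)
    counts = T.reshape(T.shape[0], -1).sum(axis=1).astype(np.float64)
    return (1.0 / (counts + _EPS_COUNT) ** 2).astype(np.float32)


def gdl_loss(P, T):
    """Generalized Dice loss, in [0, 1]; 0 at perfect overlap, 1 at a
    complete miss. All-empty truth with an all-zero prediction returns 0."""
    Pt, Tt, was_numpy = _pair(P, T)
    m = Pt.shape[0]
    Pf, Tf = Pt.reshape(m, -1), Tt.reshape(m, -1)
    w = Tensor(gdl_weights(Tf))  # constant w.r.t. the prediction
    inter = (Pf * Tf).sum(axis=1)
    total = (Pf + Tf).sum(axis=1)
    num = (w * inter).sum()
    den = (w * total).sum()
    if float(den.data) == 0.0:
        return 0.0 if was_numpy else Tensor(0.0)
    loss = 1.0 - 2.0 * num * den.pow(-1.0)
    return loss.item() if was_numpy else loss


def hybrid_loss(P, T) -> LossValue:
    """L = L_gdl + L_bce, both components reported."""
    bce = bce_loss(P, T)
    gdl = gdl_loss(P, T)
    return LossValue(value=bce + gdl, bce=bce, gdl=gdl)
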