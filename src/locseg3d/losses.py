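"""Training objectives: soft dice, binary cross-entropy, their sum, and
multi-class soft dice.

Two dice variants are provided. The ``factor2`` variant is the
conventional soft dice, ``1 - 2*|y.p| / (|y| + |p|)``, whose minimum is 0
at a perfect prediction. The ``printed`` variant omits the factor of two
in the numerator, so a perfect hard prediction scores 0.5; it is kept as
an option (`loss_variant` in the config) because some formulations write
the loss this way. A smoothing constant is added to numerator and
denominator so empty masks are well defined.

All losses accept numpy arrays or autodiff :class:`~locseg3d.nn.Tensor`
inputs; with tensors, the returned :class:`LossValue` carries the scalar
graph node so gradients can be propagated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import Tensor, as_tensor

__all__ = [
    "LossValue",
    "dice_loss",
    "bce_loss",
    "bce_dice_loss",
    "multiclass_dice_loss",
]

DICE_SMOOTH = 1.0
BCE_CLIP = 1e-7


@dataclass
class LossValue:
    """A scalar loss plus its named components.

    For combined losses, ``value`` equals the sum of ``components``.
    """

    value: float
    components: dict[str, float] = field(default_factory=dict)
    tensor: Tensor | None = None

    def backward(self) -> None:
        if self.tensor is None:
            raise ValueError("loss was computed without gradient tracking")
        self.tensor.backward()


def _pair(y, yhat) -> tuple[Tensor, Tensor]:
    ty, tp = as_tensor(y), as_tensor(yhat)
    if ty.shape != tp.shape:
        raise ValueError(f"shape mismatch: y {ty.shape} vs yhat {tp.shape}")
    return ty, tp


def _wrap(t: Tensor, components: dict[str, float] | None = None) -> LossValue:
    return LossValue(
        value=float(t.data),
        components=components or {},
        tensor=t if t.requires_grad else None,
    )


def dice_loss(y, yhat, variant: str = "factor2", smooth: float = DICE_SMOOTH) -> LossValue:
    """Soft dice loss for a binary target.

    ``printed``:  1 - (sum(y*p) + s) / (sum(y) + sum(p) + s)
    ``factor2``:  1 - (2*sum(y*p) + s) / (sum(y) + sum(p) + s)
    """
    ty, tp = _pair(y, yhat)
    num_factor = {"printed": 1.0, "factor2": 2.0}[variant]
    inter = (ty * tp).sum()
    denom = ty.sum() + tp.sum() + smooth
    loss = 1.0 - (inter * num_factor + smooth) / denom
    return _wrap(loss, {"dice": float(loss.data)})


def bce_loss(y, yhat, clip: float = BCE_CLIP) -> LossValue:
    """Binary cross-entropy, mean over voxels, with clipped predictions."""
    ty, tp = _pair(y, yhat)
    tp = tp.clip(clip, 1.0 - clip)
    ll = ty * tp.log() + (1.0 - ty) * (1.0 - tp).log()
    loss = -ll.mean()
    return _wrap(loss, {"bce": float(loss.data)})


def bce_dice_loss(y, yhat, variant: str = "factor2") -> LossValue:
    """Sum of soft dice and BCE; components reported separately."""
    ty, tp = _pair(y, yhat)
    d = dice_loss(ty, tp, variant=variant)
    b = bce_loss(ty, tp)
    total = (d.tensor if d.tensor is not None else as_tensor(d.value)) + (
        b.tensor if b.tensor is not None else as_tensor(b.value)
    )
    return _wrap(total, {"dice": d.value, "bce": b.value})


def multiclass_dice_loss(
    y,
    yhat,
    variant: str = "factor2",
    smooth: float = DICE_SMOOTH,
    simplex_tol: float = 1e-4,
) -> LossValue:
    """Multi-class soft dice: per-class dice terms averaged over classes.

    `y` is one-hot and `yhat` a per-voxel probability simplex, both with
    the class axis first (or second when a batch axis is present, i.e.
    ``(N, K, Z, Y, X)``).
    """
    ty, tp = _pair(y, yhat)
    class_axis = 1 if ty.ndim == 5 else 0
    k = ty.shape[class_axis]
    colsum = tp.data.sum(axis=class_axis)
    if np.abs(colsum - 1.0).max() > simplex_tol:
        raise ValueError("yhat is not a per-voxel probability simplex")
    num_factor = {"printed": 1.0, "factor2": 2.0}[variant]
    axes = tuple(i for i in range(ty.ndim) if i != class_axis)
    inter = (ty * tp).sum(axis=axes)
    denom = ty.sum(axis=axes) + tp.sum(axis=axes) + smooth
    terms = (inter * num_factor + smooth) / denom  # per-class dice scores
    loss = 1.0 - terms.sum() * (1.0 / k)
    comps = {f"dice_class_{i}": float(terms.data[i]) for i in range(k)}
    return _wrap(loss, comps)
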