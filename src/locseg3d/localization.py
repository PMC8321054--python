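"""Gradient-weighted class-activation localization and ROI cropping.

The localizer network produces final decoder feature maps ``x_k``. For a
target class ``c`` with scalar score ``S_c`` the gradient-weighted class
activation map is

    GCAM_c = ReLU( sum_k x_k * dS_c / dx_k )

i.e. each channel is weighted element-wise by the gradient of the score
with respect to it, the channels are summed, and the result rectified.
For a dense (segmentation-style) localizer, ``S_c`` is taken as the sum
of the class-c pre-activation outputs over all voxels, the standard
dense-prediction extension of a classification score.

The resulting density map is turned into a fixed-size axis-aligned box
in full-resolution index space: the intensity-weighted centroid of the
above-threshold region is rescaled from density-map coordinates, a box
of the configured crop shape is centred there and shifted to lie inside
the volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .io import LabelVolume, Volume
from .nn import Tensor

__all__ = [
    "DensityMap",
    "ROIBox",
    "NoLocalizationError",
    "gcam",
    "density_to_roi",
    "crop",
    "uncrop",
    "derive_crop_shape",
]


class NoLocalizationError(RuntimeError):
    """Raised when a density map contains no positive evidence."""


@dataclass
class DensityMap:
    """Non-negative 3D activation grid at localizer (low) resolution."""

    data: np.ndarray
    source_shape: tuple[int, int, int]  # full-resolution shape it maps onto

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("density map must be 3D")
        if (self.data < 0).any():
            raise ValueError("density map must be non-negative (post-ReLU)")
        self.source_shape = tuple(int(s) for s in self.source_shape)


@dataclass(frozen=True)
class ROIBox:
    """Half-open axis-aligned box [start, start+shape) in full-resolution space."""

    start: tuple[int, int, int]
    shape: tuple[int, int, int]

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(s, s + n) for s, n in zip(self.start, self.shape))

    def to_dict(self) -> dict:
        return {"start": list(self.start), "shape": list(self.shape)}


def gcam(features: Tensor, class_score_fn: Callable[[Tensor], Tensor]) -> np.ndarray:
    """Compute the gradient-weighted class activation map.

    Parameters
    ----------
    features : Tensor, shape (N, K, Z, Y, X) or (K, Z, Y, X)
        Feature maps; must participate in the autodiff graph.
    class_score_fn : callable
        Maps `features` to a scalar class score tensor.

    Returns
    -------
    ndarray
        ReLU of the channel-sum of gradient-weighted feature maps, one
        grid per batch element (leading batch axis dropped when absent).
    """
    if not features.requires_grad:
        raise ValueError(
            "features do not track gradients; build them with requires_grad "
            "(run the network on a gradient-enabled input)"
        )
    score = class_score_fn(features)
    if score.data.size != 1:
        raise ValueError("class score must be a scalar")
    features.grad = None
    score.backward()
    if features.grad is None:
        raise ValueError("no gradient reached the feature maps")
    channel_axis = 1 if features.ndim == 5 else 0
    weighted = (features.data * features.grad).sum(axis=channel_axis)
    return np.maximum(weighted, 0.0)


def _weighted_centroid(d: np.ndarray, threshold_frac: float) -> np.ndarray:
    peak = float(d.max())
    mask = d >= threshold_frac * peak
    w = np.where(mask, d, 0.0)
    total = w.sum()
    idx = np.indices(d.shape, dtype=np.float64)
    return np.array([(idx[a] * w).sum() / total for a in range(3)])


def density_to_roi(
    d: DensityMap,
    crop_shape: tuple[int, int, int],
    threshold_frac: float = 0.5,
) -> ROIBox:
    """Place a fixed-size box around the density's weighted centroid.

    The centroid of voxels at or above ``threshold_frac * max`` is
    rescaled to full-resolution coordinates; the box is clipped to lie
    inside the volume. Axes where the volume is smaller than the crop
    cover the whole axis (the crop is zero-padded downstream).
    """
    if not 0 < threshold_frac < 1:
        raise ValueError("threshold_frac must be in (0, 1)")
    if float(d.data.max()) <= 0:
        raise NoLocalizationError("density map is identically zero")
    centroid_low = _weighted_centroid(d.data, threshold_frac)
    scale = np.array(d.source_shape, dtype=np.float64) / np.array(d.data.shape)
    # centre of the low-res voxel, mapped to full resolution
    centroid = (centroid_low + 0.5) * scale - 0.5
    start = []
    shape = []
    for c, n, full in zip(centroid, crop_shape, d.source_shape):
        if n >= full:
            start.append(0)
            shape.append(full)
            continue
        s = int(round(c - n / 2.0))
        s = max(0, min(s, full - n))
        start.append(s)
        shape.append(n)
    return ROIBox(tuple(start), tuple(shape))


def crop(v: Volume | LabelVolume, box: ROIBox) -> Volume | LabelVolume:
    """Extract the box from a volume; spacing is unchanged."""
    for s, n, full in zip(box.start, box.shape, v.shape):
        if s < 0 or s + n > full:
            raise ValueError(f"box {box} does not fit inside volume of shape {v.shape}")
    return v.with_data(np.ascontiguousarray(v.data[box.slices()]))


def uncrop(
    seg: LabelVolume | np.ndarray,
    box: ROIBox,
    full_shape: tuple[int, int, int],
) -> LabelVolume | np.ndarray:
    """Place a cropped segmentation back into the full grid (background outside)."""
    data = seg.data if isinstance(seg, LabelVolume) else np.asarray(seg)
    if tuple(data.shape) != tuple(box.shape):
        raise ValueError(f"segmentation shape {data.shape} != box shape {box.shape}")
    full = np.zeros(tuple(full_shape), dtype=data.dtype)
    full[box.slices()] = data
    if isinstance(seg, LabelVolume):
        return seg.with_data(full)
    return full


def derive_crop_shape(
    labels: list[LabelVolume],
    margin: int = 10,
    divisors: tuple[int, int, int] = (8, 8, 8),
    max_shape: tuple[int, int, int] | None = None,
) -> tuple[int, int, int]:
    """Fixed crop size from training labels.

    Per axis: the maximum foreground bounding-box extent over the
    training split, plus a margin, rounded up to pooling divisibility
    and clipped to the (divisibility-respecting) volume extent.
    """
    if not labels:
        raise ValueError("need at least one label volume")
    extents = np.zeros(3, dtype=int)
    for lv in labels:
        fg = np.asarray(lv.data) > 0
        if not fg.any():
            continue
        for a in range(3):
            proj = fg.any(axis=tuple(i for i in range(3) if i != a))
            nz = np.flatnonzero(proj)
            extents[a] = max(extents[a], nz[-1] - nz[0] + 1)
    if not extents.any():
        raise ValueError("no foreground in any training label")
    shape = []
    vol_shape = max_shape or labels[0].shape
    for ext, d, full in zip(extents, divisors, vol_shape):
        n = int(ext) + margin
        n = ((n + d - 1) // d) * d
        n = min(n, (full // d) * d)
        shape.append(max(n, d))
    return tuple(shape)
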