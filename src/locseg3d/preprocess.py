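"""Preprocessing chain for cardiac MR volumes.

The chain applied before training/inference is: optional slice-wise
contrast-limited adaptive histogram equalisation (CLAHE), per-volume
z-normalisation against the volume's own mean and standard deviation,
optional resampling to a common voxel spacing, and zero-padding /
center-cropping to the fixed network input shape. The localizer
additionally receives an in-plane (optionally also through-plane)
downsampled copy.

Every geometric step records enough information to map predictions back
to the original geometry exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure

from .io import LabelVolume, Volume

__all__ = [
    "clahe_slicewise",
    "znormalize",
    "resample_to_spacing",
    "pad_or_crop",
    "PadCropRecord",
    "downsample_for_localizer",
]


def clahe_slicewise(
    v: Volume, clip_limit: float = 0.03, tiles: tuple[int, int] = (8, 8)
) -> Volume:
    """Apply 2D CLAHE independently to each z-slice.

    Slices are rescaled to [0, 1] before equalisation and restored to
    their original intensity range afterwards; a slice with zero dynamic
    range is returned unchanged.
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    out = np.empty_like(np.asarray(v.data, dtype=np.float32))
    for z in range(v.shape[0]):
        sl = np.asarray(v.data[z], dtype=np.float32)
        lo, hi = float(sl.min()), float(sl.max())
        if hi - lo <= 0:
            out[z] = sl
            continue
        norm = (sl - lo) / (hi - lo)
        ny = max(1, sl.shape[0] // tiles[0])
        nx = max(1, sl.shape[1] // tiles[1])
        eq = exposure.equalize_adapthist(
            norm, kernel_size=(ny, nx), clip_limit=clip_limit
        )
        out[z] = eq * (hi - lo) + lo
    return v.with_data(out)


def znormalize(v: Volume, eps: float = 1e-8) -> Volume:
    """Normalise a volume to zero mean, unit standard deviation.

    A constant volume maps to all zeros (epsilon-guarded denominator).
    """
    data = np.asarray(v.data, dtype=np.float32)
    sd = float(data.std())
    if sd < eps:
        return v.with_data(np.zeros_like(data))
    return v.with_data((data - data.mean()) / sd)


def _target_shape(shape, spacing, target_spacing) -> tuple[int, ...]:
    return tuple(
        max(1, int(round(n * s / t)))
        for n, s, t in zip(shape, spacing, target_spacing)
    )


def resample_to_spacing(
    v: Volume | LabelVolume,
    target_spacing: tuple[float, float, float],
    interp: str | None = None,
) -> Volume | LabelVolume:
    """Resample to a new voxel spacing.

    Output shape is ``round(shape * spacing / target)`` per axis (at
    least 1). Intensities use linear interpolation, labels nearest-
    neighbour, unless `interp` overrides.
    """
    if any(t <= 0 for t in target_spacing):
        raise ValueError("target spacing must be positive")
    is_label = isinstance(v, LabelVolume)
    if interp is None:
        interp = "nearest" if is_label else "linear"
    order = 0 if interp == "nearest" else 1
    out_shape = _target_shape(v.shape, v.spacing, target_spacing)
    if min(out_shape) < 1:
        raise ValueError("target spacing would produce an empty grid")
    if tuple(out_shape) == tuple(v.shape) and interp == "nearest":
        return v.with_data(v.data.copy(), spacing=tuple(target_spacing))
    zoom = [o / n for o, n in zip(out_shape, v.shape)]
    data = ndimage.zoom(
        np.asarray(v.data, dtype=np.float32), zoom, order=order,
        mode="grid-constant", grid_mode=True,
    )
    assert data.shape == tuple(out_shape)
    if is_label:
        data = np.round(data).astype(v.data.dtype)
    return v.with_data(data, spacing=tuple(float(t) for t in target_spacing))


@dataclass
class PadCropRecord:
    """Inverse mapping for :func:`pad_or_crop`."""

    original_shape: tuple[int, int, int]
    pad_low: tuple[int, int, int]   # zeros added at the low-index side
    crop_low: tuple[int, int, int]  # voxels removed at the low-index side

    def restore(self, data: np.ndarray, fill=0) -> np.ndarray:
        """Map an array in padded/cropped geometry back to the original."""
        out = data
        # undo padding: slice out the retained region
        sl = tuple(
            slice(p, p + min(n, data.shape[i] - p))
            for i, (p, n) in enumerate(zip(self.pad_low, self.original_shape))
        )
        out = out[sl]
        # undo cropping: re-embed into the original extent
        full = np.full(self.original_shape, fill, dtype=data.dtype)
        dst = tuple(
            slice(c, c + s) for c, s in zip(self.crop_low, out.shape)
        )
        full[dst] = out
        return full


def pad_or_crop(
    v: Volume | LabelVolume,
    target_shape: tuple[int, int, int],
    fill: float = 0.0,
) -> tuple[Volume | LabelVolume, PadCropRecord]:
    """Symmetrically zero-pad or center-crop each axis to `target_shape`.

    Odd pad/crop remainders go to the high-index side. Returns the
    transformed volume and the record needed to invert the operation.
    """
    if any(t <= 0 for t in target_shape):
        raise ValueError("target shape must be positive")
    data = np.asarray(v.data)
    pad_low, pad_high, crop_low = [], [], []
    for n, t in zip(data.shape, target_shape):
        if t >= n:
            extra = t - n
            pad_low.append(extra // 2)
            pad_high.append(extra - extra // 2)
            crop_low.append(0)
        else:
            extra = n - t
            pad_low.append(0)
            pad_high.append(0)
            crop_low.append(extra // 2)
    sl = tuple(
        slice(c, c + min(t, n)) for c, t, n in zip(crop_low, target_shape, data.shape)
    )
    out = data[sl]
    out = np.pad(
        out,
        tuple(zip(pad_low, pad_high)),
        mode="constant",
        constant_values=fill,
    )
    rec = PadCropRecord(tuple(data.shape), tuple(pad_low), tuple(crop_low))
    return v.with_data(out), rec


def downsample_for_localizer(
    v: Volume | LabelVolume,
    factor: tuple[int, int, int],
    keep_z: bool = False,
) -> Volume | LabelVolume:
    """Integer-factor reduction for the low-resolution localizer input.

    Images are reduced by block averaging (box anti-aliasing), labels by
    strided nearest-neighbour sampling. With `keep_z` the through-plane
    factor is forced to 1. Output shape is ``ceil(shape / factor)``.
    """
    factor = tuple(int(f) for f in factor)
    if any(f < 1 for f in factor):
        raise ValueError(f"downsampling factors must be >= 1, got {factor}")
    if keep_z:
        factor = (1,) + factor[1:]
    is_label = isinstance(v, LabelVolume)
    data = np.asarray(v.data)
    if is_label:
        out = data[:: factor[0], :: factor[1], :: factor[2]].copy()
    else:
        data = np.asarray(data, dtype=np.float32)
        pads = [(-n) % f for n, f in zip(data.shape, factor)]
        if any(pads):
            data = np.pad(data, tuple((0, p) for p in pads), mode="edge")
        z, y, x = data.shape
        fz, fy, fx = factor
        out = (
            data.reshape(z // fz, fz, y // fy, fy, x // fx, fx)
            .mean(axis=(1, 3, 5))
            .astype(np.float32)
        )
    new_spacing = tuple(s * f for s, f in zip(v.spacing, factor))
    return v.with_data(out, spacing=new_spacing)
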