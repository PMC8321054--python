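"""Volume containers and NIfTI/NRRD input/output.

In-memory convention: arrays are indexed ``(z, y, x)`` with ``z`` the
slice (through-plane) axis, spacing is ``(sz, sy, sx)`` in millimetres,
and indices are 0-based. Files are read with nibabel (NIfTI) or
SimpleITK (NRRD); both loaders normalise to this axis order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import SimpleITK as sitk

__all__ = [
    "Volume",
    "LabelVolume",
    "read_volume",
    "read_labelvolume",
    "write_volume",
    "write_labelvolume",
]


@dataclass
class Volume:
    """A 3D intensity grid with physical voxel spacing.

    Attributes
    ----------
    data : ndarray, shape (Z, Y, X)
        Real-valued intensities.
    spacing : tuple (sz, sy, sx)
        Voxel edge lengths in mm, all strictly positive.
    origin : tuple
        Physical position of voxel (0, 0, 0) in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.isfinite(self.data).all():
            raise ValueError("volume data contains NaN or Inf")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray, spacing=None) -> "Volume":
        return replace(self, data=data, spacing=spacing or self.spacing)


@dataclass
class LabelVolume:
    """Integer label grid aligned with a :class:`Volume`.

    Values lie in ``{0..K}`` where 0 is background and ``class_names``
    names the K foreground structures in label order.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    class_names: list[str] = field(default_factory=lambda: ["structure"])

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.data.ndim}")
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.allclose(self.data, np.round(self.data)):
                self.data = self.data.astype(np.int16)
            else:
                raise ValueError("label data must be integer-valued")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        k = len(self.class_names)
        vals = np.unique(self.data)
        if vals.size and (vals.min() < 0 or vals.max() > k):
            raise ValueError(
                f"label values {vals} outside {{0..{k}}} for {k} named classes"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def num_classes(self) -> int:
        return len(self.class_names)

    def with_data(self, data: np.ndarray, spacing=None) -> "LabelVolume":
        return replace(self, data=data, spacing=spacing or self.spacing)


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def _read_raw(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        # nibabel data axes are (x, y, z); reorder to (z, y, x)
        data = np.asarray(img.dataobj).transpose(2, 1, 0)
        zooms = img.header.get_zooms()[:3]
        if any(z == 0 for z in zooms):
            raise ValueError(f"{path}: zero voxel spacing in NIfTI header 'pixdim'")
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
        origin = tuple(float(v) for v in img.affine[:3, 3][::-1])
    elif path.name.lower().endswith(".nrrd"):
        img = sitk.ReadImage(str(path))
        data = sitk.GetArrayFromImage(img)  # already (z, y, x)
        sp = img.GetSpacing()  # (x, y, z)
        if any(s == 0 for s in sp):
            raise ValueError(f"{path}: zero voxel spacing in NRRD header 'space directions'")
        spacing = (float(sp[2]), float(sp[1]), float(sp[0]))
        origin = tuple(float(v) for v in img.GetOrigin()[::-1])
    else:
        raise ValueError(f"unrecognised volume format: {path.name}")
    return data, spacing, origin


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI or NRRD volume into the (z, y, x) convention."""
    data, spacing, origin = _read_raw(path)
    return Volume(np.asarray(data, dtype=np.float32), spacing, origin)


def read_labelvolume(path: str | Path, class_names: list[str] | None = None) -> LabelVolume:
    data, spacing, origin = _read_raw(path)
    data = np.asarray(data)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"{path}: label volume has non-integer values")
        data = np.round(data).astype(np.int16)
    if class_names is None:
        k = int(data.max()) if data.size else 0
        class_names = [f"structure_{i}" for i in range(1, max(k, 1) + 1)]
    return LabelVolume(data, spacing, origin, class_names)


def _write_raw(data: np.ndarray, spacing, origin, path: Path) -> None:
    if not path.parent.exists():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    if _is_nifti(path):
        affine = np.diag([spacing[2], spacing[1], spacing[0], 1.0])
        affine[:3, 3] = origin[::-1]
        img = nib.Nifti1Image(np.ascontiguousarray(data.transpose(2, 1, 0)), affine)
        img.header.set_zooms((spacing[2], spacing[1], spacing[0]))
        nib.save(img, str(path))
    elif path.name.lower().endswith(".nrrd"):
        img = sitk.GetImageFromArray(np.ascontiguousarray(data))
        img.SetSpacing((spacing[2], spacing[1], spacing[0]))
        img.SetOrigin(tuple(origin[::-1]))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unrecognised volume format: {path.name}")


def write_volume(v: Volume, path: str | Path) -> Path:
    path = Path(path)
    _write_raw(np.asarray(v.data, dtype=np.float32), v.spacing, v.origin, path)
    return path


def write_labelvolume(lv: LabelVolume, path: str | Path) -> Path:
    """Write labels with an integer dtype so they round-trip bit-exactly."""
    if not np.issubdtype(np.asarray(lv.data).dtype, np.integer):
        raise ValueError("label data must be integer")
    path = Path(path)
    _write_raw(np.asarray(lv.data, dtype=np.int16), lv.spacing, lv.origin, path)
    return path
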