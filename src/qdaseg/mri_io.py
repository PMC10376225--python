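"""NIfTI volume I/O and 3D volume <-> ordered 2D slice-stack conversion.

The pipeline operates slice-wise on single-channel grayscale volumes
(BraTS-style 240x240x155 grids).  Conventions: 0-based (row, col, slice)
indexing, the axial plane is the first two axes of the stored array, world
coordinates only through the affine.  Intensities are always handled as
floating point in memory regardless of on-disk dtype; masks are written as
unsigned 8-bit 0/1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "Slice",
    "PLANES",
    "load_volume",
    "save_volume",
    "save_mask",
    "load_mask",
    "volume_to_slices",
    "slices_to_volume",
    "export_slice_png",
]

#: plane name -> axis whose index enumerates the slices
PLANES = {"axial": 2, "coronal": 1, "sagittal": 0}


@dataclass
class Volume:
    """3D grayscale image with physical spacing and a voxel->world affine."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"Volume requires a 3D array, got shape {self.data.shape}"
            )
        if any(n <= 0 for n in self.data.shape):
            raise ValueError(f"Volume dimensions must be positive: {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing entries must be > 0: {self.spacing}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume intensities must be finite")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class Slice:
    """2D grayscale slice with in-plane spacing and its index in the stack."""

    data: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError(f"Slice requires a 2D array, got shape {self.data.shape}")
        if any(n <= 0 for n in self.data.shape):
            raise ValueError(f"Slice dimensions must be positive: {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Slice intensities must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)


def load_volume(path: str | Path) -> Volume:
    """Read a single-channel 3D NIfTI volume.

    Raises ``FileNotFoundError`` for missing files and ``ValueError`` for
    images that are not plain 3D single-channel grids (naming the shape).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(
            f"unsupported image: expected a 3D single-channel volume, "
            f"got shape {data.shape}"
        )
    zooms = img.header.get_zooms()[:3]
    return Volume(data=data.astype(np.float64), spacing=tuple(zooms), affine=img.affine)


def save_volume(path: str | Path, vol: Volume) -> None:
    """Write a volume as float64 NIfTI, preserving spacing and affine."""
    img = nib.Nifti1Image(vol.data.astype(np.float64), vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def save_mask(path: str | Path, mask: np.ndarray, template: Volume) -> None:
    """Write a boolean mask as a 0/1 uint8 NIfTI with the template's affine."""
    mask = np.asarray(mask)
    if mask.shape != template.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match template {template.shape}"
        )
    img = nib.Nifti1Image(mask.astype(np.uint8), template.affine)
    img.header.set_zooms(template.spacing)
    nib.save(img, str(path))


def load_mask(path: str | Path) -> np.ndarray:
    """Read a mask NIfTI back as a boolean array."""
    img = nib.load(str(Path(path)))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"unsupported mask image of shape {data.shape}")
    return data > 0


def _inplane_spacing(spacing: Sequence[float], axis: int) -> tuple[float, float]:
    keep = [spacing[a] for a in range(3) if a != axis]
    return (keep[0], keep[1])


def volume_to_slices(vol: Volume, plane: str = "axial") -> list[Slice]:
    """Split a volume into an ordered stack of 2D slices along a plane."""
    if plane not in PLANES:
        raise ValueError(f"unknown plane {plane!r}; expected one of {sorted(PLANES)}")
    axis = PLANES[plane]
    spacing = _inplane_spacing(vol.spacing, axis)
    out = []
    for k in range(vol.shape[axis]):
        plane_data = np.take(vol.data, k, axis=axis)
        out.append(Slice(data=plane_data.copy(), spacing=spacing, index=k))
    return out


def slices_to_volume(
    slices: Sequence[Slice | np.ndarray],
    template: Volume,
    plane: str = "axial",
) -> Volume:
    """Restack ordered slices (or raw 2D arrays) into a volume.

    The result takes its spacing and affine from ``template``; shape and
    count must match the template along the chosen plane.
    """
    if plane not in PLANES:
        raise ValueError(f"unknown plane {plane!r}; expected one of {sorted(PLANES)}")
    axis = PLANES[plane]
    arrays = [s.data if isinstance(s, Slice) else np.asarray(s, dtype=np.float64)
              for s in slices]
    if len(arrays) != template.shape[axis]:
        raise ValueError(
            f"slice count {len(arrays)} does not match template axis length "
            f"{template.shape[axis]}"
        )
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError(f"slices disagree in shape: {sorted(shapes)}")
    data = np.stack(arrays, axis=axis)
    if data.shape != template.shape:
        raise ValueError(
            f"restacked shape {data.shape} does not match template {template.shape}"
        )
    return Volume(data=data, spacing=template.spacing, affine=template.affine.copy())


def export_slice_png(path: str | Path, sl: Slice) -> None:
    """Lossy-normalized PNG export for visual inspection only.

    The image is min-max normalized to 8 bits; never read back into the
    pipeline.
    """
    import imageio.v3 as iio

    data = sl.data
    lo, hi = float(data.min()), float(data.max())
    if hi > lo:
        norm = (data - lo) / (hi - lo)
    else:
        norm = np.zeros_like(data)
    iio.imwrite(str(path), (norm * 255).astype(np.uint8))
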