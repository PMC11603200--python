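"""Volumetric stack I/O, voxel geometry and maximum-intensity projections.

Axis order is (z, y, x) everywhere in this package; ``spacing`` follows the
same order and is given in micrometres.  Light-sheet stacks are anisotropic
(the z step is usually coarser than the in-plane pixel size), so the spacing
travels with every volume instead of being an afterthought.

Intensities are treated as arbitrary fluorescence units throughout: no bit
depth or calibration is assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import tifffile


class ChannelRole(str, Enum):
    """What a fluorescence channel images: nanoparticles or tissue."""

    NP = "NP"
    AF = "AF"
    OTHER = "OTHER"


class MaskLabel(str, Enum):
    AIRWAY = "AIRWAY"
    LUNG = "LUNG"
    NP_POSITIVE = "NP_POSITIVE"
    OTHER = "OTHER"


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three positive numbers (z,y,x), got {spacing!r}")
    return spacing


@dataclass
class ImageStack:
    """A 3D scalar fluorescence volume with voxel geometry.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Non-negative, finite intensities in arbitrary units.
    spacing : (float, float, float)
        Voxel size in µm, ordered (z, y, x), strictly positive.
    channel_role : ChannelRole
        NP (nanoparticle fluorescence), AF (tissue autofluorescence) or OTHER.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    channel_role: ChannelRole = ChannelRole.OTHER

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"stack must be 3D, got ndim={self.voxels.ndim}")
        if not np.issubdtype(self.voxels.dtype, np.number):
            raise TypeError("stack must be numeric")
        if np.issubdtype(self.voxels.dtype, np.floating):
            if not np.all(np.isfinite(self.voxels)):
                raise ValueError("stack contains non-finite values")
        if self.voxels.size and self.voxels.min() < 0:
            raise ValueError("stack contains negative intensities")
        self.spacing = _check_spacing(self.spacing)
        self.channel_role = ChannelRole(self.channel_role)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        """Volume of one voxel in µm³."""
        return float(np.prod(self.spacing))


@dataclass
class BinaryMask:
    """A 0/1 volume aligned to an :class:`ImageStack`.

    Nonzero values are coerced to 1 on construction (0/255 mask dialects are
    common); a warning is emitted when coercion changes values.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    label: MaskLabel = MaskLabel.OTHER

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={vox.ndim}")
        if vox.dtype != np.uint8 or (vox.size and vox.max(initial=0) > 1):
            coerced = (vox != 0).astype(np.uint8)
            if vox.size and not np.array_equal(coerced, vox):
                nonbinary = np.setdiff1d(np.unique(vox), [0, 1])
                if nonbinary.size:
                    warnings.warn(
                        f"mask values {nonbinary[:5].tolist()}... coerced to 1",
                        stacklevel=2,
                    )
            vox = coerced
        self.voxels = vox
        self.spacing = _check_spacing(self.spacing)
        self.label = MaskLabel(self.label)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    def as_bool(self) -> np.ndarray:
        return self.voxels.astype(bool)

    @property
    def volume_um3(self) -> float:
        return float(self.voxels.sum(dtype=np.int64)) * float(np.prod(self.spacing))


@dataclass
class Projection2D:
    """A 2D maximum-intensity projection with its in-plane spacing (µm)."""

    pixels: np.ndarray
    axis: int
    spacing: tuple[float, float] = field(default=(1.0, 1.0))

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("projection must be 2D")


def read_stack(path: str | Path, spacing, role: ChannelRole = ChannelRole.OTHER) -> ImageStack:
    """Read a multi-page TIFF into an :class:`ImageStack`.

    Integer pixel types are preserved losslessly.  Spacing is declared by the
    caller (µm, z/y/x); TIFF metadata is not trusted for geometry.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vox = tifffile.imread(path)
    if vox.ndim == 2:
        vox = vox[None]
    if vox.ndim != 3:
        raise ValueError(f"{path}: expected a 3D stack, got shape {vox.shape}")
    return ImageStack(vox, spacing, role)


def write_stack(path: str | Path, stack: ImageStack | BinaryMask) -> None:
    """Write a stack or mask as a multi-page TIFF (masks as uint8 {0,1})."""
    vox = stack.voxels
    if isinstance(stack, BinaryMask):
        vox = vox.astype(np.uint8)
    tifffile.imwrite(Path(path), vox, photometric="minisblack")


def read_mask(path: str | Path, spacing, label: MaskLabel = MaskLabel.OTHER) -> BinaryMask:
    """Read a 0/1 (or 0/255) multi-page TIFF mask."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vox = tifffile.imread(path)
    if vox.ndim == 2:
        vox = vox[None]
    if vox.ndim != 3:
        raise ValueError(f"{path}: expected a 3D mask, got shape {vox.shape}")
    return BinaryMask(vox, spacing, label)


def write_projection(path: str | Path, proj: Projection2D) -> None:
    tifffile.imwrite(Path(path), proj.pixels)


def max_intensity_projection(stack: ImageStack, axis: int = 0) -> Projection2D:
    """Maximum-intensity projection along one axis.

    Each output pixel is the maximum of the source stack along ``axis``; the
    result keeps the two remaining axes in (z,y,x) order.
    """
    if axis not in (0, 1, 2):
        raise ValueError(f"axis must be 0, 1 or 2, got {axis}")
    pixels = stack.voxels.max(axis=axis)
    plane_spacing = tuple(s for i, s in enumerate(stack.spacing) if i != axis)
    return Projection2D(pixels, axis=axis, spacing=plane_spacing)  # type: ignore[arg-type]


def mask_from_threshold(
    stack: ImageStack, threshold: float, *, inclusive: bool = False
) -> BinaryMask:
    """Binary NP-positive mask from an intensity threshold.

    Strict ``>`` by default, so a threshold equal to the background plateau
    excludes the plateau; pass ``inclusive=True`` for ``>=``.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    if inclusive:
        vox = stack.voxels >= threshold
    else:
        vox = stack.voxels > threshold
    return BinaryMask(vox.astype(np.uint8), stack.spacing, MaskLabel.NP_POSITIVE)


def require_aligned(*volumes: ImageStack | BinaryMask) -> None:
    """Raise unless all volumes share shape and spacing (no silent resampling)."""
    if not volumes:
        return
    ref = volumes[0]
    for v in volumes[1:]:
        if v.shape != ref.shape:
            raise ValueError(f"shape mismatch: {v.shape} vs {ref.shape}")
        if not np.allclose(v.spacing, ref.spacing):
            raise ValueError(f"spacing mismatch: {v.spacing} vs {ref.spacing}")
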