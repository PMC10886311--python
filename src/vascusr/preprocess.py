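"""Stack I/O and the intensity-normalization chain applied before training.

Raw two-photon stacks are 16-bit multi-page TIFFs.  Before any frame is used
as a high-resolution training target it passes through a fixed chain:

    3D median filter (radius 1)  →  full-scale contrast stretch (FSCS) with a
    small saturated fraction  →  16→8-bit conversion  →  frame separation.

The FSCS fills the full bit range of the stack so that training images share
a common intensity scale regardless of laser power or depth.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage


_VALID_DEPTHS = (8, 16)
_DTYPES = {8: np.uint8, 16: np.uint16}


@dataclasses.dataclass
class ImageStack:
    """A 3D grayscale intensity volume with physical voxel spacing.

    Parameters
    ----------
    voxels : ndarray, shape (z, y, x)
        Non-negative intensities within ``[0, 2**bit_depth - 1]``.
    spacing_um : tuple of float
        Physical voxel size ``(z, y, x)`` in micrometres; strictly positive.
    bit_depth : {8, 16}
        Unsigned integer bit depth of the acquisition.
    """

    voxels: np.ndarray
    spacing_um: tuple[float, float, float] = (3.0, 1.367, 1.367)
    bit_depth: int = 16

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim == 2:
            self.voxels = self.voxels[None]
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a (z, y, x) array")
        if self.voxels.shape[0] < 1:
            raise ValueError("stack needs at least one frame")
        if self.bit_depth not in _VALID_DEPTHS:
            raise ValueError(f"bit_depth must be one of {_VALID_DEPTHS}")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError("spacing_um must be 3 strictly positive values")
        lo, hi = self.voxels.min(), self.voxels.max()
        if lo < 0 or hi > self.max_value:
            raise ValueError(
                f"intensities [{lo}, {hi}] outside [0, {self.max_value}]"
            )

    @property
    def max_value(self) -> int:
        """Largest representable intensity, ``2**bit_depth - 1``."""
        return (1 << self.bit_depth) - 1

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.voxels.shape[1:]

    def astype_float(self) -> np.ndarray:
        """Voxels scaled to [0, 1] as float64."""
        return self.voxels.astype(np.float64) / self.max_value

    def replace(self, voxels: np.ndarray, bit_depth: int | None = None) -> "ImageStack":
        return ImageStack(
            voxels=voxels,
            spacing_um=self.spacing_um,
            bit_depth=self.bit_depth if bit_depth is None else bit_depth,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ImageStack):
            return NotImplemented
        return (
            self.bit_depth == other.bit_depth
            and self.spacing_um == other.spacing_um
            and self.voxels.shape == other.voxels.shape
            and bool(np.all(self.voxels == other.voxels))
        )


def from_float(
    frames: np.ndarray,
    bit_depth: int = 8,
    spacing_um: tuple[float, float, float] = (3.0, 1.367, 1.367),
) -> ImageStack:
    """Quantize a float array in [0, 1] to an integer :class:`ImageStack`."""
    frames = np.asarray(frames, dtype=np.float64)
    top = (1 << bit_depth) - 1
    vox = np.rint(np.clip(frames, 0.0, 1.0) * top).astype(_DTYPES[bit_depth])
    return ImageStack(vox, spacing_um=spacing_um, bit_depth=bit_depth)


def read_stack(
    path: str | Path,
    spacing_um: tuple[float, float, float] | None = None,
) -> ImageStack:
    """Read a single-channel multi-page TIFF into an :class:`ImageStack`.

    Axial spacing is taken from ImageJ metadata when present; ``spacing_um``
    overrides any metadata.  Multi-channel (RGB) input is rejected.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        if tif.pages[0].samplesperpixel != 1:
            raise ValueError(f"{path}: single-channel required")
        arr = tif.asarray()
        meta_spacing = _spacing_from_metadata(tif)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(
            f"{path}: single-channel required (got array of shape {arr.shape})"
        )
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise ValueError(f"{path}: unsupported sample format {arr.dtype}")
    spacing = spacing_um or meta_spacing or (3.0, 1.367, 1.367)
    return ImageStack(arr, spacing_um=spacing, bit_depth=depth)


def _spacing_from_metadata(tif: tifffile.TiffFile):
    try:
        ij = tif.imagej_metadata or {}
        z = float(ij.get("spacing", 0.0))
        page = tif.pages[0]
        xres = page.tags.get("XResolution")
        if z > 0 and xres is not None:
            num, den = xres.value
            xy = den / num if num else 0.0
            if xy > 0:
                return (z, xy, xy)
    except Exception:
        pass
    return None


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write an :class:`ImageStack` as a multi-page grayscale TIFF.

    The round trip ``read_stack(write_stack(s))`` is voxel-identical and
    byte-deterministic (no timestamps in the file).
    """
    path = Path(path)
    z, y, x = stack.spacing_um
    tifffile.imwrite(
        path,
        stack.voxels.astype(_DTYPES[stack.bit_depth]),
        imagej=True,
        resolution=(1.0 / x, 1.0 / y),
        metadata={"spacing": z, "unit": "um"},
    )


def median_filter_3d(
    stack: ImageStack, radius: tuple[int, int, int] = (1, 1, 1)
) -> ImageStack:
    """3D median filter with per-axis radius (window ``2r+1`` per axis).

    Borders are handled by reflection.  The default radius (1, 1, 1) is a
    3x3x3 window, the despeckling step used on raw stacks.
    """
    radius = tuple(int(r) for r in radius)
    if any(r < 0 for r in radius):
        raise ValueError("radius must be non-negative")
    size = tuple(2 * r + 1 for r in radius)
    out = ndimage.median_filter(stack.voxels, size=size, mode="mirror")
    return stack.replace(out)


def fscs_normalize(stack: ImageStack, saturation_frac: float = 0.003) -> ImageStack:
    """Full-scale contrast stretch over the whole stack.

    The clip bounds are the ``saturation_frac/2`` and ``1 - saturation_frac/2``
    intensity quantiles of the entire stack (the saturated fraction is split
    evenly between tails); ``[low, high]`` maps linearly onto the full bit
    range, values outside are clipped.  Output therefore attains both 0 and
    ``2**bit_depth - 1`` on any non-constant input.
    """
    if not 0.0 <= saturation_frac < 1.0:
        raise ValueError("saturation_frac must be in [0, 1)")
    vox = stack.voxels.astype(np.float64)
    low = np.quantile(vox, saturation_frac / 2.0)
    high = np.quantile(vox, 1.0 - saturation_frac / 2.0)
    if high <= low:
        warnings.warn("constant stack: FSCS output is all zeros", stacklevel=2)
        return stack.replace(np.zeros_like(stack.voxels))
    top = stack.max_value
    stretched = (vox - low) * (top / (high - low))
    out = np.rint(np.clip(stretched, 0.0, top)).astype(_DTYPES[stack.bit_depth])
    return stack.replace(out)


def convert_16_to_8(stack: ImageStack) -> ImageStack:
    """Convert a 16-bit stack to 8 bits: ``i -> round(i * 255 / 65535)``."""
    if stack.bit_depth != 16:
        raise ValueError("convert_16_to_8 requires a 16-bit stack")
    out = np.rint(stack.voxels.astype(np.float64) * (255.0 / 65535.0))
    return stack.replace(out.astype(np.uint8), bit_depth=8)


def split_frames(stack: ImageStack) -> list[tuple[int, np.ndarray]]:
    """Separate a stack into ``(z_index, frame)`` pairs in acquisition order."""
    return [(z, stack.voxels[z].copy()) for z in range(stack.n_frames)]


def merge_frames(
    frames: Sequence[np.ndarray],
    spacing_um: tuple[float, float, float],
    bit_depth: int,
) -> ImageStack:
    """Reassemble frames (in z order) into a stack; inverse of split_frames."""
    return ImageStack(np.stack(list(frames)), spacing_um=spacing_um, bit_depth=bit_depth)


def preprocess_stack(
    stack: ImageStack,
    median_radius: tuple[int, int, int] = (1, 1, 1),
    saturation_frac: float = 0.003,
    to_8bit: bool = True,
) -> ImageStack:
    """The full normalization chain applied to a raw 16-bit stack."""
    out = median_filter_3d(stack, median_radius)
    out = fscs_normalize(out, saturation_frac)
    if to_8bit and out.bit_depth == 16:
        out = convert_16_to_8(out)
    return out
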