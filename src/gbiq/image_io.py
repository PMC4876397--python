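"""Reading fluorescent raster channels and round-tripping grid-matrix tables.

Images are single-plane grayscale TIFF or PNG, 8- or 16-bit. Intensities are
never rescaled on read: the raw integer raster of the file is the in-memory
raster. RGB or other multi-sample layouts are rejected rather than converted,
because a silent luminance conversion would corrupt every downstream grid
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "ImageChannel",
    "MultiChannelImage",
    "read_channel",
    "write_channel",
    "write_grid_matrix",
    "read_grid_matrix",
    "FormatError",
]

#: fixed leading schema of the grid-matrix CSV; per-channel statistic columns
#: (<name>_median, <name>_iqr, ...) follow, then any appended cluster columns.
GRID_MATRIX_INDEX_COLUMNS = ["image_id", "grid_row", "grid_col", "g"]


class FormatError(ValueError):
    """Raised for images or tables whose layout the package does not accept."""


@dataclass(frozen=True)
class ImageChannel:
    """A single named grayscale channel.

    Parameters
    ----------
    name : str
        Channel label, e.g. ``"H33342"``, ``"EGFP"``, ``"DAPI"``.
    pixels : ndarray of shape (height, width)
        Non-negative integer intensities.
    bit_depth : {8, 16}
        Intensity range is ``[0, 2**bit_depth - 1]``.
    """

    name: str
    pixels: np.ndarray
    bit_depth: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise FormatError(
                f"channel {self.name!r}: expected a 2-D raster, got shape {px.shape}"
            )
        if self.bit_depth not in (8, 16):
            raise FormatError(
                f"channel {self.name!r}: bit depth must be 8 or 16, got {self.bit_depth}"
            )
        if not np.issubdtype(px.dtype, np.integer):
            raise FormatError(
                f"channel {self.name!r}: float rasters are not accepted "
                f"(dtype {px.dtype}); statistics require the original integer data"
            )
        if px.min() < 0 or px.max() > 2**self.bit_depth - 1:
            raise FormatError(
                f"channel {self.name!r}: intensities outside "
                f"[0, {2**self.bit_depth - 1}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class MultiChannelImage:
    """Aligned, same-depth channels of one field of view."""

    image_id: str
    channels: tuple[ImageChannel, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        chans = tuple(self.channels)
        if not chans:
            raise FormatError("an image needs at least one channel")
        names = [c.name for c in chans]
        if len(set(names)) != len(names):
            raise FormatError(f"duplicate channel names: {names}")
        h, w, d = chans[0].height, chans[0].width, chans[0].bit_depth
        for c in chans[1:]:
            if (c.height, c.width, c.bit_depth) != (h, w, d):
                raise FormatError(
                    f"channel {c.name!r} ({c.height}x{c.width}, {c.bit_depth}-bit) "
                    f"does not match {chans[0].name!r} ({h}x{w}, {d}-bit)"
                )
        object.__setattr__(self, "channels", chans)

    @property
    def channel_names(self) -> list[str]:
        return [c.name for c in self.channels]

    @property
    def height(self) -> int:
        return self.channels[0].height

    @property
    def width(self) -> int:
        return self.channels[0].width

    @property
    def bit_depth(self) -> int:
        return self.channels[0].bit_depth

    def channel(self, name: str) -> ImageChannel:
        for c in self.channels:
            if c.name == name:
                return c
        raise KeyError(f"no channel named {name!r}; have {self.channel_names}")


def read_channel(path: str | Path, name: str) -> ImageChannel:
    """Read one grayscale TIFF/PNG plane as a named channel.

    The pixel array matches the file bit-exactly; bit depth is inferred from
    the stored sample type. Multi-sample (RGB/RGBA) images raise
    :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    arr = iio.imread(path)
    if arr.ndim == 3:
        raise FormatError(
            f"{path}: {arr.shape[-1]} samples per pixel (RGB/multi-band); "
            "GBIQ requires one single-plane grayscale file per channel"
        )
    if arr.ndim != 2:
        raise FormatError(f"{path}: unsupported image layout with shape {arr.shape}")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise FormatError(
            f"{path}: unsupported sample type {arr.dtype}; expected uint8 or uint16"
        )
    return ImageChannel(name=name, pixels=arr, bit_depth=depth)


def write_channel(channel: ImageChannel, path: str | Path) -> None:
    """Write a channel as grayscale TIFF or PNG (by file extension)."""
    dtype = np.uint8 if channel.bit_depth == 8 else np.uint16
    iio.imwrite(Path(path), channel.pixels.astype(dtype))


def write_grid_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a grid matrix as UTF-8 comma-separated text.

    Floating-point statistics are written with 17 significant digits so a
    read-back reproduces them beyond the 15-digit round-trip contract.
    """
    if len(matrix) == 0:
        raise ValueError("refusing to write an empty grid matrix")
    missing = [c for c in GRID_MATRIX_INDEX_COLUMNS if c not in matrix.columns]
    if missing:
        raise FormatError(f"grid matrix missing required columns: {missing}")
    matrix.to_csv(path, index=False, float_format="%.17g", encoding="utf-8")


def read_grid_matrix(path: str | Path) -> pd.DataFrame:
    """Read a grid-matrix CSV, validating the fixed leading schema."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in GRID_MATRIX_INDEX_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(
            f"{path}: not a grid matrix — missing columns {missing}"
        )
    return df


def grid_matrix_channels(matrix: pd.DataFrame) -> list[str]:
    """Channel names inferred from ``<name>_median`` columns, in column order."""
    return [c[: -len("_median")] for c in matrix.columns if c.endswith("_median")]
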