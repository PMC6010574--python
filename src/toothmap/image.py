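"""8-bit grayscale raster type used throughout the pipeline.

All quantitative steps operate on single-channel 8-bit images, the native
currency of the acquisition workflow this package models.  Arithmetic that
leaves the 8-bit range saturates to [0, 255] and rounds half-up, mirroring
integer image-editor semantics.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

CHANNEL_TAGS = ("nuclear", "green", "red", "other")


def round_half_up(x: np.ndarray | float) -> np.ndarray:
    """Round to nearest integer with ties going up (0.5 -> 1)."""
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def clip_u8(x: np.ndarray | float) -> np.ndarray:
    """Round half-up and saturate to the 8-bit range, returning uint8."""
    return np.clip(round_half_up(x), 0, 255).astype(np.uint8)


@dataclass(frozen=True)
class GrayImage8:
    """A calibrated 8-bit single-channel raster.

    Parameters
    ----------
    pixels
        2-D ``uint8`` array, row-major (row 0 at the image top).
    pixel_size
        Physical size of one pixel in cm, when the image has been
        calibrated to a measurement scale; ``None`` otherwise.
    channel_tag
        Which fluorescence channel the raster came from: ``nuclear``
        (DAPI), ``green``, ``red`` or ``other``.
    """

    pixels: np.ndarray
    pixel_size: Optional[float] = None
    channel_tag: str = "other"

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {arr.shape}")
        if arr.dtype != np.uint8:
            if np.issubdtype(arr.dtype, np.integer) and arr.min(initial=0) >= 0 and arr.max(initial=0) <= 255:
                arr = arr.astype(np.uint8)
            else:
                raise ValueError("pixels must be 8-bit integers in [0, 255]")
        if self.channel_tag not in CHANNEL_TAGS:
            raise ValueError(f"channel_tag must be one of {CHANNEL_TAGS}, got {self.channel_tag!r}")
        if self.pixel_size is not None and not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive (cm/pixel)")
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage8":
        """Same metadata, new raster."""
        return replace(self, pixels=np.asarray(pixels, dtype=np.uint8))


def as_gray8(img, channel_tag: str = "other", pixel_size: Optional[float] = None) -> GrayImage8:
    """Coerce an array or GrayImage8 into a GrayImage8."""
    if isinstance(img, GrayImage8):
        return img
    return GrayImage8(np.asarray(img), pixel_size=pixel_size, channel_tag=channel_tag)


def imread_gray8(path: str | os.PathLike, channel_tag: str = "other",
                 pixel_size: Optional[float] = None) -> GrayImage8:
    """Read an 8-bit grayscale TIFF or PNG."""
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("L"))
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    return GrayImage8(arr.astype(np.uint8), pixel_size=pixel_size, channel_tag=channel_tag)


def imwrite_gray8(path: str | os.PathLike, img: GrayImage8) -> None:
    """Write an 8-bit grayscale TIFF or PNG."""
    path = os.fspath(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(path, img.pixels)
    else:
        from PIL import Image

        Image.fromarray(img.pixels, mode="L").save(path)
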