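"""Background equalization and fluorescence bleed-through reduction.

Immunofluorescence photomicrographs of tissue sections carry an additive
autofluorescent background and mutual leakage between the red and green
detection channels.  This module reproduces the two corrections applied
before any quantification:

1. **Iterative dark-point level adjustment.**  Marker points are placed in
   structures known to be negative for the stain (cell nuclei for antibody
   channels, inter-nuclear spaces for the nuclear stain).  The black point
   of the intensity histogram is raised and the remaining range is
   stretched linearly back to [0, 255]; the marker intensities are
   re-measured after each pass and the adjustment stops once all of them
   fall at or below the target (default 15, the conventional "0-15 is
   background" criterion).  At most three passes are applied.

2. **Counter-signal subtraction.**  Red is subtracted pixel-wise from
   green and vice versa (clipped at zero), separating the two channels,
   followed by median filtering to suppress the salt noise the
   subtraction leaves behind.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .image import GrayImage8, clip_u8

#: intensities at or below this value are treated as residual background
DEFAULT_BACKGROUND_TARGET = 15

#: per-pass cap on how far above the target the dark point may be placed,
#: so one aggressive pass cannot clip dim true signal
DARK_POINT_CAP_ABOVE_TARGET = 10


@dataclass(frozen=True)
class MarkerPointSet:
    """Pixel positions used to monitor background during level adjustment.

    The points must sit in structures known to be negative for the
    staining being corrected.
    """

    points: tuple[tuple[int, int], ...]
    expected_negative: bool = True

    def __post_init__(self) -> None:
        pts = tuple((int(r), int(c)) for r, c in self.points)
        if not pts:
            raise ValueError("MarkerPointSet.points must be non-empty")
        object.__setattr__(self, "points", pts)

    def validate_for(self, img: GrayImage8) -> None:
        h, w = img.shape
        for r, c in self.points:
            if not (0 <= r < h and 0 <= c < w):
                raise ValueError(f"marker point ({r}, {c}) outside image bounds {h}x{w}")

    def rows_cols(self) -> tuple[np.ndarray, np.ndarray]:
        arr = np.asarray(self.points)
        return arr[:, 0], arr[:, 1]


@dataclass(frozen=True)
class LevelAdjustment:
    """Audit record of a dark-point adjustment: the dark points applied in
    order (at most three) and the maximum marker intensity remaining."""

    dark_points: tuple[int, ...]
    residual_max: int

    def __post_init__(self) -> None:
        if len(self.dark_points) > 3:
            raise ValueError("at most three dark-point passes are recorded")


def measure_points(img: GrayImage8, markers: MarkerPointSet) -> list[int]:
    """Read the pixel intensity at each marker point, in marker order."""
    markers.validate_for(img)
    rows, cols = markers.rows_cols()
    return [int(v) for v in img.pixels[rows, cols]]


def dark_point_adjust(
    img: GrayImage8,
    markers: MarkerPointSet,
    target: int = DEFAULT_BACKGROUND_TARGET,
    max_passes: int = 3,
) -> tuple[GrayImage8, LevelAdjustment]:
    """Iterative black-point remap until marker intensities reach the target.

    Each pass measures the marker points, sets the dark point ``d`` to the
    maximum marker intensity (capped at ``target + 10``) and remaps every
    pixel ``v -> round(255 * max(0, v - d) / (255 - d))``.  Passes stop
    early once all markers read at or below ``target``.  The remap never
    increases a pixel value and fixes 0 and 255.

    Returns the adjusted image together with a :class:`LevelAdjustment`
    audit record.
    """
    if not markers.expected_negative:
        raise ValueError("markers must be expected_negative for dark-point adjustment")
    if not 0 <= target <= 255:
        raise ValueError(f"target must be an 8-bit value, got {target}")
    if max_passes < 1:
        raise ValueError("max_passes must be >= 1")
    markers.validate_for(img)

    arr = img.pixels.copy()
    rows, cols = markers.rows_cols()
    applied: list[int] = []
    for _ in range(max_passes):
        mx = int(arr[rows, cols].max())
        if mx <= target:
            break
        d = min(mx, target + DARK_POINT_CAP_ABOVE_TARGET)
        if d >= 255:
            raise ValueError("markers saturated")
        arr = clip_u8(255.0 * np.maximum(0.0, arr.astype(float) - d) / (255.0 - d))
        applied.append(d)

    residual = int(arr[rows, cols].max())
    return img.with_pixels(arr), LevelAdjustment(tuple(applied), residual)


def white_point_stretch(img: GrayImage8, white_point: int) -> GrayImage8:
    """Optional white-point remap ``v -> round(255 * v / w)`` (clipped).

    Off the default preprocessing path; provided for workflows that also
    equalize the bright end of the histogram.
    """
    if not 1 <= white_point <= 255:
        raise ValueError("white_point must be in [1, 255]")
    return img.with_pixels(clip_u8(255.0 * img.pixels.astype(float) / white_point))


def leakage_subtract(
    green: GrayImage8,
    red: GrayImage8,
    median_radius: int = 1,
) -> tuple[GrayImage8, GrayImage8]:
    """Mutual counter-channel subtraction followed by median filtering.

    ``green' = median(clip(green - red, 0))`` and symmetrically for red.
    Before filtering, at most one of the two outputs is nonzero at any
    pixel.  ``median_radius`` r gives a (2r+1) square kernel; 0 disables
    filtering.
    """
    if green.shape != red.shape:
        raise ValueError(f"shape mismatch: green {green.shape} vs red {red.shape}")
    if median_radius < 0:
        raise ValueError("median_radius must be >= 0")

    g = green.pixels.astype(np.int16)
    r = red.pixels.astype(np.int16)
    g_sub = np.clip(g - r, 0, 255).astype(np.uint8)
    r_sub = np.clip(r - g, 0, 255).astype(np.uint8)
    if median_radius > 0:
        size = 2 * median_radius + 1
        g_sub = ndimage.median_filter(g_sub, size=size)
        r_sub = ndimage.median_filter(r_sub, size=size)
    return green.with_pixels(g_sub), red.with_pixels(r_sub)


def read_marker_csv(path) -> MarkerPointSet:
    """Load marker points from a two-column CSV of (row, col)."""
    pts = np.loadtxt(path, delimiter=",", dtype=int, ndmin=2)
    return MarkerPointSet(tuple((int(r), int(c)) for r, c in pts))


def write_marker_csv(path, markers: MarkerPointSet) -> None:
    np.savetxt(path, np.asarray(markers.points, dtype=int), delimiter=",", fmt="%d")
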