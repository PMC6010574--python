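"""Pixel-value -> optical-density calibration and cm-calibrated profiles.

Densitometric readout converts 8-bit pixel intensities to optical density
(OD) using a scanned 21-step calibrated tablet spanning 0.05-3.05 OD.
OD runs opposite to intensity: higher pixel values mean lower OD.  The
conversion curve is a piecewise-linear monotone interpolation through the
(pixel, OD) readings, clamped outside the measured range.  Calibrated
images are reduced to per-row plot profiles (distance in cm along the
vertical scan axis) or passed through as surface-plot height fields.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .image import GrayImage8

OD_MIN, OD_MAX = 0.05, 3.05  # density range of the 21-step tablet


@dataclass(frozen=True)
class StepTabletReading:
    """One step of the calibration tablet: nominal OD and the pixel value
    it scans to."""

    nominal_od: float
    measured_pixel: int

    def __post_init__(self) -> None:
        if not OD_MIN <= self.nominal_od <= OD_MAX:
            raise ValueError(
                f"nominal_od {self.nominal_od} outside the tablet range [{OD_MIN}, {OD_MAX}]"
            )
        if not 0 <= self.measured_pixel <= 255:
            raise ValueError(f"measured_pixel {self.measured_pixel} outside [0, 255]")


@dataclass(frozen=True)
class CalibrationCurve:
    """Monotone pixel->OD mapping: piecewise linear through the readings,
    clamped to the endpoint OD outside the measured pixel range."""

    readings: tuple[StepTabletReading, ...]
    _px: np.ndarray
    _od: np.ndarray

    def __call__(self, pixels) -> np.ndarray:
        return np.interp(np.asarray(pixels, dtype=float), self._px, self._od)

    def map_pixel(self, pixel: float) -> float:
        return float(self(pixel))


def build_calibration(readings: Sequence[StepTabletReading]) -> CalibrationCurve:
    """Fit the conversion curve from step-tablet readings.

    Requires at least two readings with distinct pixel values; OD must
    decrease as pixel value increases (anti-monotone pairs are rejected —
    they indicate a misread tablet).  Duplicate (pixel, OD) readings are
    collapsed.
    """
    if len(readings) < 2:
        raise ValueError("calibration needs at least two step-tablet readings")
    by_px: dict[int, float] = {}
    for r in readings:
        if r.measured_pixel in by_px and by_px[r.measured_pixel] != r.nominal_od:
            raise ValueError(
                f"duplicate pixel value {r.measured_pixel} with conflicting OD readings"
            )
        by_px[r.measured_pixel] = r.nominal_od
    if len(by_px) < 2:
        raise ValueError("calibration needs at least two distinct pixel values")
    px = np.array(sorted(by_px), dtype=float)
    od = np.array([by_px[int(p)] for p in px], dtype=float)
    if np.any(np.diff(od) >= 0):
        raise ValueError(
            "anti-monotone readings: OD must strictly decrease with increasing pixel value"
        )
    ordered = tuple(
        StepTabletReading(float(o), int(p)) for p, o in zip(px, od)
    )
    return CalibrationCurve(ordered, px, od)


@dataclass(frozen=True)
class SurfaceGrid:
    """2-D field of OD values with cm axes (row/column pitch = pixel_size)."""

    values: np.ndarray
    pixel_size: Optional[float] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("SurfaceGrid values must be 2-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("SurfaceGrid values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class ProfileCurve:
    """Per-row OD profile along the vertical scan axis, positions in cm."""

    positions: np.ndarray  # cm
    values: np.ndarray  # OD
    aggregation: str

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.values):
            raise ValueError("positions and values must have equal length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


def to_od(img: GrayImage8, curve: CalibrationCurve) -> SurfaceGrid:
    """Convert an 8-bit image to OD units, element-wise through the curve."""
    return SurfaceGrid(curve(img.pixels), pixel_size=img.pixel_size)


def plot_profile(grid: SurfaceGrid, row_statistic: str = "mean") -> ProfileCurve:
    """Reduce the OD grid to one value per row (image scanned vertically).

    ``row_statistic``: 'mean' (default) or 'max'.  Positions are row
    index times the pixel size in cm.
    """
    if grid.pixel_size is None:
        raise ValueError("plot profile requires a cm-calibrated grid (pixel_size set)")
    if row_statistic not in ("mean", "max"):
        raise ValueError(f"row_statistic must be 'mean' or 'max', got {row_statistic!r}")
    reducer = np.mean if row_statistic == "mean" else np.max
    values = reducer(grid.values, axis=1)
    positions = np.arange(grid.shape[0], dtype=float) * grid.pixel_size
    return ProfileCurve(positions, values, row_statistic)


def surface_plot_data(grid: SurfaceGrid, step: int = 1, reduce: str = "max") -> dict:
    """Renderable height field for 3-D surface plots: cm axes plus the OD
    grid, optionally decimated blockwise (``reduce``: 'max', 'min' or
    'mean') for display.  Plotting itself is presentation-layer."""
    if step < 1:
        raise ValueError("step must be >= 1")
    z = grid.values
    if step > 1:
        h, w = z.shape
        th, tw = (h // step) * step, (w // step) * step
        blocks = z[:th, :tw].reshape(th // step, step, tw // step, step)
        if reduce == "max":
            z = blocks.max(axis=(1, 3))
        elif reduce == "min":
            z = blocks.min(axis=(1, 3))
        elif reduce == "mean":
            z = blocks.mean(axis=(1, 3))
        else:
            raise ValueError(f"unknown reduce {reduce!r}")
    ps = grid.pixel_size if grid.pixel_size is not None else 1.0
    return {
        "x_cm": np.arange(z.shape[1], dtype=float) * ps * step,
        "y_cm": np.arange(z.shape[0], dtype=float) * ps * step,
        "z_od": z,
    }


def synthetic_step_tablet(
    n_steps: int = 21, pixel_range: tuple[int, int] = (5, 250), step_width: int = 8
) -> tuple[list[StepTabletReading], GrayImage8]:
    """Synthetic stand-in for a scanned calibration step tablet.

    Emulates a 21-step wedge spanning 0.05-3.05 OD: nominal OD increases
    linearly across steps while the scanned pixel value decreases
    linearly.  Returns the readings and a step-wedge image (one vertical
    stripe per step) usable for round-trip tests.
    """
    if n_steps < 2:
        raise ValueError("a tablet needs at least two steps")
    ods = np.linspace(OD_MIN, OD_MAX, n_steps)
    pxs = np.round(np.linspace(pixel_range[1], pixel_range[0], n_steps)).astype(int)
    if len(np.unique(pxs)) != n_steps:
        raise ValueError("pixel range too narrow for the requested number of steps")
    readings = [StepTabletReading(float(o), int(p)) for o, p in zip(ods, pxs)]
    strip = np.repeat(pxs.astype(np.uint8)[np.newaxis, :], step_width, axis=0)
    tablet = np.repeat(strip, step_width, axis=1)
    return readings, GrayImage8(tablet, channel_tag="other")


def read_calibration_csv(path) -> list[StepTabletReading]:
    """Load readings from a two-column CSV (nominal_od, pixel)."""
    arr = np.loadtxt(path, delimiter=",", ndmin=2)
    return [StepTabletReading(float(od), int(px)) for od, px in arr]
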