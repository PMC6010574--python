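"""Threshold-band construction, intensity hotmaps and expression-domain size.

The quantification convention this package reproduces sets seven intensity
thresholds per 8-bit photomicrograph — 15, 30, 45, 55, 70, 85 and 95 —
and builds, for each consecutive pair, the *subtraction product*: the
lower threshold mask with the higher threshold mask (their overlap when
the two are colorized and merged) subtracted away.  That yields six band
images covering half-open intensity intervals, plus the open top band
(>= 95) kept as-is; the seven are pseudo-colored and merged into a
composite "hotmap".  The expression domain of a factor is the area at or
above the baseline threshold (15), reported as a percentage of a region
of interest.  Finer sample-unit bands at 5-pixel increments over 15-95
serve as the observation unit for statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .image import GrayImage8

DEFAULT_LEVELS = (15, 30, 45, 55, 70, 85, 95)

#: pseudo-colors of the seven default bands, low to high intensity
BAND_COLOR_ORDER = (
    "dark blue",
    "bright blue",
    "dark green",
    "bright green",
    "dark red",
    "bright red",
    "yellow",
)

PALETTE: dict[str, tuple[int, int, int]] = {
    "dark blue": (0, 0, 139),
    "bright blue": (0, 128, 255),
    "dark green": (0, 100, 0),
    "bright green": (0, 255, 0),
    "dark red": (139, 0, 0),
    "bright red": (255, 0, 0),
    "yellow": (255, 255, 0),
}


@dataclass(frozen=True)
class ThresholdSet:
    """Strictly increasing 8-bit threshold levels; the first is the baseline."""

    levels: tuple[int, ...] = DEFAULT_LEVELS

    def __post_init__(self) -> None:
        lv = tuple(int(v) for v in self.levels)
        if len(lv) < 2:
            raise ValueError("ThresholdSet needs at least two levels")
        if any(not 1 <= v <= 255 for v in lv):
            raise ValueError(f"threshold levels must be in [1, 255], got {lv}")
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError(f"threshold levels must be strictly increasing, got {lv}")
        object.__setattr__(self, "levels", lv)

    @property
    def baseline(self) -> int:
        return self.levels[0]


@dataclass(frozen=True)
class BandImage:
    """Binary mask of pixels in one half-open intensity interval [low, high).

    ``high`` is 256 for the open top band.  ``subtraction_product`` marks
    bands built by the merge-and-subtract step, as opposed to the raw top
    threshold image.
    """

    mask: np.ndarray
    interval: tuple[int, int]
    color_label: str
    subtraction_product: bool = True

    def __post_init__(self) -> None:
        low, high = self.interval
        if not (0 <= low < high <= 256):
            raise ValueError(f"invalid band interval {self.interval}")
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class ROIMask:
    """Region of interest: whole tooth germ, cervical loop, or inner enamel
    epithelium with surrounding mesenchyme.  Supplied, never auto-segmented."""

    mask: np.ndarray
    id: str = "whole_tooth_germ"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not m.any():
            raise ValueError(f"ROI {self.id!r} is empty")
        object.__setattr__(self, "mask", m)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class Hotmap:
    """Composite label raster: each above-baseline pixel carries the index of
    its intensity band; pixels below the baseline are unlabeled (-1)."""

    labels: np.ndarray
    band_colors: tuple[str, ...]
    palette: dict[str, tuple[int, int, int]] = field(default_factory=lambda: dict(PALETTE))
    thresholds: Optional[ThresholdSet] = None

    def label_counts(self) -> dict[str, int]:
        return {
            color: int((self.labels == i).sum()) for i, color in enumerate(self.band_colors)
        }

    def to_rgb(self) -> np.ndarray:
        """Render the hotmap as an RGB uint8 array (black below baseline)."""
        rgb = np.zeros(self.labels.shape + (3,), dtype=np.uint8)
        for i, color in enumerate(self.band_colors):
            rgb[self.labels == i] = self.palette.get(color, (255, 255, 255))
        return rgb


@dataclass(frozen=True)
class DomainMeasurement:
    """Expression-domain size of one factor in one ROI at one stage."""

    factor: str
    stage: str
    roi_id: str
    roi_area: int
    domain_area: int
    fraction: float  # percent of ROI area
    band_histogram: dict[str, int]

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 100:
            raise ValueError("fraction must be a percentage in [0, 100]")
        if sum(self.band_histogram.values()) != self.domain_area:
            raise ValueError("band histogram must sum to the domain area")


def threshold_image(img: GrayImage8, t: int) -> np.ndarray:
    """Binary threshold mask, inclusive at t: pixels with value >= t."""
    if not 1 <= t <= 255:
        raise ValueError(f"threshold must be in [1, 255], got {t}")
    return img.pixels >= t


def _band_color(i: int, n_bands: int) -> str:
    if n_bands <= len(BAND_COLOR_ORDER) and i < n_bands - 1:
        return BAND_COLOR_ORDER[i]
    return f"band {i}"


def band_images(img: GrayImage8, ts: ThresholdSet = ThresholdSet()) -> list[BandImage]:
    """Colorize-merge-subtract banding.

    For each consecutive threshold pair (t_i, t_{i+1}) the low mask and
    high mask are merged and their overlap subtracted, leaving the
    subtraction-product band [t_i, t_{i+1}); with the default seven
    levels this creates six such images.  The open top band (>= last
    level, the raw top threshold image) is appended last and labeled
    yellow.
    """
    levels = ts.levels
    masks = [threshold_image(img, t) for t in levels]
    n_bands = len(levels)
    bands: list[BandImage] = []
    for i, (lo_mask, hi_mask) in enumerate(zip(masks, masks[1:])):
        # merge of the two colorized thresholds minus their (yellow) overlap
        band_mask = lo_mask & ~(lo_mask & hi_mask)
        bands.append(
            BandImage(band_mask, (levels[i], levels[i + 1]), _band_color(i, n_bands))
        )
    bands.append(BandImage(masks[-1], (levels[-1], 256), "yellow", subtraction_product=False))
    return bands


def compose_hotmap(bands: Sequence[BandImage], thresholds: Optional[ThresholdSet] = None) -> Hotmap:
    """Merge disjoint band masks into a composite hotmap label raster."""
    if not bands:
        raise ValueError("no bands to compose")
    shape = bands[0].mask.shape
    labels = np.full(shape, -1, dtype=np.int16)
    covered = np.zeros(shape, dtype=bool)
    for i, band in enumerate(bands):
        if band.mask.shape != shape:
            raise ValueError("band masks have mismatched shapes")
        if (covered & band.mask).any():
            raise ValueError("bands overlap; hotmap requires pairwise disjoint bands")
        labels[band.mask] = i
        covered |= band.mask
    return Hotmap(labels, tuple(b.color_label for b in bands), thresholds=thresholds)


def domain_size(
    img: GrayImage8,
    roi: ROIMask,
    ts: ThresholdSet = ThresholdSet(),
    factor: str = "",
    stage: str = "",
) -> DomainMeasurement:
    """Expression-domain size: pixels at or above the baseline threshold,
    as a percentage of the ROI area, with the per-band pixel histogram."""
    if roi.mask.shape != img.shape:
        raise ValueError(f"ROI shape {roi.mask.shape} does not match image {img.shape}")
    domain = threshold_image(img, ts.baseline) & roi.mask
    domain_area = int(domain.sum())
    hist = {
        b.color_label: int((b.mask & roi.mask).sum()) for b in band_images(img, ts)
    }
    return DomainMeasurement(
        factor=factor,
        stage=stage,
        roi_id=roi.id,
        roi_area=roi.area,
        domain_area=domain_area,
        fraction=100.0 * domain_area / roi.area,
        band_histogram=hist,
    )


def sample_unit_bands(
    img: GrayImage8, low: int = 15, high: int = 95, step: int = 5
) -> list[BandImage]:
    """Fine bands at fixed increments (default 5 px over 15-95), the
    sampling unit for expression-domain statistics.

    Each band is the subtraction product over [l, l+step); together they
    partition the [low, high) intensity range into (high-low)/step images.
    """
    if not low < high:
        raise ValueError(f"low ({low}) must be less than high ({high})")
    if step < 1 or (high - low) % step != 0:
        raise ValueError(f"step {step} must divide the range {high - low}")
    bands = []
    for lo in range(low, high, step):
        lo_mask = threshold_image(img, lo)
        hi_mask = threshold_image(img, lo + step) if lo + step <= 255 else np.zeros_like(lo_mask)
        bands.append(
            BandImage(lo_mask & ~hi_mask, (lo, lo + step), f"{lo}-{lo + step}")
        )
    return bands


def measurements_to_frame(measurements: Sequence[DomainMeasurement]):
    """Tidy table of domain measurements (one row per factor/stage/ROI)."""
    import pandas as pd

    rows = []
    for m in measurements:
        row = {
            "factor": m.factor,
            "stage": m.stage,
            "roi": m.roi_id,
            "roi_area": m.roi_area,
            "domain_area": m.domain_area,
            "fraction": m.fraction,
        }
        for color, count in m.band_histogram.items():
            row[f"band[{color}]"] = count
        rows.append(row)
    return pd.DataFrame(rows)
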