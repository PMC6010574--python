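"""Intensity-correlation and serial-threshold co-localization analysis.

Two channels are compared three ways:

* a **scatterplot** — the exact 256x256 joint histogram of pixel
  intensities over an ROI, the object read visually in merged-doublet
  co-localization figures;
* an **intensity correlation** — Pearson's r plus an overlap fraction
  over pixels where either channel is at or above the baseline (15),
  yielding a nuclear / non-nuclear / mixed pattern call against the
  DAPI channel; and
* **serial co-localization** — a reference channel held at its baseline
  threshold intersected with a probe channel at rising thresholds; when
  nearly all overlap sits in the lowest band the pattern is flagged
  "baseline-only" (the configuration reported for a matrix factor
  overlapping an enzyme only at low signal intensity).

Background co-absence is never counted as co-localization: pixels below
the baseline in both channels are excluded from the correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .banding import ROIMask
from .image import GrayImage8

DEFAULT_BASELINE = 15
DEFAULT_PROBE_THRESHOLDS = (15, 30, 45, 55)


def _roi_mask(roi, shape) -> np.ndarray:
    if roi is None:
        return np.ones(shape, dtype=bool)
    mask = roi.mask if isinstance(roi, ROIMask) else np.asarray(roi, dtype=bool)
    if mask.shape != shape:
        raise ValueError(f"ROI shape {mask.shape} does not match image {shape}")
    return mask


@dataclass(frozen=True)
class ScatterplotGrid:
    """Joint intensity histogram of two channels over an ROI."""

    counts: np.ndarray  # (256, 256), counts[a, b]
    n_pixels: int

    def marginal_a(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def marginal_b(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def transposed(self) -> "ScatterplotGrid":
        return ScatterplotGrid(self.counts.T.copy(), self.n_pixels)


@dataclass(frozen=True)
class ColocResult:
    """Correlation-based co-localization summary for a channel pair."""

    pearson_r: float
    overlap_fraction: float  # % of A-positive pixels that are also B-positive
    pattern_call: str  # nuclear | non_nuclear | mixed
    n_qualifying: int
    baseline: int


@dataclass(frozen=True)
class SerialColocSeries:
    """Overlap of a baseline-thresholded reference with a probe channel at
    rising thresholds; masks nest as the probe threshold increases."""

    reference_threshold: int
    probe_thresholds: tuple[int, ...]
    overlap_masks: tuple[np.ndarray, ...]
    overlap_areas: tuple[int, ...]
    baseline_only: bool


def scatterplot(
    a: GrayImage8, b: GrayImage8, roi: Union[ROIMask, np.ndarray, None] = None
) -> ScatterplotGrid:
    """Exact 256x256 joint histogram of (a, b) intensities over the ROI."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mask = _roi_mask(roi, a.shape)
    av = a.pixels[mask].astype(np.int64)
    bv = b.pixels[mask].astype(np.int64)
    counts = np.bincount(av * 256 + bv, minlength=256 * 256).reshape(256, 256)
    return ScatterplotGrid(counts, int(mask.sum()))


def intensity_correlation(
    a: GrayImage8,
    b: GrayImage8,
    roi: Union[ROIMask, np.ndarray, None] = None,
    baseline: int = DEFAULT_BASELINE,
    r_cutoff: float = 0.5,
    overlap_cutoff: float = 50.0,
) -> ColocResult:
    """Pearson correlation and overlap fraction over signal-bearing pixels.

    Qualifying pixels have either channel at or above the baseline; the
    overlap fraction is the percentage of A-positive pixels that are also
    B-positive.  The pattern is called *nuclear* when B is the nuclear
    channel and both r and overlap clear their cutoffs, *non_nuclear*
    when both fall below, and *mixed* otherwise.  The cutoffs are
    pragmatic defaults, not a published convention.
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    mask = _roi_mask(roi, a.shape)
    a_pos = (a.pixels >= baseline) & mask
    b_pos = (b.pixels >= baseline) & mask
    qualifying = a_pos | b_pos
    n = int(qualifying.sum())
    if n < 2:
        raise ValueError("insufficient signal: fewer than two qualifying pixels")

    av = a.pixels[qualifying].astype(float)
    bv = b.pixels[qualifying].astype(float)
    if av.std() == 0 or bv.std() == 0:
        r = 0.0  # a constant channel carries no linear association
    else:
        r = float(np.corrcoef(av, bv)[0, 1])

    n_a = int(a_pos.sum())
    overlap = 100.0 * int((a_pos & b_pos).sum()) / n_a if n_a else 0.0

    is_nuclear_ref = b.channel_tag == "nuclear"
    if is_nuclear_ref and r >= r_cutoff and overlap >= overlap_cutoff:
        call = "nuclear"
    elif r < r_cutoff and overlap < overlap_cutoff:
        call = "non_nuclear"
    else:
        call = "mixed"
    return ColocResult(r, overlap, call, n, baseline)


def serial_coloc(
    reference: GrayImage8,
    probe: GrayImage8,
    probe_thresholds: Sequence[int] = DEFAULT_PROBE_THRESHOLDS,
    reference_threshold: int = DEFAULT_BASELINE,
    baseline_only_factor: float = 2.0,
) -> SerialColocSeries:
    """Serial mergers of a baseline-held reference with a rising-threshold probe.

    Per probe level L the overlap mask is (reference >= baseline) AND
    (probe >= L); areas are non-increasing in L by mask nesting.  The
    series is flagged *baseline-only* when the lowest level's overlap
    exceeds the next level's by more than ``baseline_only_factor``.
    """
    if reference.shape != probe.shape:
        raise ValueError(f"shape mismatch: {reference.shape} vs {probe.shape}")
    levels = tuple(int(t) for t in probe_thresholds)
    if len(levels) < 1 or any(b <= a for a, b in zip(levels, levels[1:])):
        raise ValueError(f"probe thresholds must be ascending, got {levels}")
    ref_mask = reference.pixels >= reference_threshold
    masks = tuple(ref_mask & (probe.pixels >= lv) for lv in levels)
    areas = tuple(int(m.sum()) for m in masks)
    baseline_only = (
        len(areas) >= 2 and areas[0] > baseline_only_factor * areas[1]
    )
    return SerialColocSeries(reference_threshold, levels, masks, areas, baseline_only)
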