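"""Synthetic tooth-germ photomicrographs with complete ground truth.

Real material for this kind of study is archival histology: serial
sections of developing human tooth germs, double-stained for a nuclear
dye plus one or two factors, photographed as 8-bit fluorescence channels.
No such images can ship with a software package, so every downstream
stage is exercised on a parametric phantom instead.

The phantom emulates the features of those acquisitions that the
pipeline actually consumes:

* an epithelial/mesenchymal organ cross-section — an enamel-organ-like
  epithelial shell enclosing a dental-papilla-like mesenchymal core,
  with cervical loops at the margins and an inner-enamel-epithelium
  band along the papilla interface (topology, not anatomy);
* DAPI-like nuclei: bright disks scattered through the tissue;
* compartment-restricted factor expression with linear intensity
  gradients;
* an additive autofluorescent background with Gaussian noise; and
* linear red<->green spectral bleed-through.

Ground truth (compartment masks, expression-domain fractions,
co-localization fractions) is computed from the *clean* rasters — before
background, noise and leakage are added — at the pipeline's baseline
threshold of 15, so that what the measurement stages recover can be
compared against what was put in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
from scipy import ndimage

from .image import GrayImage8, clip_u8
from .preprocess import MarkerPointSet

STAGE_LABELS = ("bud", "cap", "bell_cl", "bell_iee")
COMPARTMENTS = ("epithelium", "mesenchyme", "cervical_loop", "iee", "background")
FACTOR_CHANNELS = ("green", "red")
CHANNELS = ("nuclear",) + FACTOR_CHANNELS

#: threshold defining "expressed" in the ground truth, identical to the
#: baseline band lower bound used by the measurement stages
GROUND_TRUTH_THRESHOLD = 15

#: fraction of the nuclear signal that bleeds into antibody channels when
#: primary antibodies are omitted (negative-control acquisitions)
NEGATIVE_CONTROL_NUCLEAR_BLEED = 0.02


@dataclass(frozen=True)
class GradientExpression:
    """Expression of one factor within one compartment.

    ``mean`` is the central intensity; a linear gradient along
    ``direction`` ('none', 'up', 'down', 'left', 'right') spans
    ``mean - span/2`` to ``mean + span/2`` across the compartment's
    bounding box.  ``nuclear_mode`` controls sub-cellular placement:
    'uniform' paints the whole compartment, 'internuclear' excludes
    nucleus disks, 'nuclear' paints only onto nuclei (scaled to the
    nucleus brightness) — the latter two exist so co-localization calls
    have a known truth.
    """

    mean: float
    direction: str = "none"
    span: float = 0.0
    nuclear_mode: str = "uniform"

    def __post_init__(self) -> None:
        if not 0 <= self.mean <= 255:
            raise ValueError(f"compartment_expression: mean {self.mean} outside [0, 255]")
        if self.direction not in ("none", "up", "down", "left", "right"):
            raise ValueError(f"compartment_expression: unknown direction {self.direction!r}")
        if self.span < 0:
            raise ValueError("compartment_expression: span must be >= 0")
        if self.nuclear_mode not in ("uniform", "internuclear", "nuclear"):
            raise ValueError(f"compartment_expression: unknown nuclear_mode {self.nuclear_mode!r}")


def _default_expression() -> dict[str, dict[str, GradientExpression]]:
    return {
        "green": {
            "epithelium": GradientExpression(mean=110.0, direction="down", span=60.0),
            "iee": GradientExpression(mean=170.0),
            "cervical_loop": GradientExpression(mean=140.0),
        },
        "red": {
            "mesenchyme": GradientExpression(mean=90.0, direction="up", span=40.0),
            "iee": GradientExpression(mean=60.0),
        },
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic photomicrograph.

    Defaults emulate a x40 acquisition scaled down to 256x192 px, with
    the autofluorescent background level (25) and noise (SD 3) that the
    dark-point adjustment is expected to push into the 0-15 range.
    """

    width: int = 256
    height: int = 192
    pixel_size: float = 0.01  # cm/pixel on the calibrated print scale
    stage_label: str = "cap"
    background_level: float = 25.0
    background_noise_sd: float = 3.0
    leakage_green_to_red: float = 0.15
    leakage_red_to_green: float = 0.10
    nucleus_density: float = 4.0  # nuclei per 1000 px^2
    compartment_expression: Mapping[str, Mapping[str, GradientExpression]] = field(
        default_factory=_default_expression
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError(f"width/height must be >= 64, got {self.width}x{self.height}")
        if not 0 <= self.background_level <= 64:
            raise ValueError(f"background_level {self.background_level} outside [0, 64]")
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be >= 0")
        for name in ("leakage_green_to_red", "leakage_red_to_green"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1), got {v}")
        if self.stage_label not in STAGE_LABELS:
            raise ValueError(f"stage_label must be one of {STAGE_LABELS}, got {self.stage_label!r}")
        if self.nucleus_density < 0:
            raise ValueError("nucleus_density must be >= 0")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        for ch, comps in self.compartment_expression.items():
            if ch not in FACTOR_CHANNELS:
                raise ValueError(f"compartment_expression: unknown channel {ch!r}")
            for comp in comps:
                if comp not in COMPARTMENTS:
                    raise ValueError(f"compartment_expression: unknown compartment {comp!r}")


@dataclass(frozen=True)
class Phantom:
    """A generated synthetic section plus its ground truth.

    ``channels`` hold the observed rasters (clean signal + leakage +
    background + noise, clipped to 8 bit); ``clean`` the pre-noise,
    pre-leakage signal from which the ground truth is counted.
    ``compartment_masks`` are pairwise disjoint and tile the frame.
    """

    channels: Mapping[str, GrayImage8]
    clean: Mapping[str, np.ndarray]
    compartment_masks: Mapping[str, np.ndarray]
    nuclei_mask: np.ndarray
    true_domain_fraction: Mapping[tuple[str, str], float]
    true_coloc_fraction: Mapping[tuple[str, str], float]
    spec: PhantomSpec

    @property
    def tissue_mask(self) -> np.ndarray:
        return ~self.compartment_masks["background"]


def _ellipse_mask(h: int, w: int, cr: float, cc: float, ar: float, ac: float) -> np.ndarray:
    rr, cc_ = np.mgrid[0:h, 0:w]
    return ((rr - cr) / ar) ** 2 + ((cc_ - cc) / ac) ** 2 <= 1.0


def _disk_mask(h: int, w: int, cr: float, cc: float, radius: float) -> np.ndarray:
    rr, cc_ = np.mgrid[0:h, 0:w]
    return (rr - cr) ** 2 + (cc_ - cc) ** 2 <= radius**2


def compartment_geometry(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Parametric compartment masks for one developmental stage.

    Only the topology matters for testing: an epithelial shell, a
    mesenchymal core invaginating from below (absent at the bud stage),
    cervical loops where the shell margins wrap around the core, and an
    inner-epithelium band along the core interface.  Masks are pairwise
    disjoint and together tile the frame.
    """
    h, w = spec.height, spec.width
    germ = _ellipse_mask(h, w, 0.52 * h, 0.50 * w, 0.34 * h, 0.36 * w)

    papilla_scale = {"bud": 0.0, "cap": 0.55, "bell_cl": 0.72, "bell_iee": 0.72}[spec.stage_label]
    loop_radius = {"bud": 0.0, "cap": 0.045, "bell_cl": 0.07, "bell_iee": 0.06}[spec.stage_label]

    if papilla_scale > 0:
        papilla = _ellipse_mask(
            h, w, 0.66 * h, 0.50 * w, papilla_scale * 0.34 * h, papilla_scale * 0.36 * w
        )
        papilla &= germ
    else:
        papilla = np.zeros((h, w), dtype=bool)

    epithelium = germ & ~papilla

    loops = np.zeros((h, w), dtype=bool)
    if loop_radius > 0:
        r = loop_radius * h
        cr = 0.70 * h
        for cc in (0.50 * w - papilla_scale * 0.36 * w, 0.50 * w + papilla_scale * 0.36 * w):
            loops |= _disk_mask(h, w, cr, cc, r)
        loops &= germ

    if papilla.any():
        iee = ndimage.binary_dilation(papilla, iterations=max(2, h // 48)) & epithelium & ~loops
    else:
        iee = np.zeros((h, w), dtype=bool)

    masks = {
        "cervical_loop": loops,
        "iee": iee,
        "epithelium": epithelium & ~loops & ~iee,
        "mesenchyme": papilla & ~loops,
        "background": ~germ & ~loops,
    }
    return masks


def _gradient_field(mask: np.ndarray, expr: GradientExpression) -> np.ndarray:
    """Clean intensity field for one compartment: mean + linear ramp."""
    field_ = np.zeros(mask.shape, dtype=float)
    if not mask.any():
        return field_
    field_[mask] = expr.mean
    if expr.direction != "none" and expr.span > 0:
        rows, cols = np.nonzero(mask)
        if expr.direction in ("up", "down"):
            lo, hi = rows.min(), rows.max()
            coord = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]][0]
        else:
            lo, hi = cols.min(), cols.max()
            coord = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]][1]
        extent = max(hi - lo, 1)
        t = (coord - lo) / extent  # 0 at top/left edge of bbox, 1 at bottom/right
        if expr.direction in ("up", "left"):
            t = 1.0 - t
        ramp = (t - 0.5) * expr.span
        field_[mask] += ramp[mask]
    return np.clip(field_, 0, 255)


def _place_nuclei(spec: PhantomSpec, tissue: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Clean nuclear raster: constant-intensity disks at random tissue positions."""
    h, w = spec.height, spec.width
    clean = np.zeros((h, w), dtype=float)
    n = int(round(spec.nucleus_density * h * w / 1000.0))
    idx = np.flatnonzero(tissue)
    if n == 0 or idx.size == 0:
        return clean
    centers = rng.choice(idx, size=n, replace=True)
    radii = rng.uniform(1.5, 2.5, size=n)
    intensities = rng.uniform(170, 230, size=n)
    for flat, rad, inten in zip(centers, radii, intensities):
        cr, cc = divmod(int(flat), w)
        r0, r1 = max(0, int(cr - rad - 1)), min(h, int(cr + rad + 2))
        c0, c1 = max(0, int(cc - rad - 1)), min(w, int(cc + rad + 2))
        rr, ccs = np.mgrid[r0:r1, c0:c1]
        disk = (rr - cr) ** 2 + (ccs - cc) ** 2 <= rad**2
        clean[r0:r1, c0:c1][disk] = np.maximum(clean[r0:r1, c0:c1][disk], inten)
    return clean


def _clean_factor_channels(
    spec: PhantomSpec,
    masks: Mapping[str, np.ndarray],
    clean_nuclear: np.ndarray,
) -> dict[str, np.ndarray]:
    nuclei = clean_nuclear > 0
    clean: dict[str, np.ndarray] = {}
    for ch in FACTOR_CHANNELS:
        acc = np.zeros((spec.height, spec.width), dtype=float)
        for comp, expr in spec.compartment_expression.get(ch, {}).items():
            mask = masks[comp]
            if expr.nuclear_mode == "uniform":
                fld = _gradient_field(mask, expr)
            elif expr.nuclear_mode == "internuclear":
                fld = _gradient_field(mask & ~nuclei, expr)
            else:  # nuclear: factor rides on the nuclei, scaled to their brightness
                fld = np.where(mask & nuclei, clean_nuclear * (expr.mean / 200.0), 0.0)
            acc = np.maximum(acc, fld)
        clean[ch] = np.asarray(clip_u8(acc), dtype=np.uint8).astype(float)
    return clean


def observed_from_clean(
    spec: PhantomSpec, clean: Mapping[str, np.ndarray], rng: np.random.Generator
) -> dict[str, GrayImage8]:
    """Apply the acquisition model: leakage, background, noise, clipping.

    observed_green = clip(clean_green + leakage_red_to_green * clean_red
    + background + noise), and symmetrically for red; the nuclear channel
    receives background and noise only.
    """
    h, w = spec.height, spec.width
    pre = {
        "nuclear": clean["nuclear"].astype(float),
        "green": clean["green"] + spec.leakage_red_to_green * clean["red"],
        "red": clean["red"] + spec.leakage_green_to_red * clean["green"],
    }
    out: dict[str, GrayImage8] = {}
    for ch in CHANNELS:
        noisy = pre[ch] + spec.background_level
        if spec.background_noise_sd > 0:
            noisy = noisy + rng.normal(0.0, spec.background_noise_sd, size=(h, w))
        out[ch] = GrayImage8(clip_u8(noisy), pixel_size=spec.pixel_size, channel_tag=ch)
    return out


def _domain_fractions(clean: Mapping[str, np.ndarray], masks: Mapping[str, np.ndarray]) -> dict:
    fractions: dict[tuple[str, str], float] = {}
    whole = np.ones(next(iter(clean.values())).shape, dtype=bool)
    regions = dict(masks)
    regions["whole_frame"] = whole
    for ch in FACTOR_CHANNELS:
        expressed = clean[ch] >= GROUND_TRUTH_THRESHOLD
        for comp, mask in regions.items():
            area = int(mask.sum())
            frac = 100.0 * int((expressed & mask).sum()) / area if area else 0.0
            fractions[(ch, comp)] = frac
    return fractions


def _coloc_fractions(clean: Mapping[str, np.ndarray]) -> dict[tuple[str, str], float]:
    out: dict[tuple[str, str], float] = {}
    for a, b in (("green", "red"), ("green", "nuclear"), ("red", "nuclear")):
        am = clean[a] >= GROUND_TRUTH_THRESHOLD
        bm = clean[b] >= GROUND_TRUTH_THRESHOLD
        na = int(am.sum())
        out[(a, b)] = 100.0 * int((am & bm).sum()) / na if na else 0.0
    return out


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Generate one synthetic section; bit-identical for a fixed spec."""
    rng = np.random.default_rng(spec.seed)
    masks = compartment_geometry(spec)
    clean_nuclear = _place_nuclei(spec, ~masks["background"], rng)
    clean = _clean_factor_channels(spec, masks, clean_nuclear)
    clean["nuclear"] = clean_nuclear
    channels = observed_from_clean(spec, clean, rng)
    return Phantom(
        channels=channels,
        clean=clean,
        compartment_masks=masks,
        nuclei_mask=clean_nuclear > 0,
        true_domain_fraction=_domain_fractions(clean, masks),
        true_coloc_fraction=_coloc_fractions(clean),
        spec=spec,
    )


def negative_control_phantom(spec: PhantomSpec) -> Phantom:
    """Phantom with primary antibodies omitted: factor channels carry only
    background, noise and a small bleed of the nuclear signal; all factor
    ground-truth fractions are zero by construction."""
    rng = np.random.default_rng(spec.seed)
    masks = compartment_geometry(spec)
    clean_nuclear = _place_nuclei(spec, ~masks["background"], rng)
    zero = np.zeros((spec.height, spec.width), dtype=float)
    clean = {"nuclear": clean_nuclear, "green": zero, "red": zero.copy()}
    h, w = spec.height, spec.width
    bleed = NEGATIVE_CONTROL_NUCLEAR_BLEED * clean_nuclear
    channels: dict[str, GrayImage8] = {}
    for ch in CHANNELS:
        base = clean_nuclear if ch == "nuclear" else bleed
        noisy = base + spec.background_level
        if spec.background_noise_sd > 0:
            noisy = noisy + rng.normal(0.0, spec.background_noise_sd, size=(h, w))
        channels[ch] = GrayImage8(clip_u8(noisy), pixel_size=spec.pixel_size, channel_tag=ch)
    return Phantom(
        channels=channels,
        clean=clean,
        compartment_masks=masks,
        nuclei_mask=clean_nuclear > 0,
        true_domain_fraction=_domain_fractions(clean, masks),
        true_coloc_fraction=_coloc_fractions(clean),
        spec=spec,
    )


def negative_marker_points(
    phantom: Phantom, n: int = 32, seed: int = 0
) -> MarkerPointSet:
    """Sample marker points inside ground-truth negative structures.

    Points are drawn where both clean factor channels are zero — nuclei
    and background outside every expression domain — so they read only
    autofluorescent background (plus noise) in the observed factor
    channels.
    """
    negative = (phantom.clean["green"] == 0) & (phantom.clean["red"] == 0)
    idx = np.flatnonzero(negative)
    if idx.size == 0:
        raise ValueError("phantom has no negative pixels to place markers in")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(idx, size=min(n, idx.size), replace=False)
    w = phantom.spec.width
    pts = tuple((int(f) // w, int(f) % w) for f in chosen)
    return MarkerPointSet(pts, expected_negative=True)


# ---------------------------------------------------------------------------
# serialization: per-channel TIFF + JSON sidecar with RLE masks


def rle_encode(mask: np.ndarray) -> list[list[int]]:
    """Run-length encode a boolean mask (row-major [start, length] runs)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    if not flat.any():
        return []
    padded = np.concatenate(([False], flat, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return [[int(s), int(e - s)] for s, e in zip(starts, ends)]


def rle_decode(runs: list[list[int]], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(shape[0] * shape[1], dtype=bool)
    for start, length in runs:
        flat[start : start + length] = True
    return flat.reshape(shape)


def _spec_to_dict(spec: PhantomSpec) -> dict:
    d = {k: getattr(spec, k) for k in (
        "width", "height", "pixel_size", "stage_label", "background_level",
        "background_noise_sd", "leakage_green_to_red", "leakage_red_to_green",
        "nucleus_density", "seed",
    )}
    d["compartment_expression"] = {
        ch: {comp: vars(expr) for comp, expr in comps.items()}
        for ch, comps in spec.compartment_expression.items()
    }
    return d


def spec_from_dict(d: dict) -> PhantomSpec:
    d = dict(d)
    expr = {
        ch: {comp: GradientExpression(**params) for comp, params in comps.items()}
        for ch, comps in d.pop("compartment_expression", {}).items()
    }
    if expr:
        d["compartment_expression"] = expr
    return PhantomSpec(**d)


def save_phantom(phantom: Phantom, outdir) -> None:
    """Write per-channel 8-bit TIFFs plus a JSON sidecar (RLE masks,
    ground truth, spec)."""
    from .image import imwrite_gray8

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for ch, img in phantom.channels.items():
        imwrite_gray8(outdir / f"{ch}.tif", img)
    sidecar = {
        "spec": _spec_to_dict(phantom.spec),
        "shape": [phantom.spec.height, phantom.spec.width],
        "masks_rle": {k: rle_encode(v) for k, v in phantom.compartment_masks.items()},
        "nuclei_rle": rle_encode(phantom.nuclei_mask),
        "true_domain_fraction": {f"{ch}/{comp}": v for (ch, comp), v in phantom.true_domain_fraction.items()},
        "true_coloc_fraction": {f"{a}/{b}": v for (a, b), v in phantom.true_coloc_fraction.items()},
    }
    (outdir / "phantom.json").write_text(json.dumps(sidecar))


def load_phantom(indir) -> Phantom:
    """Regenerate a saved phantom from its sidecar spec (bit-identical by
    seeded determinism)."""
    indir = Path(indir)
    sidecar = json.loads((indir / "phantom.json").read_text())
    return generate_phantom(spec_from_dict(sidecar["spec"]))
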