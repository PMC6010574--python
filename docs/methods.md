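# Methods

This note documents the models, conventions and numerical choices behind
`toothmap`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The quantification model

All analysis happens in the 8-bit pixel-intensity dialect of the
acquisition workflow: values in [0, 255], saturating arithmetic, and
rounding half-up (`floor(x + 0.5)`), so results match what an integer
image editor would produce rather than what unconstrained float
arithmetic would.

### Dark-point background equalization

Autofluorescent background is removed by repeatedly raising the black
point of the histogram. Marker points placed in structures known to be
negative for the stain (nuclei for antibody channels, inter-nuclear
spaces for the nuclear dye) are read before each pass; the pass remaps
`v → round(255 · max(0, v − d) / (255 − d))` with dark point
`d = min(max marker intensity, target + 10)`, and iteration stops once
every marker reads at or below the target (default 15) or after three
passes. The cap of `target + 10` on a single pass is our design choice:
the original presets behind the triple adjustment are not recoverable,
and an uncapped pass at a noisy marker maximum could clip dim true
signal; three capped passes reach the same endpoint more gently. The
remap is monotone, never increases a pixel, and fixes 0 and 255. A
white-point stretch exists (`white_point_stretch`) but is off the
default path, since only the black point is needed to meet the 0–15
background criterion.

### Leakage subtraction

Bleed-through correction is literal counter-channel subtraction —
`green' = clip(green − red, 0)` and symmetrically — followed by a 3×3
median filter (radius configurable, 0 disables). This is deliberately
*not* scaled spectral unmixing: the procedure being modeled subtracts
the full counter-signal, which guarantees that at most one channel is
nonzero per pixel before filtering and makes the operation idempotent
once channels are separated. The cost is that mutual leakage also
removes genuine co-located signal; co-localization analysis therefore
runs on dark-point-adjusted but (by default) unsubtracted channels when
both factors are expected in the same compartment.

### Threshold banding and domains

Bands are built exactly as the colorize–merge–subtract construction
implies: threshold masks are inclusive (`v ≥ t`), the overlap of
consecutive masks is the higher mask, and subtracting it leaves the
half-open interval `[tᵢ, tᵢ₊₁)`. With the seven default levels
(15, 30, 45, 55, 70, 85, 95) this yields six subtraction products plus
the raw top band (≥ 95, labeled yellow) — reconciling "six new images"
with seven listed band colors. The interval convention was the one
genuinely open decision; half-open intervals are forced by the
subtraction construction itself (each pixel lands in exactly one band).
Domain size is `100 · |{p ∈ ROI : v(p) ≥ 15}| / |ROI|`. ROIs are
supplied masks (phantom-derived in the pipeline), never auto-segmented,
mirroring manually drawn regions. Magnification is metadata only;
nothing is resampled. Sample-unit bands tile 15–95 in 5-pixel
increments (16 per image); each band's ROI-fraction is one statistical
observation.

### Densitometry

The pixel→OD curve interpolates step-tablet readings piecewise-linearly
over pixel value. Linear interpolation was chosen over splines because
it is exact at the knots and preserves monotonicity unconditionally;
readings whose OD fails to decrease strictly with pixel value are
rejected rather than repaired — an anti-monotone reading means the
tablet was misread, and silently reordering calibration data would hide
that. Pixels outside the measured range clamp to the endpoint OD,
avoiding negative or over-range densities. The synthetic tablet
(`synthetic_step_tablet`) is a stand-in wedge: 21 equal OD steps over
0.05–3.05 mapped to a linearly decreasing pixel ramp; it reproduces the
tablet's structure (step count and density range), not the proprietary
step values. Plot profiles reduce each row by mean (default) or max —
the original reduction is not documented — at positions `row ×
pixel_size` in cm.

### Co-localization

The visual scatterplot reading is made numerical as: Pearson r and an
overlap fraction (percentage of A-positive pixels also B-positive)
over *qualifying* pixels, those with either channel at or above the
baseline 15. Co-absent background is excluded because joint emptiness
is not co-localization. The nuclear call requires the reference to be
the nuclear channel with r ≥ 0.5 and overlap ≥ 50%; non-nuclear
requires both below; anything else is mixed. These cutoffs are
explicitly pragmatic defaults (configurable), not a published
convention. A channel that is constant over the qualifying pixels gets
r = 0 (no measurable linear association). Serial co-localization holds
the reference at baseline and raises the probe threshold through the
first four hotmap levels (15, 30, 45, 55 — the probe levels were not
stated numerically); masks nest by construction, and the series is
flagged baseline-only when the lowest level's overlap area exceeds the
next level's by more than 2× (configurable). Manders coefficients and
Costes randomization are intentionally out of scope.

### Rank statistics

Kruskal–Wallis H (tie-corrected) and Dunn's z are assembled directly
from the definitions (see README for the formulas), with p-values from
the χ² and normal upper tails. The chi-square approximation is used at
every sample size; no exact permutation is attempted, so p-values for
groups with fewer than ~5 observations are approximate. Dunn's
adjustment defaults to Bonferroni over all k(k−1)/2 pairs (the
documented behavior of the usual commercial implementation), with Holm
and none available. `compare_domains` flags a pair only when the
omnibus test *and* the adjusted pairwise p both clear α — post hoc
conditional on the omnibus, which is what keeps the familywise error at
the nominal level in the null-study test. Its observations are
sample-unit-image fractions; bands from one section are
pseudo-replicates, not independent specimens, and the report carries
that caveat.

## The phantom: what it emulates, what it does not

The phantom generates what the pipeline consumes, not what a microscope
sees. It emulates: an epithelial shell enclosing a mesenchymal papilla
with cervical loops and an inner-epithelial interface band (parametric
ellipses/disks — correct topology, no anatomical fidelity),
constant-intensity nuclei disks at ~4 per 1000 px², per-compartment
factor expression with linear gradients, additive background (default
level 25) with Gaussian noise (default SD 3, clipped and rounded), and
linear spectral bleed-through (defaults 0.15 green→red, 0.10
red→green). Ground truth is counted on the clean rasters — before
leakage, background and noise — at threshold 15, the same baseline the
measurement stages use, which makes generator truth and
`DomainMeasurement` directly commensurable.

It does **not** emulate: point-spread blur, chromatic aberration,
non-uniform illumination, staining texture (real profiles can be
"flat" or "spiky"; phantom texture is a free knob, deliberately
uncalibrated), nuclear heterochromatin structure, or section-to-section
variability. Passing tests therefore demonstrate that the *measurement
machinery* is correct and self-consistent under a known generative
model — not that the biological conclusions drawn from real tissue
would be robust to optics or staining artifacts.

Default frame size is 256×192 px (the acquisition aspect ratio scaled
down so the full suite and the acceptance script run in seconds);
`pixel_size` defaults to 0.01 cm/px on the calibrated print scale used
for profiles. A `nuclear_mode` per expression entry ("uniform",
"internuclear", "nuclear") controls sub-cellular placement so that
co-localization pattern calls have a constructible truth. The
negative-control phantom zeroes the factor signal and adds a 2% nuclear
bleed, emulating acquisitions with primary antibodies omitted.

## Determinism and problem sizes

Every stochastic component draws from `numpy.random.default_rng` seeded
from an explicit integer; the pipeline splits its root seed per stage
via `SeedSequence.spawn` (reduced mod 2³¹) and records the registry in
the run manifest, whose artifact checksums are reproducible across
reruns. Test and acceptance problem sizes — 200 random 64×64 images for
band-oracle equivalence, 20 phantom seeds for background and
ground-truth recovery, 100 small datasets plus 2000 type-I replicates
for the rank statistics — were chosen as the smallest sizes at which
the properties are statistically meaningful.

## Known limitations

- Plain counter-channel subtraction under-reports genuinely co-located
  signal (see above); it is the modeled procedure, not the best
  possible unmixing.
- The pattern-call cutoffs (r ≥ 0.5, overlap ≥ 50%) are arbitrary
  defaults; real nuclear/non-nuclear boundaries depend on cell density.
- Rank tests treat sample-unit images as independent observations;
  specimen-level correlation is not modeled (no mixed effects).
- The calibration curve accepts any ≥2 readings; it does not hard-code
  the 19-measurement convention sometimes quoted for 21-step tablets.
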