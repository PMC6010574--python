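# toothmap

Quantification of immunofluorescence expression domains in histological
sections of developing tooth germs — the image-analysis workflow used to
map cell-surface heparan sulfate proteoglycans (syndecans 1–4) and
HS-metabolism enzymes (EXT1, NDST1/2, HPSE1) across odontogenesis stages
(bud → cap → bell), rebuilt as a tested, reusable Python pipeline.

The package is aimed at researchers quantifying stained-factor
distribution in 8-bit fluorescence photomicrographs, and at anyone who
needs a fully synthetic, ground-truthed test bed for that kind of
pipeline.

## What it computes

Given 8-bit channels (DAPI-like nuclear, green, red), the pipeline:

1. **Background equalization** (`preprocess`): iterative dark-point
   level adjustment. Marker points are placed in structures known to be
   negative for the stain; each pass raises the black point *d* and
   remaps `v → round(255·max(0, v−d)/(255−d))` until all markers read
   ≤ 15 (at most three passes). Red↔green bleed-through is then removed
   by mutual counter-channel subtraction with median filtering.
2. **Threshold banding** (`banding`): seven thresholds
   (15, 30, 45, 55, 70, 85, 95) per image; consecutive threshold masks
   are merged and their overlap subtracted, producing six band images
   over half-open intervals `[tᵢ, tᵢ₊₁)` plus the open top band (≥ 95),
   pseudo-colored and merged into a composite **hotmap**. The
   **expression domain** is the area ≥ 15, reported as % of an ROI;
   finer 5-pixel sample-unit bands over 15–95 are the statistical
   observation unit.
3. **Densitometry** (`densitometry`): a monotone pixel→OD conversion
   curve from 21-step calibration-tablet readings (0.05–3.05 OD), OD
   surface grids and cm-calibrated vertical plot profiles.
4. **Co-localization** (`coloc`): exact 256×256 intensity scatterplots,
   Pearson r + overlap fraction over above-baseline pixels with a
   nuclear / non-nuclear / mixed pattern call, and serial-threshold
   overlap of a baseline-held reference with a rising-threshold probe
   (flagging baseline-only co-localization).
5. **Statistics** (`stats`): tie-corrected Kruskal–Wallis

   H = [12/(N(N+1)) Σᵢ nᵢ r̄ᵢ² − 3(N+1)] / [1 − Σⱼ(tⱼ³−tⱼ)/(N³−N)]

   followed by Dunn's post hoc

   z = (r̄ᵢ − r̄ⱼ) / √[(N(N+1)/12 − ΣT/(12(N−1)))(1/nᵢ + 1/nⱼ)]

   with Bonferroni adjustment, at α = 0.05.
6. **Phantom** (`phantom`): seeded synthetic tooth-germ sections
   (epithelial shell, mesenchymal papilla, cervical loops, inner-enamel
   band, nuclei, gradients, background, noise, linear bleed-through)
   with exact ground-truth masks and fractions, so every stage above is
   testable without tissue.

`pipeline.run_study` chains all of it per developmental stage and writes
hotmaps, domain/sample-unit tables, OD profiles, co-localization JSON, a
rank-test report and a check-summed run manifest.

## Worked example

```python
import numpy as np
from toothmap import (PhantomSpec, ROIMask, dark_point_adjust, domain_size,
                      generate_phantom, leakage_subtract, negative_marker_points)

phantom = generate_phantom(PhantomSpec(seed=1))         # cap stage, bg 25, noise 3
markers = negative_marker_points(phantom, n=32, seed=2)
green, rec = dark_point_adjust(phantom.channels["green"], markers, target=15)
red, _ = dark_point_adjust(phantom.channels["red"], markers, target=15)
green, red = leakage_subtract(green, red)
print("dark points:", rec.dark_points, "residual:", rec.residual_max)

roi = ROIMask(np.ones(green.shape, dtype=bool), "whole_frame")
m = domain_size(green, roi, factor="sdc1", stage="cap")
print(f"domain: {m.fraction:.1f}% of ROI "
      f"(truth {phantom.true_domain_fraction[('green', 'whole_frame')]:.1f}%)")
```

prints

```
dark points: (25,) residual: 6
domain: 27.2% of ROI (truth 27.2%)
```

The single dark-point pass at 25 pushes the autofluorescent background
(level 25, noise SD 3) to a residual of 6 — inside the 0–15 background
criterion — and after leakage subtraction the measured green expression
domain recovers the generator's ground truth.

A full study run:

```sh
toothmap run --config study.yaml     # or: python -m toothmap.cli run ...
```

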