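# Methods

## Problem and model

A side-view micrograph of a cleared leaf shows a bright translucent
background, a leaf band along the bottom whose surface edge images dark,
and dark hair-like trichomes rooted on that surface. Counting them is an
instance segmentation problem that classical image processing can only
approximate, because trichomes occlude one another in projection and
debris mimics small hairs. The package therefore implements a family of
estimators of increasing human input, all defined on a 1-px skeleton of
the dark structures, and quantifies each estimator's failure modes on
synthetic scenes with exact ground truth.

### Preprocessing

1. **Lightness.** The image is converted to CIE L\*a\*b\* (D65, via
   scikit-image) and only L\* (0–100) is kept. Trichome/leaf contrast
   lives almost entirely in lightness; hue varies with clearing chemistry
   and illumination, so it is discarded.
2. **Segmentation.** A global threshold on L\*. Default `"auto"` uses
   Otsu's criterion — the 256-bin histogram split maximizing between-class
   variance — with the *minority* class taken as trichomes (they are
   sparse relative to the background); both the threshold and the polarity
   can be fixed in `PreprocessConfig`. A segmentation in which every pixel
   (or no pixel) is foreground raises a degenerate-segmentation error
   rather than propagating nonsense.
3. **Mask smoothing.** The binary mask is blurred as 0/1 reals with a
   Gaussian (`gaussian_sigma`, default 1 px) and re-thresholded at 0.5.
   This deletes sub-resolution speckle while leaving solid-region
   interiors unchanged. Smoothing precedes thinning because blurring a
   1-px skeleton would destroy its thinness; an optional
   `post_skeleton_sigma` adds a second low-pass pass (followed by
   re-thinning) for noisy skeletons.
4. **Component filtering.** 8-connected components; `largest` (default)
   keeps the single biggest component — the leaf band plus every trichome
   rooted on it — which removes all detached debris; `area_threshold`
   keeps every component of at least `min_component_area` px, the right
   choice when the surface band is fragmented.
5. **Thinning.** Morphological thinning to a 1-px skeleton, preserving
   the number of 8-connected components and idempotent on thin input.
   Thinning can leave a fully-foreground 2×2 block where two 1-px
   diagonals cross at offset positions; a pruning pass deletes such block
   pixels **only when they are simple points** (their removal provably
   preserves local connectivity). Connectivity wins over strict thinness
   on those degenerate configurations, because component and crossing
   counts depend on it; on mask-like inputs (structures wider than 1 px)
   the final skeleton never contains a 2×2 block.

Conventions throughout: row 0 at the top, so the leaf sits at large row
indices and "upward" means decreasing row; 8-connectivity everywhere.

### Counting

**Endpoints.** Skeleton pixels with exactly one 8-neighbor. A *free*
endpoint is one farther than `base_exclusion` (default 3 px) vertically
from the base curve — every filament owns one non-free root endpoint at
the surface — and at least `border_margin` (default 5) columns from the
left/right edge, mirroring the manual-counting rule that trichomes
emerging from the image border are not counted. The count of free
endpoints estimates the count of trichomes. Fails in both directions:
surviving debris adds endpoints; occlusion (a tip resting on another
stalk) removes them.

**Surface contouring.** The base curve is the lowest foreground pixel per
column (gaps interpolated linearly, edges extended by nearest value). The
offset is h/(n_curves+1) in the default *interior* mode, where h is the
vertical extent of the skeleton's occupied rows — curves then sit strictly
between surface and tips; *inclusive* mode (h/n_curves) puts the last
curve at tip height, where it intersects almost nothing, and exists for
comparison. Each of the `n_curves` (default 4) upward translations
(`round(k·offset)` px, clipped at row 0) is rasterized as an 8-connected
1-px path; a **crossing** is a maximal run of consecutive columns whose
path pixel 8-touches the skeleton, with runs separated by ≤
`gap_tolerance` (default 2) columns merged — a single slanted skeleton
line otherwise counts several times through rasterization — and runs
entirely inside the border margin discarded. Per-curve counts are
integers; the reported count is their unrounded mean. The annotated
variant replaces the detected base curve with a supplied one; everything
else is identical.

**Intersection curve.** One human-drawn curve through the stalks, counted
with the same crossing definition (`n_curves = 1`).

### Evaluation

OLS of predicted on reference counts (SciPy `linregress`): R², slope,
intercept, two-sided *P* for the slope. RMSE is computed on the raw
differences `predicted − reference`, *not* on regression residuals, so a
calibrated-looking regression cannot hide a systematic bias.
`evaluate_by_group` repeats this per group (repetition, genotype, noise
level), skipping groups with n < 3 or a constant reference with a warning.

## Synthetic scenes

`generate_scene` renders what the estimators assume: a smooth sinusoidal
surface (`base_amplitude`/`base_wavelength`, default 4 px / 180 px) drawn
as a dark 2-px strip near the bottom third of a 640×300 canvas, and
`n_trichomes` quadratic arcs rooted on it (length 60 ± 6 px, thickness
2 px, angle SD 6° from vertical, lateral bow ≤ 3 px), rendered at L\* 15
on an L\* 85 background and converted to RGB through CIE Lab so the
lightness conversion is exercised end to end. All randomness flows from
one generator seeded with `spec.seed`; a spec is bit-reproducible.

Design points that matter for interpretation:

* **Non-occlusion is enforced, not hoped for.** With
  `occlusion_bias = 0`, roots keep ≥ `min_root_spacing` (9 px) and each
  filament is confined to a lane that keeps ≥ 7 px horizontal clearance
  from its neighbors at every height — enough that crossing runs never
  merge under the default `gap_tolerance`. With `occlusion_bias > 0`,
  each filament (after the first) independently, with that probability,
  has its tip placed *exactly on* its left neighbor's stalk at 55–75% of
  the neighbor's height — the configuration in which the endpoint method
  loses exactly one endpoint per occlusion. Occlusion is Bernoulli per
  filament rather than a fixed fraction so that its effect on a sweep
  carries binomial scatter, as overlap in real projections does.
* **The oracle curve is a guarantee, not a heuristic.** It parallels the
  base at 0.3× the mean filament length; filament lengths are truncated
  below so every filament (occluded ones included) crosses it, and the
  generator verifies this and refuses to emit a scene violating it.
* **Speckles** are short dark strokes (default length 5 px) placed away
  from filaments and recorded in `noise_mask`. They are removed entirely
  by largest-component filtering; under `area_threshold` filtering they
  survive and each contributes spurious endpoints — the two filtering
  strategies bracket the realistic noise regimes.
* **What is not emulated:** texture, veins, depth of field, illumination
  gradients, glandular heads, trichome branching, and sub-pixel
  anti-aliasing of real optics. Passing tests show the *estimators* are
  correct and exhibit the documented failure modes under controlled
  geometry; they do not certify segmentation quality on real micrographs,
  where thresholding is the fragile step.

`SceneSpec.noiseless(n, seed)` is the verification preset: equal lengths,
flat base, near-vertical filaments (angle SD 2°), no noise or occlusion.
Equal lengths are essential for *exact* recovery by the contour method —
the offset derives from the common band height h, and with varying
lengths the upper curves pass above the shorter trichomes, an undercount
that is a property of the method (visible on the default, realistic
conditions) rather than a rendering artifact.

## Numerical choices

* Otsu operates on a 256-bin histogram of the L\* values; ties in the
  between-class variance resolve to the lowest candidate.
* Mask smoothing re-thresholds at ≥ 0.5, so a half-plane edge is stable.
* Curve translation rounds the offset to whole pixels before shifting;
  rows clip at 0.
* Polyline annotations are sorted by column; duplicate columns are
  averaged; profiles extrapolate by nearest endpoint value and clip to
  the image.
* Overlay extraction accepts pixels within ±60/channel of pure yellow
  (255,255,0) or red (255,0,0) and takes the per-column mean row, making
  it invariant to symmetric stroke thickness; it requires ≥ 50% column
  coverage.
* Degenerate inputs fail loudly: empty masks, uniform images, constant
  references, single-row skeletons each raise a typed error; an empty
  skeleton yields an endpoint count of 0 with a warning (a legitimately
  glabrous image is not an error).

## Problem sizes

The verification suite and `scripts/acceptance.py` use 640×300 scenes: 50
clean scenes (counts 5–40) for exact recovery, 30-scene sweeps (counts
10–60, 5 replicates each) for the R² comparisons, and 12 speckled scenes
for the noise-inflation numbers. These sizes give stable statistics while
keeping a full run in the low minutes on one core.

## Known limitations

* The automated contour method inherits every base-detection failure; on
  leaves with strong surface clutter the annotated variants are the only
  reliable ones (this is reproduced by the corrupted-base experiments).
* Crossing counts saturate when distinct trichomes pass within
  `gap_tolerance` columns of each other at curve height; dense scenes
  undercount even with a perfect annotation curve.
* The endpoint method's two failure modes (noise ↑, occlusion ↓) can
  cancel on average while both inflate scatter; its mean being right is
  not evidence it works.
* Real-image thresholds may need manual `lightness_threshold` overrides
  when clearing is uneven; the auto threshold assumes a bimodal
  lightness histogram.
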