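# Methods

## The measurement problem

An anti-dsDNA antibody stains every double-stranded DNA species in a cell:
the nucleus, the mitochondrial nucleoids, cytoplasmic DNA of nuclear origin,
and the quantity of interest — mitochondria-derived DNA that has escaped into
the cytosol.  Direct gating on "dsDNA outside organelles" is unreliable,
because membrane markers cannot distinguish DNA inside a mitochondrion from
DNA sitting beside one.  The approach implemented here instead *subtracts*
the confounders photometrically: a mitochondrial-matrix marker (Hsp60) and a
nuclear marker (histone H2B) are scaled and subtracted from the dsDNA
channel, so that in a control cell nothing survives, and in a pathological
cell only marker-free cytoplasmic dsDNA puncta remain to be counted.

## Calibration of the subtraction factors

The factors are *defined* by their effect on controls: `x` is the smallest
multiplier for which `dsDNA − x·Hsp60 ≤ 0` over the mitochondrial signal of
control images, and `y` the analogue for `dsDNA − y·H2B` over nuclei.
Operationally:

* the mitochondrial mask is "Hsp60 above its threshold" (Otsu of the positive
  pixels, or a fixed value), the nuclear mask "H2B above its threshold";
* `x` is the q-quantile of the pixelwise ratio `dsDNA/Hsp60` pooled over the
  masked pixels of all control images of the batch, `y` likewise with H2B.
  `q = 1` (the maximum) reproduces the defining rule exactly; the default
  `q = 0.999` tolerates one pixel per thousand (hot pixels, rare noise
  excursions) and uses the "higher" order statistic, so at most a fraction
  `1 − q` of masked control pixels can show a positive residual;
* ratios are never formed where the denominator is below its threshold.

One `(x, y)` pair is estimated per experiment batch by pooling all control
images, and applied unchanged to every condition (per-image factors, if ever
wanted, are just the estimator applied to a single-image list).  `verify_factors` reports, per
control image, the fraction of masked pixels with positive residual — 0 at
`q = 1` by construction.  Raw intensities are used; no background
subtraction is applied by default.

Three estimator details matter in practice, all tunable:

* **Pre-smoothing** (`smooth_sigma`, default 1.5 px).  The ratio of two
  proportional signals is invariant under linear smoothing, but the noise of
  a per-pixel ratio is not: smoothing shrinks it by roughly the kernel norm
  (≈ 3.8× at σ = 1.5), which an extreme quantile needs — without it the
  q = 0.999 ratio tail is pure noise and the factors overshoot by ~20% at a
  noise level of 5% of signal.
* **Mask erosion** (`mask_erosion_px`, default 2).  Pixels at the mask rim
  have denominators near the threshold; their ratio variance diverges.
  Eroding each marker mask keeps only interior pixels.
* **Cross-marker exclusion** (`exclusion_radius_px`, default 12).  The
  point-spread and smoothing kernels have finite support (truncated at 4σ);
  excluding a buffer of that radius around the *other* marker's mask
  guarantees that nuclear signal never leaks into the mitochondrial ratio
  and vice versa.  This is what makes the noiseless recovery *exact* rather
  than approximate.

With these defaults the estimated factors land within ~11% of the true bleed
factors on the synthetic benchmark at 5%-of-signal noise (the estimator is
one-sidedly conservative: quantiles of a noisy non-negative ratio overshoot,
which errs toward suppressing false puncta rather than creating them).

## Subtraction and contrast

`Subtract-1 = clip(dsDNA − x·Hsp60, 0)` keeps nuclear signal;
`Subtract-2 = clip(dsDNA − x·Hsp60 − y·H2B, 0)` removes it too.  Negatives
are clipped: display-level image subtraction saturates at zero and the
thresholding stage assumes non-negative input.  An optional linear contrast
window, identical for every image of a batch (default `(0, 99.9th percentile
of the pooled subtracted controls)` via `auto_window`), rescales to [0, 1];
an optional pre-subtraction window on the multiplied marker image exists for
batches where the multiplication raises the background, and is off by
default.

## Binarization and particle classification

The subtracted image is binarized at an Otsu threshold computed on its
*non-zero* pixels (the clipped zero background would otherwise dominate the
histogram); `≥ threshold` is foreground, an all-zero image gives an empty
mask with a warning.  Two numerical choices proved load-bearing:

* **Denoise–threshold split.**  `detect` smooths the subtracted image
  (`denoise_sigma`, default 1 px) before masking — a punctum a few pixels
  across sits barely above the per-pixel noise floor, and averaging over its
  footprint restores the bimodality an automatic threshold needs — but the
  threshold itself is estimated from the **raw** subtracted pixels.
  Estimating it from the denoised image fails on signal-free fields: with
  the noise scale smoothed away, Otsu splits the residual noise and floods a
  control field with mid-size noise blobs.
* **Subtract-1 thresholding.**  When H2B is not subtracted, nuclei dominate
  the intensity histogram and would capture the Otsu split; the threshold is
  therefore estimated from histone-negative pixels only (the
  histone-positive ones are discarded by the overlap rule anyway).
* **Batch thresholding.**  `batch_threshold` pools the subtracted non-zero
  pixels of all fields of a batch into one Otsu threshold, the automated
  analogue of adjusting display conditions "the same for all samples".  Use
  it (CLI `--batch-threshold`) when conditions are analysed jointly;
  per-image thresholds remain the default for standalone fields.

Connected components (8-connectivity by default, as in common particle
analysis) are measured and classified by the first failing rule, so each
punctum carries exactly one auditable class:

1. **size** — area (pixel count × pixel area) outside the inclusive
   [2, 20] μm² window → `rejected_size`.  These are the adherent-HeLa
   defaults; the window is a parameter for other cell types.
2. **shape** — circularity `4π·area/perimeter²`, capped at 1, below 0.1 →
   `rejected_shape`.  Perimeter uses the weighted boundary-configuration
   estimator; small-object circularity differs between perimeter estimators,
   so shape assertions in the tests use discs of radius ≥ 5 px where
   estimators agree within a few percent.
3. **donut** — Euler number < 1, i.e. the component has a hole →
   `nuclear_origin_donut`.  Ring-shaped dsDNA arises from nuclear-origin
   cytoplasmic DNA whose weak histone co-signal survives subtraction only at
   the rim; topology is the most direct operationalisation.  Holes smaller
   than `fill_holes_below_um2` (default 0.5 μm²) are filled first: one- or
   two-pixel noise dropouts inside a genuine punctum are not lumina.
4. **histone overlap** — fraction of component pixels where `y·H2B` exceeds
   its Otsu threshold, above 0.3 → `nuclear_origin_overlap`.
5. otherwise `ectopic_mito`.

Manual review of original images is out of scope; instead every punctum row
in the CSV carries its measurements (area, perimeter, circularity, Euler
number, centroid, overlap fraction) so a human can audit any call.

## Cell counting and the summary statistic

Cells are counted as H2B nuclei: Gaussian smoothing, Otsu on positive
pixels, hole filling, an area floor (`min_nucleus_area_um2`, default 40 μm²,
required to exceed the puncta size cap so the two object classes cannot
overlap), and an optional distance-transform watershed that splits touching
nuclei (marker peaks at least one minimal nucleus radius apart on a smoothed
distance map; components without a peak keep their label so nuclei are never
lost).  Border-touching nuclei are counted — the ratio uses whole-field
counts and excluding them would bias the denominator.

The field-level statistic is `dots_per_cell = n_ectopic / n_cells`,
undefined (and excluded from group means, but tallied) when a field has no
cells.  Groups are summarised as mean ± SEM over fields — the per-image
ratio is the statistical unit, which avoids pseudo-replication — and
compared with the classical pooled-variance two-sided Student's t-test
(Welch behind a flag).  Identical constant groups raise an error rather
than reporting p = 0.  The per-condition table also reports the pooled
alternative (total puncta / total cells) since the choice of aggregation is
not obvious a priori.

## The synthetic benchmark

The generator renders 256×256 px fields at 0.25 μm/px with, by default,
5 nuclei (radius 4.5–6 μm, amplitude 0.8–1.0), a curvilinear mitochondrial
network (random-walk filaments dilated to ~3 px width, base intensity 0.6,
with bright nucleoid bumps to 1.0), and the three object classes the method
must separate: ectopic puncta (discs of 3–12 μm², amplitude 0.25), nuclear-
origin dots (dsDNA plus a supra-threshold H2B co-signal), and donuts
(annuli, outer radius 7 px, lumen 4 px, with a faint sub-threshold H2B
co-signal).  Channels are blurred with a Gaussian PSF (σ = 1 px) and receive
Gaussian noise of σ = 0.05 — 5% of full scale, so the default ectopic
punctum sits at SNR 5; a Poisson–Gaussian model is available.  In control
content the dsDNA channel is exactly `0.6·H2B + 1.5·Hsp60`: mitochondrial
dsDNA is rendered proportional to the matrix signal (nucleoids appear as
intensity bumps shared by both channels), which is precisely the
proportionality assumption the subtraction method itself makes, and it makes
the defining calibration property hold exactly in the noiseless limit.

Determinism: every structural layer (nuclei, network, puncta, dots, donuts,
noise) draws from its own child RNG of the scene seed.  Rendering is a pure
function of the scene spec, and enlarging one layer — adding histone dots to
a scene — leaves every other layer and the noise field bit-identical, which
is what makes the "confounders change the count by exactly zero" and
"+1 punctum ⇒ +1 count" checks exact rather than statistical.  Ectopic
puncta are placed ≥ 6 px clear of nuclei and the network (and ≥ 8 px from
each other) so ground-truth classes are unambiguous; placement failure after
bounded retries raises an explicit error.

The presets mirror the three experimental conditions: `control` has at most
one ectopic punctum and no nuclear dots; `tfam_kd` has 8–15 ectopic puncta
(mitochondrial-DNA destabilisation); `gba_kd` mixes 4–8 ectopic puncta with
3–6 histone-positive nuclear-origin dots.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: spatially varying background and illumination,
optical aberrations and vignetting, chromatic mis-registration between
channels, nuclear texture and nucleoli, genuinely filamentous (non-disc)
puncta, and out-of-focus light from neighbouring z-planes.  On real images
the calibration masks and the threshold choice should be inspected (the CLI
logs both, and `verify_factors` quantifies the control residuals).

## Benchmark sizes and observed behaviour

The test suite and the acceptance script run the benchmark at 20 seeds for
calibration recovery and detection (10 puncta per field at SNR 5), 10 fields
per group for condition comparisons, and 100 (tests) / 20 (script)
replicates for the power estimate; these sizes give stable statistics while
keeping a full run in the minutes range on one CPU.  Under those conditions
the pipeline recovers the bleed factors within 15%, detects ≥ 95% of
in-range puncta with ≤ 0.5 false calls per field, and separates knockdown
from control at p < 0.05 in every replicate.  All of these numbers are
recomputed, not stored, by `pytest tests/` and `scripts/acceptance.py`.

## Known limitations

* The quantile calibration is deliberately conservative under noise
  (estimates sit above the true bleed), trading a few percent of punctum
  intensity for zero control background.  Strongly non-proportional bleed
  (per-pixel spectral variation) is out of scope — no spatially varying
  unmixing is attempted.
* Puncta whose true area is near the 2 μm² floor can fall under it after
  thresholding (the detected area depends on the threshold relative to the
  spot profile); counts at the size boundary are threshold-sensitive, which
  is inherent to the fixed-window protocol.
* Circularity of objects a few pixels across is estimator-dependent.
* The analysis is strictly 2-D; z-stacks must be projected first
  (`max_project`), and 3-D puncta splitting across planes are not handled.
* Cells are equated with H2B-positive nuclei; multinucleated or mitotic
  cells bias the denominator.
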