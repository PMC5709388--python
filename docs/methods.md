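# Methods

## Problem and model

The package quantifies treatment response in 3D tumor cultures from one
image triplet per well: transmitted-light brightfield, calcein-AM
fluorescence (live cells) and propidium-iodide fluorescence (dead cells).
The unit of analysis is the individual organoid ("nodule"): a connected
dark silhouette in brightfield, indexed once and tracked through every
readout. Viability is an intensity ratio, not an absolute intensity, which
makes it robust to gain differences between experiments as long as the two
control groups (untreated and fixed/permeabilized "total killing" wells)
were used to set the acquisition so both channels span their dynamic range.

## Segmentation

**Adaptive thresholding.** The brightfield image is min–max rescaled to
[0, 1]; for dark objects the complement is thresholded against
`2·sensitivity · local_mean(·, w)` with `w = 65 px` and sensitivity 0.55.
The factor-of-two scaling is a design choice made because the reference
semantics of the sensitivity parameter in the original MATLAB routine are
not documented: with it, sensitivity 0.5 degenerates exactly to plain
local-mean thresholding and 0.55 demands a 10 % deviation above the local
mean, which gives the parameter an interpretable scale. The local mean uses
replicate padding at the borders (zero padding would produce edge halos).
A consequence of any local-mean scheme is that objects wider than the
neighborhood hollow out; the synthetic size distribution and the defaults
keep organoid diameters below ~65 px at 38.62 µm²/px. The rescale of a
constant image is undefined; such images yield an empty mask with a
warning.

**Size filter.** Objects below `min_object_area` (default 1950 µm²,
roughly five 400 µm² cells) are removed. Retention is inclusive
(area ≥ threshold); the boundary case is not specified more precisely by
the quantity's definition, so ≥ was fixed and documented. A second printed
value of this threshold, 1931 µm² (= 50 px at 38.62 µm²/px), circulates in
descriptions of the method; 1950 is the default here and the parameter is
fully configurable. Connected components use 8-connectivity by default so
touching organoid lobes count as one nodule; survivors are relabeled 1..N
in raster-scan order of their first pixel, making the indexing
deterministic.

**Otsu thresholding.** Implemented over an equal-width histogram
(default 256 bins) spanning [min, max] of the sample; every interior bin
edge is scored by between-class variance and the maximizing *edge* is
returned, ties to the lowest edge. Splits that fall inside a run of empty
bins produce identical partitions whose scores differ only by float
summation noise; they are treated as ties (relative tolerance 1e-9). The
test suite verifies exact agreement with an exhaustive within-class
variance minimizer and one-bin-width agreement with scikit-image's
bin-center convention.

**Focus filter.** The summed live+dead image is rescaled to [0, 1] and
binarized at its global Otsu threshold (all pixels, not object-restricted).
The default `pixelwise` mode intersects the brightfield mask with this
binarization and then re-applies the size filter — intersection can shrink
an object below the physical cut, and re-filtering keeps the area
invariant honest. A `whole_object` mode instead keeps an object intact iff
at least half of its pixels pass the cut; it exists because "multiplying"
the masks and "excluding out-of-focus organoids" suggest different
granularities and both are defensible. Pixelwise with re-filtering is the
default because it also removes bright-background noise blobs that survive
the brightfield stage. The focus filter's output is the definitive index
set.

## Background correction

Background is estimated only from no-treatment wells: the final mask is
dilated with a discrete disk of radius 2 px ((i, j) in the element iff
i² + j² ≤ r²), and the per-channel **median** over the remaining
inter-organoid pixels is taken per image, then averaged across control
images. The median is essential: detached fluorescent cells and debris
contaminate the inter-organoid space, and the mean overcorrects by ~9 %
already at 1 % contamination at 10× background. Subtraction is applied to
every image of the experiment and clipped at 0 — negative intensities are
non-physical and a negative mean would break the [0, 1] bound of the
viability ratio. An image whose dilated mask covers ≥ 99 % of pixels has
no background sample and is an error.

## Quantification

Per-object channel intensity is the arithmetic **mean** over the object's
pixels. The viability ratio is invariant to using sums instead (both
channels integrate over the same pixel set); the mean is reported so
`mean_live`/`mean_dead` do not scale with object size. An object with zero
intensity in both channels gets viability NaN (flagged missing, the object
row is kept so area statistics stay complete).

The live threshold is Otsu over the pooled within-mask live pixels of all
no-treatment images, times a factor (default 0.4). Pooling within-mask
avoids the empty background dominating the histogram; the 0.4 factor sets
the dynamic range between the total-killing anchor (no live area) and the
no-treatment anchor (live area ≈ total area) and is exposed in the config
because its optimal value is acquisition-dependent. Pixels count as live
under strict inequality ("exceeding" the threshold). The dead threshold is
calibrated symmetrically on the total-killing controls' dead channel —
the dead-area readout is defined by mirror symmetry with the live one, and
total-killing wells are the group in which the dead channel is guaranteed
to express its full range.

Normalized viability divides by the median viability of the no-treatment
objects (error if that median is 0).

## Analytics

Group summaries use the per-image median of each metric (robust to the
heavy-tailed size distribution) and report mean, SD (ddof = 1) and
SEM = SD/√n across images; images with zero objects are counted as dropped.
Histograms are left-closed/right-open with the last bin closed. Pairwise
readout relations use ordinary least squares (scipy's linregress; slope
standard error retained so slope differences can be judged against their
resolution). Dose-response uses a three-parameter exponential decay
`R(d) = plateau + (R0 − plateau)·exp(−k·d)`, all parameters bounded ≥ 0,
fitted by deterministic multi-start least squares over a fixed grid of
initial decay rates scaled by the dose range; ties in residual sum of
squares go to the smallest k. The model choice is a default — the
procedure is generic least squares and a linear model is selectable.
Heatmaps paint each object with its viability through the viridis map
(8-bit RGB, background black, magenta sentinel for undefined viability);
they are presentation artifacts, the CSV is the scientific output.

## Pipeline ordering

Brightfield masking needs no fluorescence and runs first; control wells
are segmented once on raw images solely to obtain masks for background
sampling, then — after subtraction — every well is re-segmented so the
focus filter sees corrected channels, and those label maps are the ones
all readouts use. Thresholds are calibrated on the corrected controls.
Every parameter, the background estimate, both thresholds and per-stage
object counts are echoed into the run report, so a run is reconstructible
from report + inputs.

## Synthetic scenes

The generator emulates what the pipeline must be robust to, not optics:

- **Geometry** — organoids are unions of 1–4 overlapping rotated ellipses
  (axis ratio 1–2.2), giving the lobed, non-spherical shapes of
  stroma-containing cocultures; true areas are log-normal (median
  20 000 µm², σ_log 0.45 — a few hundred cells per organoid at
  38.62 µm²/px, with the upper tail kept below the adaptive-threshold
  neighborhood). Masks are pairwise disjoint with a 3 px margin.
- **Viability field** — `v(p) = base · (1 − depth · c(p))` with `c` the
  boundary-distance transform normalized to 1 at the core: viability is
  lowest centrally, emulating hypoxic-core formation. Untreated wells use
  base 1.0 and depth 0.2 — intact cultures with a mild core gradient,
  consistent with untreated organoids whose live area equals their total
  area.
- **Rendering** — brightfield is a background level (1000 a.u.) times a
  ×0.7–1.3 diagonal illumination ramp, with organoid pixels darkened to
  50 %; live = 100 + 1000·v, dead = 100 + 1000·(1 − v) inside organoids.
  Equal channel gains encode the calibrated-acquisition assumption above.
  Noise is Gaussian with sd 10 + 1 % of signal, clipped at 0.
- **Clutter** — dark debris specks (radius ≤ 2 px, all below half the size
  cut), bright detached single cells in inter-organoid space (live-channel
  on viable wells; PI-positive on fixed total-killing wells), and
  out-of-focus organoids: sharp brightfield silhouette, fluorescence
  divided by 15 and blurred (σ = 4 px).
- **Treatments** — `uniform_kill` scales every viability field by
  `exp(−α·dose)` (α = 0.05, chemotherapy-like homogeneous action);
  `size_dependent_kill` by `exp(−α·dose·(A_ref/A)^γ)` with A_ref the median
  area and γ = 1, so small organoids are hit harder
  (photodynamic-therapy-like sparing of large organoids).

Named presets pin the regimes the validation suite scores:
`segmentation` (1024², 55 organoids, 15 % out of focus, full illumination
ramp), `quantification` (same geometry, in-focus, per-organoid base
viability spread uniformly over 0.05–0.95, no core gradient so each
organoid has a well-defined true viability), and `control` (512²
untreated-well geometry used for calibration wells and plates). All draws
derive from a single integer seed.

What the generator deliberately omits: point-spread functions and
diffraction, z-structure, spectral bleed-through, stain-uptake kinetics,
organoids touching each other, and texture inside silhouettes. Passing
tests therefore demonstrate correctness of the *computational* pipeline
under realistic geometry, illumination, noise and clutter — not robustness
to every optical artifact of a real confocal acquisition.

## Problem sizes and numerical notes

Validation runs use 512²–1024² single-precision-scale scenes with 14–55
organoids and plates of ~11 wells, sizes at which every stage's behaviour
(including the 2×2 mosaic path) is fully exercised while the whole suite
runs in well under a minute. Determinism is exact: identical inputs yield
byte-identical CSV outputs (fixed column order, `%.10g` float formatting),
and integer TIFF round-trips are pixel-identical.

## Known limitations

- The sensitivity semantics of the adaptive threshold are this package's
  own definition (see above); absolute mask agreement with the original
  MATLAB routine is not guaranteed, though all defaults (0.55, 65 px,
  1950 µm², 0.4, 2 px) match the reference parameters.
- The pixel scale is never assumed: 38.62 µm²/px is used by the synthetic
  presets, but real manifests must state `pixel_area` explicitly because
  published descriptions of comparable acquisitions are internally
  inconsistent about it.
- Merged organoids are indexed as one object (no watershed splitting);
  bright-background noise blobs are removed only by the focus filter, so
  fluorescence-free acquisitions would need a stricter sensitivity.
- No 3D/z information; the focus filter discards, rather than recovers,
  out-of-plane objects.
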