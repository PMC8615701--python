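# Methods

This note documents the models, algorithms and numerical choices behind
`organotrace`: an open pipeline for quantifying how 3D culture conditions
(scaffold overlays, position in a scaffold dome, organoid size) delay drug
effect in live-cell fluorescence imaging of prostate-cancer models, with a
synthetic-data generator that provides exact ground truth for every stage.

## The readouts

**Nuclear AR translocation.** Androgen binding moves the androgen receptor
(AR) from cytoplasm to nucleus. With EGFP-tagged AR, the per-cell readout
at each time point is

    ratio = n / (n + c),   n = max(nuc_mean − background, 0),
                           c = max(cyt_mean − background, 0)

where `nuc_mean` and `cyt_mean` are the mean EGFP intensities over the
nucleus and a perinuclear cytoplasmic ring. 0 means fully cytoplasmic,
1 fully nuclear. Region means (not sums) are used so the statistic is
insensitive to the different pixel counts of nucleus and ring; the raw
summed intensity is recoverable from the tables if wanted. Corrected
intensities are floored at 0, which keeps the ratio in [0, 1]; cells with
no signal above background in either region are flagged invalid and
excluded from aggregates. The ratio is invariant to any common intensity
rescaling of image and background.

**Tubulin stabilization.** Taxanes bundle microtubules, turning a diffuse
EYFP-β-tubulin signal into a fibrous texture. The readout is the Haralick
contrast of the gray-level co-occurrence matrix (GLCM) inside the total
cell area:

    contrast = Σ_{i,j} P(i, j) · (i − j)²

Defaults: 32 gray levels, four symmetric offsets at distance 1
((0,1), (1,0), (1,1), (1,−1)). The quantization range is held **fixed
across a time series** (by default the global in-mask range of the
series); without a fixed range, contrast changes would confound texture
with overall intensity rescaling. Contrast is therefore invariant to a
common intensity offset and reflects only local intensity jumps.

**Viability.** Luminescence viability responses follow the four-parameter
logistic (4PL) in dose,

    r(d) = bottom + (top − bottom) / (1 + (d / ec50)^hill),

with responses normalized to vehicle (dose 0) controls at 100%.

## Kinetic model and t½

All time-courses are fitted with a symmetric logistic in time,

    v(t) = baseline + (plateau − baseline) / (1 + exp(−(t − t50)/slope)),

and t½ is reported as the fitted `t50`. The fit is unweighted least
squares (scipy `curve_fit`) with data-driven initialization (observed
min/max; half-crossing time) and box bounds keeping `t50` within one span
of the observation window. A flat series (variance < 1e−10) is returned
unconverged.

**"Not attained" rule.** t½ is only meaningful when the transition
completes inside the window. A fit reports a numeric t½ only when (a) the
last observed value has covered ≥ 90% of the fitted rise and (b) the
fitted plateau lies within the observed value range ± 20% of the observed
amplitude. Otherwise `t_half` is `None` and the label "not attained" is
used — the honest answer for slow conditions (e.g. a Matrigel overlay)
whose plateau the experiment never reaches. Both thresholds are
configurable.

**Group comparison.** Per-condition t½ values are compared with pairwise
unpaired two-tailed Welch t-tests (the unequal-variance form, since
nothing guarantees equal scatter across scaffold conditions), with
Bonferroni correction over the number of pairwise comparisons performed.
The replication unit is the independent experiment: technical-replicate
t½ values are averaged per experiment before testing. Degenerate
zero-variance comparisons return p = 1 (equal means) or p = 0 instead of
NaN.

## Dose-response fitting and curve comparison

4PL fits run on log(EC50) for numerical stability, with a two-stage
relative weighting: an unweighted fit provides predictions, then
residuals are scaled by the predicted response (floored at 1% of the
maximum) and the fit repeats. This matches the multiplicative
(constant-CV) noise of luminescence readouts. The EC50 confidence
interval is a seeded nonparametric case bootstrap (95% percentile
interval; 1000 resamples in the pipeline scenario). A fit whose amplitude
is below twice the residual scatter, or whose Hill-slope 95% CI spans
zero effect, is flagged `warning` (no resolvable dose dependence) rather
than raising.

Two curves are compared with the extra-sum-of-squares F-test: one shared
4PL (4 parameters) against separate 4PLs per dataset (8 parameters),
F = ((RSS₀ − RSS₁)/4)/(RSS₁/(n − 8)), with RSS on the weighted-residual
scale.

**Calibration caveat.** Normalizing each plate by its *own* vehicle mean
injects a shared scale error of order cv/√(n_vehicle) into every well of
that plate. The shared-vs-separate F-test correctly detects that scale
difference, so comparing two independently normalized plates inflates the
null rejection rate (~0.35 at cv = 0.05 with 3 vehicle wells). When the
pipeline compares two arms it therefore scales both by a single pooled
vehicle mean (the same-plate situation); under that convention the null
rejection rate is ~0.065 at α = 0.05. Per-arm EC50 estimates are
unaffected (the EC50 is invariant to response scaling).

## Segmentation

* **Nuclei** (Hoechst channel): Gaussian smoothing (σ = 2 px), global
  Otsu threshold, Euclidean distance transform, `peak_local_max` seeds
  (minimum separation 10 px) and watershed — the standard recipe that
  splits touching nuclei at their waist. Objects outside
  [min_area_px, max_area_px] (defaults 120–5000) are dropped; labels are
  consecutive from 1.
* **Noise guard**: any threshold is accepted only if the
  foreground–background mean separation exceeds 3 background standard
  deviations; otherwise the mask is empty (a pure-noise image must not
  segment).
* **Perinuclear rings**: `expand_labels` (nearest-label Voronoi
  expansion) by the ring width (default 5 px) minus the nuclei. Rings are
  pairwise disjoint, disjoint from nuclei, and share their nucleus label.
* **Organoids** (Hoechst + EGFP): each channel min-max normalized,
  summed, smoothed (σ = 3 px) and thresholded with the **triangle**
  method, which tracks the background shoulder of the histogram. Otsu is
  unsuitable here: once EGFP concentrates into nuclei the inter-class
  threshold jumps above the dim cytoplasm and the footprint collapses to
  the nuclei. The binary mask is then morphologically closed (an
  EDT-based closing, default radius 25 px) to bridge the gaps between a
  single organoid's cells, and hole-filled. Areas are pixel counts ×
  pixel_size², centroids are intensity-free region centroids, and the
  size class is "large" iff area > 8000 µm².
* **Core/periphery**: the distance of every in-organoid pixel to the
  organoid boundary is the Euclidean distance transform of the organoid
  mask; a nucleus is *periphery* iff this distance at its (rounded)
  centroid is ≤ 100 px, else *core*. Operating on centroids gives each
  nucleus exactly one zone. Nuclei outside every organoid are skipped
  with a warning.
* **Cell area** (EYFP-tubulin): smoothed triangle threshold, hole
  filling, removal of specks < 64 px; a constant positive frame is
  entirely foreground.
* **Background**: median intensity outside the 5-px-dilated foreground;
  if < 1% of pixels remain background, the 5th percentile of the whole
  image is used instead (logged).

Conventions: pixel indices are 0-based (row, col); physical positions are
(col + 0.5, row + 0.5)·pixel_size_um; areas use half-open pixel counting.

## Spatial aggregation

Organoid distance from the dome center is the Euclidean distance
√(x² + y²) in physical coordinates. Organoid cells inherit their
organoid's distance and are grouped into half-open radial bins
[k·250 µm, (k+1)·250 µm), 9 bins by default; distances beyond the last
bin are excluded (logged). Per (bin, time) the unweighted mean ratio over
cells is reported, so recombining bin means weighted by cell counts
reproduces the global mean exactly. Zone curves (core vs periphery per
size class) can be min-max normalized per curve, the device that makes
the kinetics of the dim organoid core comparable with the brighter
periphery.

## The synthetic-data generator

The generator emulates the study designs well enough to test every
downstream computation against exact ground truth, not to look realistic.

* **Cells are disks**: a nuclear disk (Hoechst amplitude; default radius
  14 px ≈ 4.6 µm at 0.325 µm/px) inside a cytoplasmic annulus. A cell's
  total EGFP (default 2×10⁵ counts) is split between nucleus and annulus
  by the programmed `nuclear_fraction`; per-pixel density is
  amount/pixel-count, so integrated signal is conserved exactly across
  partitions (and within 1% after PSF blur). By default
  `cyto_radius = √2 · nucleus_radius`, making the two compartments equal
  in area — under equal areas the mean-intensity ratio equals the
  programmed amount fraction, so the ground truth is identifiable by the
  mean-based statistic the pipeline computes.
* **Imaging**: Gaussian PSF blur (σ = 1 px; sub-µm optics at 2×2 camera
  binning), constant background (100 counts), Gaussian read noise
  (σ = 2 counts), quantization to 16-bit. Layouts with overlapping
  cytoplasm disks are rejected — overlapping cells would make the
  per-cell ground truth ambiguous. Every renderer takes an explicit seed
  and is bit-reproducible; there is no global random state.
* **Translocation kinetics**: nuclear_fraction(t) = baseline +
  (plateau − baseline)·logistic((t − lag − t50)/slope), clipped to
  [0, 1]; the first frame is pre-treatment baseline. The true half-
  transition time is `lag + t50`. Defaults (baseline 0.2, plateau 0.85,
  t50 0.75 h, slope 0.25 h) give the rapid sub-hour translocation of an
  uncovered monolayer; scaffold overlays are modeled as additive lags
  (1 h for the synthetic hydrogel, 3 h for Matrigel).
* **Domes**: organoids at known (x, y) inside a 2250 µm dome; each
  organoid is rendered in its own imaging field (as a high-content
  microscope visits fields), with a per-field origin so local centroids
  map to dome coordinates. The organoid's kinetic lag is a configurable
  function of its radial distance; the default scenario uses a linear
  map with the largest lag at the dome center (drug diffusing inward).
  The functional form of this map is not constrained by any data and is
  deliberately pluggable.
* **Core/periphery truth**: inside an organoid, a cell whose depth from
  the programmed circumference exceeds the 100 px rim is a core cell and
  can receive an extra lag (default +1 h in large organoids, +0 in
  small), emulating slower drug penetration into large organoids.
  Organoid scenarios use smaller, densely packed cells (nucleus 8 px,
  ~90 cells in a 70 µm organoid) so the segmented footprint tracks the
  programmed cross-section.
* **Tubulin texture**: an elliptical cell area of diffuse signal
  (600 counts ± 15% smooth modulation) plus `round(stabilization ·
  max_bundles)` bright line-segment bundles (default 40 max, 3 px wide,
  amplitude 1500). All candidate bundles are drawn up-front from the
  seed, so textures along a treatment ramp are nested and contrast is
  strictly increasing in stabilization for a fixed seed. An optional
  exponential intensity decay `exp(−rate·t)` emulates photobleaching;
  the bleaching tests use 0.025 h⁻¹ (a visible ~36% decay over 18 h)
  where the control-trend subtraction demonstrably restores the ramp.
* **Plates**: 4PL responses times lognormal noise of mean 1 and given CV
  (default 0.05), 8 log-spaced doses, 3 replicates, vehicle wells at the
  top asymptote.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: realistic cell morphology and
chromatin texture, cell motion and division, photophysics beyond
Gaussian noise plus exponential bleaching, 3D light scattering through a
dome (position-dependent lags are programmed, not emergent from a
diffusion model), autofluorescence, or segmentation difficulty of
overlapping cells. Results on real images depend on segmentation quality
in ways these tests cannot certify.

## Problem sizes used in the shipped checks

The recovery checks run at desk scale: monolayer stacks of 20 cells ×
33 frames (15-min sampling over 8 h) × 3 conditions × 3 experiments;
domes of 9–18 organoids (5–6 cells each) × 11 frames (30-min sampling
over 5 h), 50 independent simulations; 3 large + 3 small organoids for
the core/periphery analysis; 100 plates for EC50 recovery and 200
replicates each for power and type-I calibration of the curve
comparison. These sizes hold the full suite to a few minutes on one CPU
while leaving the statistical conclusions stable across seeds.

## Known limitations

* The mean-based ratio is exactly identifiable only because the
  generator renders equal-area compartments; on real images the ratio
  remains monotone in the underlying partition but its absolute scale
  depends on geometry. Comparative conclusions (lags, deltas) are
  unaffected, which is why all recovery tests are formulated as
  differences.
* A small constant bias (≈ +0.03 at low fractions) enters the measured
  ratio from PSF bleed between compartments; it cancels in condition
  differences.
* The F-test calibration statement holds for same-scale (shared
  normalization) comparisons; comparing independently normalized plates
  tests plate scale as well as curve shape (see above).
* 2D only: single-plane time-lapses, no z-stacks; tubulin texture in 3D
  organoids is out of scope (its quantification is confounded by the 3D
  orientation of bundles).
* The linear distance-to-lag map in the dome and the additive-lag
  scaffold model are modeling conveniences; nothing in the package
  estimates a physical diffusion constant.
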