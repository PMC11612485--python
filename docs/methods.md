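# Methods

## Reporter model

Tandem mCherry-GFP reporters emit in both channels at cytosolic pH; inside
an acidified lysosome the GFP chromophore is quenched while mCherry persists.
The pipeline therefore treats three object classes:

* **red-only** — an acidified mitolysosome or autolysosome (the quantity of
  interest; reported as puncta per µm² of ROI);
* **double-positive** — a differentially acidified lysosome (DAL): fused but
  not acidic enough to quench GFP;
* **triple-positive** — a DAL confirmed by a lysosomal marker channel
  (LAMP1-like).

## Detection chain

Each channel is Gaussian-smoothed (default sigma 1 px) and thresholded by
**exact Otsu** computed from the pixels inside the ROI only: the threshold
maximizes between-class variance over all splits of the unique observed
values, so it never bisects a value class and is exactly scale-equivariant.
(Fixed-width histogram implementations can misassign the boundary value on
integer-like data; the exact computation is a few cumulative sums.) The final
threshold is Otsu x `offset_factor` (default 1.0); pixels must exceed the
threshold strictly and lie inside the ROI.

**Counting route (red-only).** The GFP mask — dilated by `gfp_dilate_px`
(default 1 px, a tolerance for threshold and registration mismatch between
channels) — is subtracted pixelwise from the mCherry mask
(`mCherry AND NOT GFP`). Connected components (8-connectivity default) with
area inside [`min_area_um2`, `max_area_um2`] = [0.05, 20] µm² become puncta.
Two corrections address known failure modes of plain component counting:

* **Fragment bridging.** A punctum straddling a dual-channel structure (the
  mitochondrial network, a DAL) loses the overlapping stripe to the
  subtraction and can split in two. Pixels that are mCherry- and
  GFP-positive and lie within `bridge_radius_um` (0.3 µm) of a surviving
  fragment reconnect such fragments for counting; footprints and morphometry
  keep only subtracted pixels, and a grouped object must contain at least
  one fragment that alone reaches the minimum area (noise slivers along mask
  edges do not add up to a punctum).
* **Declumping.** Touching distinct puncta are split by watershed at local
  maxima of the smoothed mCherry image separated by at least
  `declump_min_distance_um` (0.6 µm, ~3/4 of the median punctum diameter).

**Classification route (DALs).** Puncta are segmented from the
*unsubtracted* mCherry mask and classified by object-level overlap: the
fraction of footprint pixels inside the GFP (and marker) masks. Overlap
below `overlap_cutoff` (0.5) is red-only; at or above it, double-positive;
triple-positive additionally requires marker overlap at the cutoff. On
well-separated objects the two routes agree on red-only counts. Without a
marker channel, double-positive counts include dual-channel network
fragments that pass the size gate; unambiguous DAL counting therefore uses
the marker (triple-positive) or network-poor regions.

**Density.** A punctum belongs to an ROI label iff its centroid lies in the
label (objects straddling adjacent cells are counted once). Density = count
/ label area (µm²). Coordinates are 0-based, row-major, pixel-centred.

**Morphometry.** Area = pixel count x pixel_size²; equivalent diameter =
2√(A/π); eccentricity from second central moments; form factor = 4πA/P²
with the weighted line-segment perimeter estimator (the crack-length
boundary count is used only for 1–2-pixel objects where that estimator
degenerates to zero). On a rasterized disk of radius 10 px the form factor
is ~0.9; values slightly above 1 can occur for tiny objects — a
discretization effect, not an error.

## ROI masks

External label masks (16-bit TIFF) are imported verbatim and win over any
computed segmentation. Hole filling assigns an enclosed background component
to its surrounding label only when that label is unique; holes bordered by
two labels are ambiguous and left open (the operation is idempotent). The
fallback segmentation thresholds the summed, smoothed reporter signal,
fills holes and drops objects below 20 µm² (`cell_body` mode) or returns the
whole thresholded region as one label (`tissue_region`).

## Flux assay

Nuclei are segmented from the smoothed Hoechst channel (exact Otsu, hole
filling, 10 µm² minimum, distance-transform watershed to split touching
nuclei with a 3 µm minimum separation). Each nucleus is grown into the
thresholded, smoothed GFP foreground, partitioned by nearest nucleus;
cytoplasm excludes the nucleus footprint. Spots are local maxima of the
scale-normalized Laplacian-of-Gaussian response (sigma ≈ 0.35 µm / pixel
size) above `k_mad` = 5 robust standard deviations of the response *inside
the cell foreground* (the empty background has lower shot noise and would
bias the threshold down). A red spot is red-not-green when the green
response mask covers less than half of a one-sigma disk around the peak.
Per-cell counts are normalized to the mean of the control condition; by
construction control ratios average exactly 1.

## Statistics

Images nest within subjects; the biological subject is the replication
unit, so per-image densities are averaged per subject before testing. Group
comparisons use one-way ANOVA with Bonferroni-corrected pairwise
pooled-variance (Student) t tests; the correction multiplies each raw p by
the number of comparisons actually requested (all pairs by default) and
caps at 1. Significance stars at 0.05 / 0.01 / 0.001 / 0.0001. Degenerate
zero-variance t tests return p = 1 (equal means) or p = 0 with a warning
(unequal means). Percent-of-youngest standardization is a positive
rescaling, so F statistics and p values are unchanged. Box summaries use
linear interpolation between order statistics (inclusive quartiles),
whiskers at min/max.

## Synthetic scenes

A scene is a pure function of (spec, seed) — identical inputs give
bit-identical arrays.

* **Field**: 512 x 512 px at 0.108 µm/px (~55 x 55 µm; 60x water-immersion
  scale), single plane.
* **ROI**: whole field, a star-convex soma of target area, or a soma with
  2–5 tapering processes. Soma-like ROIs carry a diffuse cytosolic fill
  (60 AU) in both channels — the signal that makes real cells segmentable.
* **Network**: random-walk filaments (steps parameterized in µm, ~0.24 µm
  wide) rendered identically into mCherry and GFP until a target fill
  fraction (default 0.08) of the ROI is covered.
* **Puncta**: class counts are Poisson(density x ROI area); positions
  uniform over the ROI (sampled in µm, so placement is
  resolution-independent); diameters lognormal (mean 0.8 µm, sd 0.3 µm; the
  quoted diameter is the 1/e² width of the Gaussian spot, sigma =
  diameter/4). Red-only puncta render into mCherry only; double-positive
  into both; the optional marker channel covers all lysosomal puncta.
  Presets whose source reports an age-dependent mitolysosome size increase
  use a 1.5x geriatric diameter.
* **Optics & noise**: Gaussian PSF (sigma 0.12 µm), Poisson shot noise on
  the expected image, additive Gaussian read noise (sd 2 AU) on a
  12-bit-like scale with background 100 AU and structure amplitudes
  120 (network) / 500 (puncta) / 300 (marker).

**Cohort presets.** Group-mean red-only densities are calibrated to
published values: A9 mito 0.005/0.018, A10 mito 0.007/0.008, A9 auto
0.003/0.002, A10 auto 0.005/0.002, choroid plexus auto 0.031/0.027
(young/geriatric, per µm²). The Purkinje-cell (2.3-fold), cerebellar-
microglia (5.4-fold) and prefrontal-cortex (-40% young→adult) presets were
published as ratios only; their young baselines (0.010, 0.005, 0.010 per
µm²) are generator choices and only the ratios are meaningful.
Double-positive (DAL) densities (0.002 young, 0.004 adult, 0.006 geriatric
per µm²) are generator choices consistent with an age-dependent DAL
accumulation; no absolute DAL densities were published. Subjects carry a
mean-one lognormal density multiplier with CV 0.10 — a modest
between-animal variability; per-image seeds derive from (base_seed, group,
subject, image) via `numpy.random.SeedSequence`.

**Flux plates** render 9 non-overlapping cells per 512 x 512 field at
0.216 µm/px (40x scale): a smooth-edged cell body (~1 µm intensity falloff,
as for a cytosolic reporter), a nucleus channel, and per-cell spot counts
drawn Poisson from condition means — vehicle 2 / DFP 10 / AZD8055 8
red-only spots per cell, exactly 0 under +BafA1 (a complete acidification
block), with double-positive structures accumulating under the block. The
condition means are generator choices; only the orderings (induction up,
block to zero) reflect reported behaviour.

## What the simulator does and does not emulate

It reproduces the features the measurement depends on: channel semantics of
the tandem tag, Poisson spatial statistics, subject nesting, realistic
sampling (pixel size, PSF, shot/read noise), dual-channel background
structures that stress the subtraction, and touching-object clutter at high
density. It does **not** model tissue autofluorescence gradients,
photobleaching, z-leakage from neighbouring planes, chromatic aberration,
cell-to-cell intensity heterogeneity, or learned-segmentation errors on
complex morphologies. Passing recovery tests therefore validates the
measurement chain's logic and calibration on idealized-but-noisy data, not
performance on arbitrary real tissue.

## Numerical choices

* Exact Otsu with first-maximum tie-break; thresholds strictly exceeded.
* Masks are half-open over the pixel grid; 8-connectivity default.
* Quartiles: linear interpolation (inclusive). Pooled-variance t (not
  Welch), matching the stated testing convention.
* YAML configs round-trip floats via Python's shortest-repr (exact binary
  round trip); every stochastic stage takes an explicit integer seed.
* Empty inputs: constant-intensity ROIs yield an empty mask plus a warning;
  empty masks yield empty record lists; zero-area ROIs and zero control
  means raise.

## Known limitations

* At the highest calibrated densities (~0.03 puncta/µm²) residual merging
  of puncta closer than the declump distance biases recovered densities a
  few percent low; fold changes are less affected because the bias largely
  cancels between groups.
* DAL (double-positive) absolute counts are only meaningful with a marker
  channel or low network clutter (see Classification route).
* The fallback ROI segmentation is intensity-based and applies to
  reporter-filled cells; it is no substitute for a trained pixel classifier
  on dim or overlapping cells.
* Single-plane analysis only; no 3-D objects, deconvolution or
  super-resolution processing.
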