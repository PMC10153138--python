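# Methods

## Scope and model of the data

The package analyzes three kinds of measurements from studies of
syncytial-embryo actin organization: (1) maximum-intensity projections of
cortical F-actin caps or myosin-labelled compartments, from which per-cap
areas, counts and densities are derived; (2) co-sedimentation
densitometry tables quantifying how much of an actin-binding protein
pellets with F-actin; (3) TIRF images of labelled filaments, measured via
line profiles drawn perpendicular to filaments or bundles. Because real
acquisitions of this kind are not redistributable, a synthetic-data
module generates all three substrates with known ground truth; every
estimator in the package is validated against that truth or against an
independent brute-force oracle.

## Cap segmentation

Pipeline (on a calibrated 2D projection):

1. multiply intensities by a constant (default 1.25; float arithmetic,
   no clipping, so the step is a pure rescale of an integer-typed
   original);
2. Frangi vesselness, maximum over scales, bright-ridge polarity
   (defaults: scales 1,3,5,7,9 px, β=0.5, c=15 — the documented defaults
   of the common 2D implementation; all exposed in
   `SegmentationParams`);
3. Gaussian blur of the ridge response, σ default 6 px (legal range
   4–10; the choice is per image and never automated);
4. regional minima (8-connected plateaus with no lower neighbor) of the
   blurred — optionally rolling-ball background-subtracted — response
   are the seeds, one marker per plateau;
5. the ridge response is median-filtered (11 px) and flooded from the
   seeds by a marker-controlled watershed; inter-basin interfaces are
   thinned to single-pixel label-0 lines.

Deterministic flooding. Pixels join basins in increasing
(relief value, frontier-entry age, row-major index) order, and inherit
the label of the neighbor with the smallest such key. The FIFO age term
makes basins grow synchronously across equal-valued plateaus, so a flat
divide is split down the middle; the row-major term makes the order
total, hence the result unique and exactly reproducible. An exhaustive
selection-by-scan implementation of the same definition serves as the
test oracle. (A pure (value, row-major) order was rejected: on plateaus
it sweeps the divide to one side, systematically misplacing boundaries
on flat relief crests.)

Numerical choices:

- Before minima detection the blurred response is discretized to 4096
  grey levels (12-bit camera depth). Far from any ridge the response
  decays through machine-epsilon wiggles; without quantization each
  wiggle is a separate "minimum" and seeds a spurious basin. Integer
  acquisition depth is the physically faithful model.
- Frangi scales for the synthetic fields are set to (4, 6) px: the
  painted furrow ridge is ~2 px wide plus PSF, and the response must be
  broad enough to survive the 11-px median filter with a usable crest.
  Scale 1 responds strongly to pixel noise and contributes a narrow
  peak that the median filter truncates into a flat, ill-conditioned
  divide. This is data-matched configuration, exactly as the per-image
  blur σ is.
- Region areas are reported with each boundary-line pixel's area shared
  among its adjacent regions (the physical boundary has zero width;
  without the correction every area is biased low by about half a
  perimeter ring).
- Degenerate inputs: a constant image is a single regional-minimum
  plateau and yields one region spanning the field; images smaller than
  the largest Frangi scale are rejected.
- Regions below `min_region_area_um2` (default 0 = off) can be merged
  into their largest neighbor — a reproducible surrogate for the manual
  cleanup interactive workflows apply.

## Morphometry

- Small-cap fraction uses a strict `area < 80 μm²` comparison
  (configurable threshold).
- Nuclear density is nuclei/μm² with the field area taken from the image
  extent unless an explicit area is supplied. When counting nuclei from
  a label map, background basins are excluded by splitting per-region
  mean intensities with an Otsu threshold; if the means span less than a
  factor of two there is no background class and all regions count.
- The centrosome "vertex angle" is the angle subtended at the nuclear
  center by the two centrosomes, so 180° means fully separated. This is
  one documented reading of an ambiguous construction; the alternative
  (angle at one centrosome) is not implemented.
- The furrow apical/basal ratio min–max normalizes the profile first,
  then averages the outermost 2 μm windows; profiles must span both
  windows and have nonzero dynamic range.

## Co-sedimentation

Raw pellet fraction is `pellet/(pellet+supernatant)` per reaction, so
densitometry units cancel. The mean raw pellet fraction of the zero-actin
reactions (p₀) is the nonspecific correction; the default corrected value
`(p−p₀)/(1−p₀)` can saturate at 1, while plain subtraction `p−p₀` is
available as a switch because the source protocols say only that the
nonspecific fraction "was subtracted". The Hill fit is trust-region
least squares over (K_d, h) with the plateau fixed at 1 by default (a
fraction bound saturates at 1; a free plateau in (0, 1.5] is provided for
densitometry that does not saturate cleanly), multi-started from
K_d ∈ {min, geometric mean, max concentration} × h ∈ {1, 2, 4} because
small-n Hill fits are multimodal. Bootstrap CIs resample points with
replacement within each concentration (seeded, percentile 2.5/97.5).

## TIRF bundling

Rolling-ball background subtraction (default ball radius 5 px) precedes
profile extraction; profiles are bilinear interpolations along a segment
given in (x, y) pixel coordinates. Profiles are fit to a 1D Gaussian with
offset — the line-profile workflow has one spatial coordinate, which is
how the printed "2-dimensional Gaussian" is read here. The bundle metric
defaults to the background-corrected amplitude; `fwhm_mean` (mean fitted
intensity over the FWHM window) is the alternative reading of "intensity
at FWHM". Both are linear in amplitude, hence in filament count, since
fluorescence adds within a diffraction-limited bundle. Every measurement
is divided by the mean of the actin-only control measurements.

## Statistics

Mann-Whitney U uses the exact null distribution when the combined sample
size is ≤ 20 with no ties, otherwise midranks with tie-corrected normal
approximation; the branch taken is recorded. Two-sided by default. The
unit of analysis is the embryo: per-object tables are reduced to one mean
per embryo before testing. No multiple-testing correction is applied by
default.

## Synthetic data: what it emulates, and what it does not

Cap fields are power-diagram (Laguerre) tessellations of a jittered site
lattice: each drawn target area sets a cell weight, and four fixed-point
weight updates pull realized cell areas toward their targets, so an area
mixture with a small mode near 30 μm² produces a visibly bimodal field.
A fallout fraction empties lattice sites (their cells become dark
background). Compartment boundaries carry a ~2 px bright ridge — except
along the image border, where a real field of view clips caps without
showing the furrow. The painted scene is convolved with a Gaussian PSF
(σ 0.8 px) and Gaussian noise is added and clipped at zero. Default
intensities (background 25, interior 115, ridge 230, noise SD 12) follow
8-bit fluorescence conventions — the same convention the Frangi c=15
default presumes; noise SD 12 (contrast-to-noise ≈ 7.5 for interiors)
is the "moderate" operating point used in the recovery suites. Not
emulated: photobleaching, shot noise, cap growth over time, 3D structure,
uneven illumination. Passing tests therefore demonstrate correctness of
the measurement pipeline on geometry-faithful, noise-realistic stills,
not robustness to every artifact of live imaging.

Binding tables put `p₀ + (1−p₀)·plateau·A^h/(K_d^h+A^h)` plus Gaussian
noise (clipped to [0,1]) through a fixed total band intensity; the
defaults are the assay's conditions (concentrations 0, 0.1, 0.25, 0.5,
1, 2, 4 μM; three replicates; ground truth K_d 0.45 μM, h 2.9). TIRF
profiles are Gaussians of σ 1.5 px at 143 nm/px whose amplitude is
count × 100 over background 20, noise SD 5; bundle counts are
2 + Poisson(1.4), giving a mean near 3.4 filaments — the scale of the
normalized bundle intensities the assay reports. Point geometries place
two centrosomes at the requested subtended angle and separation with
isotropic jitter; spindle poles duplicate centrosome positions
(metaphase poles coincide with centrosomes).

All generators draw from a single `numpy.random.Generator` seeded by the
spec, so identical spec + seed is bit-identical.

## Problem sizes in the shipped suites

The recovery suites run 20 noisy 320×320 fields of 100 caps for
segmentation, 20 seed pairs of 224×224 fields for the fallout/density
ratio, 200 simulated assays for noisy Hill recovery, and 500 jittered
nuclei for geometry recovery — sizes at which the Monte-Carlo standard
errors are small enough for the 2-SE checks to be informative while the
whole suite stays fast on a single core.

## Known limitations

- The segmentation's boundary placement is exact (within a one-pixel
  ring) on clean two-compartment fields, but three-way junctions on
  dense fields can deviate by a few pixels: the 11-px median filter
  flattens the ridge response near junctions and the divide position
  there is weakly determined. Matching and area-recovery accuracy are
  unaffected at the few-percent level.
- The jittered centrosome distance estimator carries the usual
  Rician-type bias (≈ j²/s for jitter j and separation s); tests compare
  against the bias-corrected expectation.
- The amplitude of a diffraction-limited single-filament profile at
  amplitude/noise = 10 has a Cramér-Rao floor near 5–6% median error;
  precision claims below that are not achievable and the tests instead
  verify efficiency against the CRLB prediction.
- `fraction_bound` requires at least one zero-actin reaction; datasets
  without a nonspecific control are rejected rather than guessed at.
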