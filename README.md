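# syncap

Quantitative analysis of syncytial *Drosophila* embryo actin organization
and in-vitro actin biochemistry. The early fly embryo is one giant cell in
which thousands of cortical nuclei divide synchronously; an F-actin **cap**
forms above each nucleus, and transient **pseudo-cleavage furrows** between
caps wall off neighboring spindles. When furrows fail, spindles collide and
nuclei fall out of the cortex. This package implements the measurements
used to quantify that biology:

- **Cap segmentation** — the five-step recipe applied to maximum-intensity
  projections: intensity scaling (×1.25), multiscale Frangi vesselness to
  enhance the ridge-like furrow network, Gaussian blur (σ 4–10 px),
  regional-minima seed detection, and marker-controlled watershed on the
  median-filtered (11 px) ridge image. The flooding order is fully
  deterministic (relief value, FIFO age, row-major index) and verified
  against an exhaustive flooding oracle.
- **Morphometry** — cap areas and the small-cap (<80 μm²) fraction,
  nuclear density (nuclei/μm², the nuclear-fallout readout), the
  missing-furrow ratio, centrosome separation and vertex angle (180° =
  fully opposed), spindle length, and the apical/basal furrow intensity
  ratio after (I−I_min)/(I_max−I_min) normalization.
- **Co-sedimentation analysis** — fraction of binder bound to F-actin with
  nonspecific-pelleting correction, and a nonlinear least-squares fit of
  the cooperative Hill model
  `f(A) = plateau · A^h / (K_d^h + A^h)`
  with multi-start initialization and bootstrap confidence intervals;
  low-speed pelleting (bundling) summaries.
- **TIRF bundling** — rolling-ball background subtraction (radius 5 px),
  perpendicular line-profile extraction, 1D Gaussian fits, FWHM-based
  intensity metrics, and normalization to the actin-only control mean.
- **Statistics** — Mann-Whitney U comparisons (exact for small untied
  samples, tie-corrected normal approximation otherwise) on per-embryo
  means.
- **Synthetic data** — a seeded generator producing every input with known
  ground truth: cap/nucleus fields as power-diagram tessellations with
  painted furrow ridges, PSF blur and noise; binding tables from a ground
  truth Hill model; TIRF profiles whose amplitude is filament count ×
  single-filament intensity; centrosome point annotations.

## Worked example

```sh
python examples/02_hill_binding_fit.py
```

```
true K_d = 0.45 uM, true h = 2.9
fitted K_d = 0.447 uM  (95% CI 0.440-0.456)
fitted h   = 2.97   (95% CI 2.89-3.06)
RSS = 2.85e-03 over 18 points
```

A binding table is simulated for 0.5 μM binder against 0–4 μM F-actin
(three replicates, 2% densitometry noise, 5% nonspecific pelleting), the
nonspecific fraction is subtracted, and the Hill fit recovers the
half-saturation concentration K_d and cooperativity h within the
bootstrap intervals. Similarly, `examples/01_segment_cap_field.py`
segments a 100-cap noisy field and prints

```
ground-truth caps : 100
recovered regions : 101
matched caps      : 97 (97.0%)
median area error : 2.8%
```

meaning 97% of caps were recovered one-to-one (centroids within 2 px)
with watershed boundaries landing on the painted furrow ridges. The other
examples cover TIRF bundle quantification, fallout morphometry, and the
config-driven pipeline. A thin CLI mirrors the stages:

```sh
syncap simulate --out field/ --seed 1
syncap segment --input field/caps.tif --scales 4,6 --out labels.tif --table caps.csv
syncap hillfit --input binding.csv --out fit.json
```

## Layout

- `src/syncap/` — library (`synthetic_data`, `cap_segmentation`,
  `morphometry`, `cosedimentation`, `tirf_bundling`, `reporting`,
  `pipeline`, `cli`)
- `examples/` — one short narrative script per capability
- `tests/` — unit, property and end-to-end suites with brute-force oracles
- `docs/methods.md` — models, parameter choices, and limitations
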