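# Methods

`hotspotmap` quantifies focal hotspots of macromolecule uptake on en-face
fluorescence images of arterial wall patches centred on a side-branch ostium,
maps them (together with mitosis point events) onto a fixed 10×10 grid, and
compares spatial maps with a bootstrap correlation statistic. Because no
imaging data are distributed with the package, a synthetic generator with
full ground truth stands in for acquisitions; every stage of the pipeline is
validated against it.

## Patch geometry and coordinate conventions

A patch covers 2.4 × 2.4 mm of vessel wall, viewed en face with mean blood
flow running down image rows (row 0 = most upstream). The default raster is
750 × 750 px at 3.2 µm/px, so one grid square is 75 × 75 px (≈ 57,600 µm²)
and a 50 px area is ≈ 512 µm² — roughly one endothelial cell. The branch
ostium is an ellipse centred in the patch; its pixels are excluded from all
metrics, and any grid square it touches is invalid ("black squares").
`standardise_frame` brings arbitrary acquisitions into this frame by 90°
re-orientation, integer translation and crop/pad; padded pixels carry zero
intensity and a true mask so they never contribute.

The `GridGeometry` rule divides each axis into ten half-open intervals of
`side // 10` pixels, the remainder going to the last row/column, so every
pixel and every point belongs to exactly one square.

## Image model (synthetic generator)

Each branch realisation is

    I(x) = s_b · [ B(x) + Σ_k A_k · exp(−‖x − c_k‖² / 2σ_k²) · 1(‖x−c_k‖ ≤ 3σ_k) ]

observed through `n_slices` z-slices with per-slice attenuation (one focal
slice at full signal; maximum-intensity projection recovers it), optional
Poisson shot noise and additive Gaussian read noise, quantised to uint16.

* **Spot process.** Centres follow an inhomogeneous Poisson process with
  intensity proportional to a preset rate field Λ(x) (mean 1 over valid
  pixels), zero inside the ostium. The expected count per patch is the
  observed group mean: 26.2 (immature), 49.6 (mature). The `immature` field
  is a smooth lobe downstream of the ostium; `mature` is four corner
  patches; `flat` is constant. A single contrast parameter
  (`background_pattern_gain`, default 1.2) scales the pattern; at 0 every
  preset degenerates to flat.
* **Diffuse background.** `B(x) = B₀·(1 + g·Λ(x))` when coupled to the spot
  process (default, B₀ = 100, g the same gain), emulating the observed
  spatial correlation between hotspot and non-hotspot uptake of about 0.5;
  when decoupled, Λ is replaced by an independent smooth random field of
  matched spatial variance, so realised spot and background maps are
  uncorrelated on average.
* **Spot marks.** Amplitudes and radii (Gaussian σ, px) are log-normal:
  A ~ LN(median 1200, s = 0.25); σ ~ LN(median 5 px, s = 0.35). The radius
  spread is wide enough that a meaningful fraction of spots (~30 %) keep
  above-threshold footprints beyond the nine-fold larger 450 px area filter,
  so the large-spot reanalysis is non-degenerate.
* **Between-branch variability.** One log-normal scalar s_b (log-SD 0.25)
  multiplies the whole branch, reflecting the branch-to-branch SEMs of the
  in-vivo metric means without asserting any richer model.
* **Nuclei.** BrdU-positive nuclei are an independent Poisson point process
  (6.2 immature / 3.9 mature per patch — the observed mitotic-event means)
  with a multiplicative downstream tilt of 1 + bias (default 0.4) on the
  lower half, never inside the ostium. They are deliberately independent of
  the spot process: the study found no correlation between mitosis and
  uptake maps.

All randomness flows from `(config.seed, branch_seed)` through a NumPy
`SeedSequence`; identical inputs give bit-identical files.

What the generator does **not** emulate: optics (PSF, stitching, depth
attenuation structure), multi-channel fluorescence, tracer chemistry,
spatially correlated noise, irregular ostium shapes, or registration error
between branches. Passing tests therefore demonstrate the correctness of the
analysis pipeline under the stated statistical model, not robustness to
every property of real confocal data.

## Hotspot segmentation

A hotspot is a connected component (8-connectivity by default) of unmasked
pixels with intensity **strictly above** a threshold, whose pixel area
reaches `min_area_px` (default 50). Total uptake over unmasked pixels is
decomposed exactly: pixels in accepted components are spot uptake, all other
unmasked pixels (including rejected small components) are non-spot uptake;
ostium pixels belong to neither compartment. `refilter_spots` re-applies a
larger area cutoff and is bit-identical to re-segmenting at that cutoff.

The threshold rule is selectable (`fixed`, `percentile`, `otsu`,
`median_plus_k_mad`) and always recorded in the output. The default is
median + 8 × MAD (raw, unscaled) of the unmasked pixels. The median/MAD pair
is robust to the heavy right tail the spots create; the multiplier is set
so the threshold clears the top of the *structured* diffuse background
(contrast ≈ 2.2× at the default gain) — a smaller multiplier lands inside
the background's upper tail and turns entire high-background regions into
false components. With the default spot amplitudes (~10× the background
MAD) measured recall is ≥ 0.996 and precision 1.0 on both presets.

Spots are assigned to grid squares by their intensity-weighted centroid, so
a spot straddling a boundary is counted exactly once. Per-square spot area
is a *per-spot* mean: squares without spots are undefined (not zero), and
cohort averaging skips undefined entries to avoid zero-inflating the
metric.

## Cohort maps and outlier exclusion

Cohort maps are per-square arithmetic means across branches, restricted to
branches with a defined value, under the union ostium mask (a square masked
in any branch is masked in the cohort map). No per-branch intensity
normalisation is applied by default: synthetic cohorts share units by
construction; a normalisation flag exists for heterogeneous real data.

Chauvenet's criterion is applied once (no iteration) at the animal level:
with sample mean and (n−1)-SD, a value is excluded iff
n · P(|Z| ≥ |z_i|) < 0.5. All-equal samples exclude nothing.

## Statistics

* **Map correlation.** Pearson's r between two cohort-average maps over
  jointly valid squares, summarised by the median and 2.5/97.5 percentiles
  of a bootstrap over whole branch maps — never individual squares, which
  preserves the spatial autocorrelation within a map. When animal ids are
  supplied, whole animals are resampled (hierarchical bootstrap). When the
  two metrics come from the same branches, the same resample drives both
  datasets (paired bootstrap); for metrics from different animals the
  datasets are resampled independently. A correlation is significant when
  the 95 % CI excludes zero. Default 10,000 replicates; the seed is stored
  in every result. This bootstrap is an approximation chosen to reproduce
  the reported summaries (median r, 95 % CI, CI-vs-zero significance); the
  exact autocorrelation-aware procedure used for the original tables is not
  described in enough detail to reimplement.

  A calibration caveat, measured on synthetic nulls: with *independent*
  resampling of two unrelated, spatially unstructured cohorts, the
  percentile CI is strongly conservative (observed type-I ≈ 0 rather than
  0.05), because each replicate adds fresh resampling noise to both maps
  and attenuates the replicate r toward about half the observed value. The
  paired (shared-resample) form used for within-cohort comparisons does not
  suffer from this and its power is high (significant positive spot vs
  non-spot correlation in 100 % of 20-branch synthetic cohorts).
* **Group comparison.** Student's pooled-variance t-test (Welch by flag) on
  spots per branch; df = n₁ + n₂ − 2.
* **Half-map test.** Per branch, the mean over valid squares of rows 0–4
  (upstream) and rows 5–9 (downstream); a paired, 1-tailed t-test across
  branches in the stated direction. Zero-variance zero-mean differences
  yield p = 0.5 by convention.

## Numerical and degenerate-input choices

* Conservation `spot + nonspot = total` holds to ≤ 1e-9 relative error in
  float64 (exact for integer images).
* Ties at the threshold are non-spot (strict `>`).
* `pearson_r` raises on zero variance rather than returning 0; inside the
  bootstrap, a degenerate replicate is dropped (NaN) and identical inputs
  return r = 1 exactly.
* Self-correlation of a dataset with itself (same resampling) returns
  median r = 1 with CI [1, 1] exactly.
* The remainder of `side mod 10` goes to the last grid row/column; for the
  default 750 px side there is none.

## Problem sizes used in the checks

The test suite and the acceptance script choose sizes that keep a full run
at desk scale: most pipeline checks run on a 240 px / 10 µm-per-pixel patch
(the same 2.4 mm field; area filters scaled by pixel area, 506 µm² = 5 px),
while every check that pins the 50 px / 450 px filters (refilter
equivalence, planted-spot recovery, preset pattern recovery) runs at the
full 750 px geometry. The acceptance script simulates 5 animals × 6 branches
per age group at full geometry with 2,000 bootstrap replicates.

## Known limitations

* The intensity threshold rule of the original analysis is unknown; all
  results depend on the documented default, and the alternatives are one
  config switch away.
* Lesion-frequency maps are consumed as externally supplied 10×10 CSVs,
  never computed.
* No watershed splitting: touching hotspots merge into one component.
* The independent-resampling bootstrap is conservative for unrelated
  cohorts (above); treat non-significant cross-cohort correlations
  accordingly.
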