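# Methods

This note records the models, conventions, parameter choices and numerical
details behind each analysis stage, what the synthetic generators emulate
(and deliberately do not), and the problem sizes the validation benchmarks
use. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Focal-adhesion segmentation and morphometrics

The pipeline is classic particle analysis for punctate adhesion markers:

1. **Median filter**, circular footprint of radius 1.5 px (a full 3×3
   neighbourhood at that radius) — suppresses shot noise without moving
   edges.
2. **Rolling-ball background subtraction**, radius 50 px: the background is
   the grayscale opening of the image with a ball-shaped structuring
   element. For radii ≥ 16 px the ball is rolled on a 4×-downscaled copy
   and the background bilinearly upsampled — the same shrink optimization
   ImageJ's *Subtract Background* applies at large radii. The approximation
   error is well below 1% of foreground amplitude on our synthetic scenes
   while cutting cost ~16-fold, which is what keeps per-frame movie
   processing tractable. The estimated background is clipped to never
   exceed the image.
3. **Threshold** at *k* × mean of the background-subtracted image,
   strictly greater-than, with *k* restricted to [9, 15]. The threshold was
   historically chosen per image by eye from a 9..15 sweep; our `"auto"`
   mode replaces that with a stability-plateau rule: compute the particle
   count at each integer *k*, find the adjacent pairs whose count changes
   least, and take the **middle of the longest stability run**. On clean
   images the count plateaus across the whole range and the middle of the
   plateau (k ≈ 12) is the representative member; a smallest-*k* tie-break
   would systematically pick the most dilated segmentation. A numeric *k*
   overrides the heuristic. Because the mean is taken over the whole
   background-subtracted image, the threshold is mildly cell-density
   dependent; this mirrors the original operator procedure and is flagged
   here rather than hidden.
4. **Particle analysis**: 8-connected components, area gate
   `min_area_um2` (default 0.25 µm² — no lower gate is inherent to the
   method, but single-pixel noise particles must be suppressed) and
   optional `max_area_um2` (e.g. 15 µm² to isolate the large-FA
   subpopulation as a filter option, not a default).

**Shape descriptors.** Area = pixel count × pixel area. Major/minor axes
are the ellipse-equivalent axes from second central moments; aspect ratio
is their quotient. Degenerate components (single pixels, collinear runs)
have their axes floored at one pixel width so the aspect ratio stays
defined — a single pixel has aspect exactly 1. Orientation is reported in
[−π/2, π/2) as the angle of the major axis above the image x-axis (y up).
The moments-based estimator was chosen over a bounding-box estimator
because it is rotation-equivariant (verified by property test).

**Radial position.** r_rel is the distance from the cell centroid to the FA
centroid divided by the distance from the cell centroid to the cell
boundary along the same ray, clamped to [0, 1]; the boundary is found by
marching the ray in 0.25-px steps through the cell mask. An FA centroid
coincident with the cell centroid returns 0. The cell mask comes from a
whole-cell channel when available (Otsu threshold, largest component, holes
filled); otherwise the convex hull of all segmented FA pixels stands in,
which biases r_rel upward for cells whose adhesions do not reach the true
margin — supply a cell channel when radial positions matter.

**Polar unwrapping** resamples the image on an (angle × radius) grid, angle
measured clockwise from the image "up" direction, radius from 0 to the
far-corner distance, bilinear interpolation, zero-padded outside. It is a
visualization aid; quantitative radial statistics use r_rel.

**Distribution comparison** uses the two-sample Kolmogorov–Smirnov
statistic with the asymptotic two-sided p-value; the statistic is checked
exactly against a brute-force ECDF scan over exhaustively enumerated small
multiset pairs.

## Colocalization

- **Pearson** is the product-moment correlation over (optionally masked)
  pixels; a constant channel is an error, not a zero.
- **Li's ICQ** is the fraction of pixels whose mean-centred intensities
  have a strictly positive product, minus 0.5. Pixels whose product is
  exactly zero (a value equal to either channel mean) count as
  non-positive and stay in the denominator — the convention matters only
  on quantized data and is stated here because plugin implementations
  differ.
- **Manders M1/M2** default to the pixel-count form: M1 is the fraction of
  A-positive pixels (A > thrA) that are also B-positive. An
  intensity-weighted form (`weighted=True`) reproduces the original
  intensity-fraction definition. Thresholds default to per-channel Otsu in
  the combined `coloc_stats` entry point.
- **Masked ratio images** build a binary mask from a structural channel
  (Otsu unless a threshold is given), multiply both inputs by it, and
  divide only where the masked denominator is positive; all other pixels
  are NaN ("undefined"), never raised as errors, and written as NaN in
  32-bit float TIFF.

All three statistics are verified exactly (to float associativity,
< 1e-12) against naive double-loop references, and their range, symmetry
and affine-invariance properties are exercised on random rasters.

## Biosensor analytics

The sensor model: the denominator channel reports sensor abundance (it is
fused to an FA adaptor, so it tracks FA geometry); the numerator reports a
conformation-sensitive fluorophore whose intensity scales with kinase
activity. Activity is therefore read out ratiometrically and is invariant
to expression level and uniform gain (property-tested).

- **Tracking**: greedy nearest-centroid linking, gate 1 µm/frame
  (configurable, scaled by frame gap); one-frame gaps are bridged by
  linear interpolation of centroid and geometry; anything beyond the gate
  starts or ends a track rather than swapping identities.
- **Ratio series**: per frame, summed numerator over summed denominator
  within the FA footprint (sum-then-divide rather than per-pixel-mean, for
  robustness to near-zero-denominator pixels at the FA rim). Frames with
  zero denominator are NaN and excluded — never imputed. Channels are
  rolling-ball background subtracted first. Smoothing is a boxcar over
  {i−1, i, i+1} with shrinking windows at the edges, so a 3-point series
  [1, 2, 3] smooths to [1.5, 2, 2.5].
- **Registration**: each frame is resampled on a patch grid centred on the
  FA centroid with the major axis vertical and the **distal** end (the
  axis endpoint farther from the cell centroid) up. Near-circular frames
  (aspect < 1.2) reuse the previous frame's axis, since their own
  orientation is ill-conditioned; a near-circular first frame is an error
  for kymograph use. Axis direction is kept continuous along the track.
- **Kymographs** average the ratio across a 3-px central line and resample
  at 25 normalized positions (0 = medial end, 1 = distal end) between the
  rows where the line-denominator exceeds 20% of its frame maximum.
- **Peak scoring** takes the global maximum of the kymograph matrix and
  maps its position third [0,⅓) / [⅓,⅔) / [⅔,1] to medial / central /
  distal. Ties are broken by earliest time, then larger (more distal)
  position, and logged. The global-max convention (rather than per-frame
  peak tallies) is a deliberate choice and is stated here because both
  readings of "peak location over a trace" are defensible.
- **Growth classification**: the rate is the least-squares slope of length
  (ellipse-equivalent major axis, µm) versus time over a 5-min window slid
  one sample at a time; windows classify Growing (> +0.02 µm/min), Stable
  (|rate| ≤ 0.02) or Shrinking (< −0.02), and maximal runs of same-class
  windows become segments, so every segment spans ≥ 5 min and a track that
  transitions contributes one segment per behaviour (a growth-to-shrink
  track typically yields Growing, a short Stable crossover, and
  Shrinking). The estimator (sliding-window least squares) is our choice;
  the thresholds and 5-min persistence are the field's.
- **Cohort summaries**: per segment, min/mean/max of the smoothed ratio
  within the segment; state differences by one-way ANOVA with Tukey HSD
  post-hoc; activity-versus-dynamics association by OLS of each statistic
  against |rate| with r² and two-sided p (undefined below 3 points).

## Substrate screen

Zero intensity means "not detected" (the MaxQuant-style convention for
label-free tables). The analysis chain:

1. **Parsing**: TSV/CSV with a YAML column map onto
   (condition ∈ {ctrl_ATP_PKA, neg_ATPbiotin_noPKA, exp_ATPbiotin_PKA},
   trial); contaminant/decoy accessions (`CON__`/`REV__`) dropped;
   duplicate accessions are an error; missing values read as 0.
2. **Control filter**: a protein is removed when the unlabeled-control
   intensity exceeds the experimental intensity in a **majority of trials
   where both were detected**, or when it was detected only in the
   unlabeled control. The per-trial rule ("majority of evaluable trials")
   is our operationalization of "enriched in or exclusive to the control";
   no per-trial rule is standard.
3. **Enrichment**: per trial, experimental / negative-control intensity.
   Experimental-only detection is +∞ (maximal enrichment); neither
   detected is NaN (trial not evaluable). Raw intensities are used as
   given; any normalization is upstream of this module.
4. **Hit calling**: enrichment ≥ threshold in ≥ `min_trials` trials, +∞
   trials counting by default (`count_exclusive=False` switches this off);
   hits sort by descending median finite enrichment, ties by accession.
   Monotonicity in threshold and `min_trials`, and the nesting of the
   high-stringency list inside the low-stringency list, are property
   checked against a brute-force re-evaluation.

**Motif scanning** is an in-house consensus scorer, not a neural-network
predictor: every Ser/Thr is checked against its −4..+1 window; Arg at −3
and −2 is a strong site (R-R-x-S/T), Lys–Arg at −3/−2 or Arg at −3 alone is
moderate. The score is a weighted fraction of matched determinants
(R at −3 weight 1.0, K at −3 weight 0.7, R at −2 weight 1.0, hydrophobic
{A,V,L,I,F,M,W} at +1 weight 0.5, total 2.5), so the canonical
R-R-x-S/T-Φ site scores 1.0. The weights are a package design choice meant
to rank sites sensibly, not probabilities; unknown residues (X) never
match.

## Synthetic generators

The generators emulate the statistical structure the analyses assume and
return their planted truth:

- **Scenes**: a circular cell (closed-form radial geometry, so r_rel has
  exact truth) with non-overlapping elliptical FAs (overlap is rejected —
  truth would be ambiguous), rendered by pixel-centre membership,
  Gaussian-blurred by a scalar PSF sigma, plus offset background and
  additive Gaussian noise (the simplest model matching fluorescence
  detection). Default arrangement: FAs in the peripheral band (r_rel
  0.45–0.9), 1.5–3.5 µm long, aspect 1.6–3.5, radially oriented with
  jitter, noise at 5% of FA intensity, PSF sigma 1 px.
- **Movies**: the denominator channel renders FA geometry; the numerator
  multiplies it by an activity field — uniform, or a Gaussian hot spot
  (amplitude 1.0, width 0.12 of the axis) centred at 1/6, 1/2 or 5/6 of
  the medial→distal axis; growth changes the major axis linearly; an
  inhibitor step multiplies activity by (1 − drop) during [on, off); an FA
  shrinking below one pixel is truncated with its truncation frame
  recorded. Frame regimes follow the two acquisition modes the analyses
  target: 20-s intervals (three frames/min) for minutes-long dynamics and
  3-s intervals for sub-minute linescans.
- **Trajectories**: linear length trends plus i.i.d. Gaussian noise, with
  the true class assigned from the planted rate by the ±0.02 µm/min
  thresholds.
- **Quantitation tables**: per-protein lognormal base abundances (median
  1e7, log-sd 1); planted hits multiply the experimental condition by the
  planted fold in every trial before noise; control-enriched proteins get
  5× the larger of base/hit intensity in the unlabeled control;
  multiplicative lognormal noise; missingness zeroes entries i.i.d.
  **Noise parameterization**: `lognormal_noise_sigma` is the log-sd of
  *between-condition intensity ratios*; each intensity receives σ/√2 so
  that any cross-condition ratio has the stated dispersion. This is the
  quantity screen designs reason about (the CV of fold changes), and it
  makes the generator's planted-recovery construction well-posed rather
  than knife-edged.

**What the generators do not model** — and hence what passing tests do not
demonstrate about real data: photobleaching, stage drift, 3D PSFs and
defocus, bleed-through and chromatic shift between biosensor channels,
spatially structured background, FA splitting/merging, peptide-level MS
effects (shared peptides, razor assignment, intensity-dependent
missingness). Recovery metrics here certify the analysis chain's
correctness on data that satisfies its assumptions, not robustness to
every real-world artifact.

## Validation problem sizes and numerical choices

The acceptance benchmarks use: 50 scenes × 8 FAs at 192×192 px / 0.16
µm px⁻¹ for segmentation recovery; exhaustive multiset pairs up to size 5
over a 3-value alphabet (3025 pairs) for the KS oracle; 20 random 16×16
rasters for coloc oracle equivalence and 200 for range invariants; 300
length trajectories at 0.05-µm noise for classifier accuracy; 300
single-FA movies (96×96 px, 8 frames at 3-s intervals, 60% distal / 20%
central / 20% medial hot spots) for peak scoring; one 20-frame movie with
a 50% inhibitor step; a 30/30/25 growing/stable/shrinking cohort with a
+0.2 planted stable-state offset; and a 1000-protein table with 50
planted 8-fold hits (ratio log-sd 0.3) for the screen. These sizes were
chosen to give the recovery statistics useful precision while keeping a
full validation run around half a minute.

Numerics worth knowing: thresholds are strictly greater-than; connected
components are 8-connected; ellipse axes are floored at one pixel; the
ray-march step for r_rel is 0.25 px; patch resampling and polar
unwrapping use bilinear interpolation (order 1) with zero padding; ratio
pixels with denominator ≤ 1e-9 are undefined; ANOVA on a zero-variance
cohort reports p = 1 and skips the post-hoc; the KS p-value is
asymptotic and not meaningful below a handful of points even though the
distance is exact.

## Known limitations

- The auto-*k* plateau heuristic is a reproducible stand-in for manual
  threshold choice; on images with heavy-tailed background it can sit on
  a spurious plateau. Inspect the segmentation when in doubt and set *k*
  explicitly.
- The whole-image mean in the threshold couples the threshold to cell
  density/coverage.
- Greedy tracking is adequate for sparse, slowly moving adhesions; dense
  fields with crossings need a global assignment method.
- Peak-location scoring uses the global kymograph maximum; per-frame
  tallies would weight persistent dim hot spots differently.
- The motif scanner encodes only the minimal basophilic consensus; it
  does not replace trained phosphosite predictors and its scores are
  ordinal, not calibrated.
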