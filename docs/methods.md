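# Methods

## Scope and data model

The package analyzes already-aligned 4D BOLD volumes on a common voxel grid.
Rigid-body realignment and spatial normalization are deliberately out of
scope: they are orthogonal, heavyweight registration problems served by
existing tools, and the package consumes their outputs (aligned volumes plus
six-column realignment-parameter traces). Voxel indices are 0-based; mm
coordinates follow the NIfTI affine, assumed RAS+ for synthetic data. Motion
files store rotations in radians (the prevailing rp-file dialect); the QC
thresholds are stated in degrees and converted at comparison time.

TR defaults to 3.0 s and is read from the NIfTI header time step, with a
config override because headers are frequently wrong in the wild.

## Preprocessing

Per subject, in order: discard the first 5 volumes (scanner steady-state and
subject accommodation); motion QC; Gaussian smoothing (8 mm FWHM); per-voxel
linear detrend; ideal band-pass 0.01–0.08 Hz.

* **Motion QC** fails a subject iff any per-axis |translation| ≥ 10 mm or
  any per-axis |rotation| ≥ 1°. The 1 cm limit is unusually permissive by
  modern standards but is the classical threshold pair this workflow used;
  both limits are config-exposed. Per-axis maxima (rather than a combined
  displacement norm) match the axis-wise way the limits are stated.
* **Smoothing** uses the sampled-Gaussian kernel with
  σ = FWHM/(2√(2 ln 2)) per axis in voxel units, renormalized over in-mask
  support: the smoothed image is divided by the smoothed mask indicator, so
  a constant in-mask image stays exactly constant and out-of-mask voxels
  never leak in. With FWHM = 0 smoothing is the identity.
* **Detrending** removes each voxel's least-squares line, intercept
  included. Removing the mean as well as the slope is immaterial downstream:
  correlations and rank statistics are invariant to it.
* **Band-pass** is an ideal frequency mask on the DFT with bins
  f_k = k/(n·TR): coefficients strictly below the low edge, strictly above
  the high edge, and the zero-frequency term are zeroed. An ideal filter was
  chosen over Butterworth because it is deterministic, exactly idempotent,
  and matches the behavior class of the classic resting-state toolkits this
  workflow descends from. The band must end below Nyquist = 1/(2·TR).

Stage order is governed by a flag. The default `paper` order smooths
*before* ReHo, reproducing the workflow as practiced in the source study;
conventional ReHo practice computes W on unsmoothed data because smoothing
itself manufactures neighborhood correlation (see Limitations). Under
`conventional`, smoothing is skipped in the volume chain and the W map is
smoothed after the fact.

## Regional homogeneity

Each in-mask voxel's series and those of its in-mask neighbors from the
cubic 27-neighborhood (19 and 7 available) are ranked over time with average
ranks for ties, and Kendall's W is computed from the rank sums. The
implementation uses the rank-sum form (Σ Rᵢ² − n R̄²)/((1/12)K²(n³−n)); tests
verify it against the equivalent deviation form 12·S/(K²(n³−n)) to 1e-12 and
against the Friedman statistic via χ² = K(n−1)W on small untied cases.

Numerical choices: no tie-correction denominator term (BOLD series are
continuous, exact ties measure-zero — a documented limitation for quantized
inputs); W clamped to [0,1] only against floating slop ≤ 1e-12; boundary
voxels keep truncated neighborhoods (effective K < 27) rather than being
dropped, preserving map support and cluster geometry, and are flagged;
voxels with effective K < 2 get W = 0 and a flag. No division by the global
mean W ("mReHo") by default, since raw W values are what the group contrast
compares; standardization is available for sensitivity analysis.

## Seed-based functional connectivity

The seed is the set of voxels whose centers lie within 10 mm (≤ comparison,
no partial-volume weighting) of the precuneus center (−12, −47, 32) mm,
intersected with the brain mask; on a 3 mm grid with a voxel center on the
seed center this is 171 voxels. The seed series is the unweighted voxel
mean. Voxelwise Pearson r against it is transformed with z = arctanh(r);
|r| ≥ 1 − 1e-7 is clamped and flagged. Some older toolchains print the
plain ratio (1+r)/(1−r) in place of Fisher's transform; a `legacy_ratio`
flag reproduces that form for comparison only — it is not variance-stabilized
and unsuitable for normal-theory group tests. Seed voxels stay in the
analyzed mask (their r ≈ 1 by construction); group contrasts are unaffected
because both groups share the seed.

## Group statistics

Classical equal-variance pooled two-sample t per voxel (not Welch),
df = n₁ + n₂ − 2, sign convention patients − controls so deficits are
negative; one-sample t for within-group maps. Zero-variance voxels are
flagged with t = 0 rather than propagating NaN. p maps are two-tailed
Student tails; z maps are sign-preserving probability-matched normal
quantiles computed on the complementary tail so large |t| stays accurate.

Cluster thresholding: voxels with two-tailed p < 0.001 are split by t sign
and labeled into connected components (26-connectivity default, 6/18
configurable — corner-touching voxels connected); components with strictly
more than 50 voxels are kept ("> 50" read strictly, minimum 51). Each
cluster reports its maximal-|t| voxel as peak with mm coordinates and
hemisphere from the sign of peak x. No multiple-comparison correction is
applied beyond the extent heuristic; the output metadata records this.

The printed T→Z pairs in historical peak tables of this workflow are not
reproducible by probability matching at the stated df, so peak Z values here
are always the probability-matched conversion and are not calibrated to any
external table.

## Cohort table

Two-group ANOVA for continuous variables (F = t² of the pooled t, identical
p). Pearson chi-square *without* Yates continuity correction for categorical
variables — the uncorrected statistic is what reproduces the published
p = 0.73 for the 2×2 sex comparison (the corrected one gives ≈ 0.87). The
exact conditional test is used whenever any expected cell count is below 5
(the standard reading of the "n < 5" rule), implemented as full enumeration
of r×c tables with fixed margins under the multivariate hypergeometric null,
two-sided by summing probabilities ≤ that of the observed table; it refuses
totals above 500 (configurable) and defers to chi-square. Group sizes and
percentages always come from the manifest actually supplied, never from
assumed counts.

## Synthetic cohort

The generator emulates the *statistical* structure of a two-group
resting-state study, not scanner physics: no slice timing, susceptibility,
or anatomy — an ellipsoidal "brain" (92% of the half-extents) on a
desk-scale 26×30×26 grid at 3 mm (full-size grids supported, not default),
140 acquired timepoints at TR 3 s.

Per subject, each voxel's series is the sum of: white noise (sd 6, putting
raw voxelwise SNR near 0.1, the right order for unsmoothed BOLD); a random
linear drift (slope sd 0.03, removed exactly by detrending); and
band-limited unit-variance signals built by applying the same 0.01–0.08 Hz
frequency mask used in preprocessing to white noise — guaranteeing the
implanted structure survives filtering unchanged.

* **Seed/DMN structure.** The seed sphere carries c_max·d(t), where d is the
  subject's DMN signal and c_max the larger group coupling. Each DMN node
  sphere carries c·d + √(c_max²−c²)·e with e an independent node signal and
  c the subject's coupling (group mean ± subject jitter, sd 0.06, clipped to
  [0, c_max]). The complement term keeps total coherent power — and hence
  regional homogeneity — identical across groups, so the FC contrast and the
  ReHo contrast are implanted in disjoint locations and are separable by
  construction. Ground-truth FC effect voxels are the DMN node spheres.
* **ReHo structure.** Each designated sphere adds w·l(t), an ROI-common
  signal uncorrelated with the seed (weight w per group ± jitter sd 0.04),
  raising neighborhood concordance without creating seed coupling.
* **Motion.** Smooth random walks (moving-average-filtered), compliant
  subjects peaking well below the QC limits; designated outlier subjects
  violate one randomly chosen axis (11–15 mm or 1.2–1.8°), so the QC rule
  identifies exactly the designated set.
* **Demographics** echo the matched case–control structure: ages
  N(27.9, 8.3) / N(29.1, 7.5) for patients/controls clipped to the
  recruitment range, balanced sex, education in three levels.

Determinism: one `SeedSequence` per cohort spawns independent per-subject
substreams, so a subject's data is reproducible bit-for-bit and independent
of generation order.

**Effect-size defaults.** The study provides no empirical effect sizes, so
the defaults are set by a power analysis targeting in-ROI group |t| ≈ 8 at
20 vs 20 — comfortably detectable at voxelwise p < 0.001 (t ≈ 3.57 at
df = 38) while keeping the smoothing halo around the implanted spheres to
about one voxel, so recovered clusters track ground truth tightly. The
analysis accounts for the effective temporal degrees of freedom of
band-limited series (≈ 56 of 135 samples in a 0.01–0.08 Hz band, not 135)
when estimating between-subject variance of z and W. This yields coupling
0.85 (controls) vs 0.40 (patients) and local weight 0.90 vs 0.40. At the
default seed the pipeline recovers the implanted effects with Dice ≈ 0.70
(FC) and ≈ 0.87 (ReHo) and reports no opposite-sign clusters.

## Validation experiments and problem sizes

* **Recovery** runs the full chain in memory on the default 20 vs 20 cohort
  (~30 s on one CPU) and measures the Dice overlap between the union of
  decreased clusters and the implanted voxels, per contrast.
* **Null type-I calibration** uses 10 replicate cohorts of 10 vs 10 on a
  14³ grid with identical group parameters and smoothing disabled — without
  smoothing the voxel tests are spatially independent, so the aggregated
  false-positive count is genuinely binomial and the nominal 0.001 level can
  be checked against an exact error bar. It also counts significant clusters
  per null map (expected ≈ 0).
* **ReHo null mean** samples W on a stride-3 interior lattice (disjoint
  neighborhoods, hence independent values; 512 voxels on a 26³ grid) and
  checks the analytic E[W] = 1/K within 3 empirical standard errors.

These sizes were chosen so the whole validation battery completes in about
a minute while leaving the statistical checks well-powered.

## What passing tests do and do not show

The synthetic cohort validates the *computational* chain: that the
statistics are computed correctly, the null calibration holds, implanted
effects of realistic magnitude are recovered in the right place with the
right sign, and QC exclusions propagate. It does not validate performance on
real data — no physiological noise spectra, spatial autocorrelation beyond
the smoothing kernel, motion-correlated artifacts, registration error, or
anatomical variability are simulated. Conclusions about sensitivity or
specificity on real cohorts do not follow.

## Known limitations

* Smoothing before ReHo (the default, faithful order) inflates baseline W
  everywhere by manufacturing local correlation; between-group contrasts are
  unaffected because both groups share the kernel, but absolute W values are
  not comparable across smoothing choices. The `conventional` order is
  provided for that reason.
* No tie correction in Kendall's W: heavily quantized series would bias W
  downward.
* Uncorrected cluster-extent inference does not control familywise error;
  it reproduces the historical practice, and the metadata says so.
* The exact r×c test is exhaustive enumeration — fine for cohort tables,
  infeasible for large totals (it refuses and defers to chi-square).
* The motion model is a smooth random walk; it generates QC-relevant
  amplitudes but not realistic motion spectra or spin-history artifacts.
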