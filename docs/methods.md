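# Methods

## Scientific setting

`limbictex` analyzes longitudinal structural-MRI plasticity at the level of
anatomically defined regions of interest (ROIs). The target design is a
three-group psychosis cohort: patients treated with electroconvulsive
therapy plus medication (ECT), patients treated with medication only (MED),
both scanned at baseline and follow-up, and a cross-sectional healthy
control (HC) group used purely as a normative reference. Fourteen bilateral
limbic ROIs (hippocampus, amygdala, accumbens area, ventral diencephalon,
caudal and rostral anterior cingulate, parahippocampal gyrus) are consumed
as a FreeSurfer-style integer label map aligned to the T1-weighted
intensity volume.

Two outcome families are extracted per ROI:

* **Gray-matter volume**, computed as voxel count × voxel volume (mm³)
  from the label map. This is deliberately not a surface-based or
  partial-volume estimate: the package consumes label maps only, and the
  downstream interaction statistics are invariant to any consistent volume
  definition.
* **GLSZM texture features.** A *zone* is a maximal 3D-connected set of
  voxels sharing a discretized gray level; the gray level size zone matrix
  P(i, j) counts zones of level i and size j. Sixteen standard scalar
  features summarize P, including large area emphasis
  (LAE = Σ P(i,j)·j²/Nz), the coarseness measure that is the pipeline's
  primary texture outcome. GLSZM features are rotation independent by
  construction, which suits neuroimaging data that may be rotated during
  processing.

## GLSZM computation

1. **Discretization.** Within-ROI intensities are binned into a fixed
   *count* of equal-width levels (default `n_bins = 16`) spanning the
   per-ROI min–max range. Fixed-count binning is invariant to positive
   affine rescaling of the intensities, which matters because synthetic
   and scanner intensities live on different scales. A fixed-width mode is
   not provided; if parity with a specific published feature value is
   needed, the bin count is the only knob. A constant ROI legally maps to
   a single level (Ng = 1), giving LAE = N², SAE = 1/N², GLV = 0.
2. **Zone labeling.** Connected components of equal-level voxels under a
   26-neighborhood by default (6 and 18 selectable), computed with
   `scipy.ndimage.label` on the ROI's bounding box (voxels outside the ROI
   are background). Every ROI voxel belongs to exactly one zone, so
   Σ P(i,j)·j equals the ROI voxel count — a conservation law the test
   suite asserts on random grids.
3. **Matrix and features.** P is stored sparsely over *observed* levels
   and zone sizes; a dense size axis of length N would be wasteful and
   every formula touches only observed (i, j) pairs. The gray-level mean
   used by gray level variance is the zone-weighted mean μ = Σ p(i,j)·i of
   the normalized matrix. Zone entropy uses log₂ over positive p only.

ROIs smaller than `min_voxels = 10` are rejected as degenerate — a size
zone matrix over a handful of voxels is noise, not texture. Intensity and
label grids must be identical; no resampling is performed, because
interpolation would manufacture texture. The affine is carried for
provenance but never used in computation (coordinates are 0-based array
indices).

## Normalization and feature selection

Texture features are z-scored per (ROI, feature) against the HC baseline
sample mean and sd (ddof = 1), so normal anatomical differences between
ROIs cannot leak into the scores; patient values at both timepoints are
transformed with the same HC statistics. Zero-variance reference pairs are
dropped with a warning; fewer than 3 HC subjects per pair is an error.

To reduce the 16 features to a representative subset, PCA runs on the
z-scored HC observations, pooling HC subject × ROI rows into one matrix of
16 feature columns (pooling yields a single feature set applied to every
ROI; a per-ROI mode exists for sensitivity analyses). The smallest number
of components whose cumulative explained variance reaches the threshold
(default 0.90) is retained, and each retained component contributes the
feature with its largest absolute loading; a feature already chosen falls
through to the next-largest loading, so selections are distinct. Loading
sign is ignored, and exact magnitude ties break by the canonical feature
order, making selection deterministic. On the default synthetic cohort
this yields five components above 90% — the same component count the
pipeline is designed around.

## Longitudinal inference

For each (ROI, outcome) the group×time interaction is estimated with a
linear mixed model (subject random intercept, REML via statsmodels):

    y_ist = β0 + β_g·group + β_t·time + δ·(group×time) + γ'·covariates + a_s + ε_ist

with MED and baseline as reference levels, so δ is the ECT-specific change
difference. Covariates default to age, sex (binary indicator), and
olanzapine-equivalent antipsychotic dose; volume models additionally
adjust for estimated intracranial volume (eTIV) when the manifest provides
it. Inference on δ uses a Wald t with between–within denominator df
(n_obs − n_subjects − 2, the two within-subject terms being time and the
interaction). With two complete timepoints this reproduces the two-sample
t-test on change scores exactly; the REML optimizer is polished with
Powell steps so the agreement holds to ~1e-8 in p, and the test suite
asserts it to 1e-6. Satterthwaite df are not available in statsmodels;
the between–within choice is exact in the balanced 2-timepoint design this
pipeline targets. If the REML fit fails to converge, the model is refit as
OLS on within-subject change scores with the same covariates (the same
estimand at two timepoints) and flagged `change_score_ols` in the output.
Rows with missing outcome or covariates are dropped listwise with a logged
count; constant or collinear design columns raise an error naming the
column.

Multiple comparisons use Benjamini–Hochberg FDR within two families:
volumes (14 ROI tests) and texture (selected features × 14 ROIs, i.e. 70
tests when five features are selected). The family partition is
configurable since reasonable alternatives exist (e.g. per-feature
families).

Texture (ROI, feature) pairs significant after FDR proceed to
repeated-measures correlation (rmcorr) against the clinical scores (PANSS
total, positive, negative, general; CGI-S), separately per patient group —
the scientific contract being that coupling between texture change and
symptom change should appear in the ECT group and not in the MED group.
rmcorr estimates the common within-subject correlation by ANCOVA with
subject as a factor (implementation: `pingouin.rm_corr`), with df = N − 1
at two visits; its confidence interval uses the Fisher z transform with
that df. BH correction is applied across the five clinical variables
within each (ROI, feature, group). Degenerate inputs (all within-subject
x-changes zero, fewer than 3 subjects, unequal visit counts) are errors.

## Synthetic cohorts

The generator exists so every stage of the pipeline — including image I/O
— can be exercised and calibrated without any acquired data. Its defaults
are the study conditions the pipeline targets: group sizes 36/27/70
(ECT/MED/HC), voxel size 1 × 0.98 × 0.98 mm, fourteen disjoint ellipsoidal
ROIs placed on an 18-voxel lattice in a 64³ grid, HC scanned once and
patients twice.

* **Texture** is a Gaussian random field: white noise smoothed with an
  isotropic Gaussian kernel of width σ voxels, masked to the ROI
  ellipsoid. σ is a single interpretable coarseness knob: larger σ gives
  larger same-level zones and hence higher LAE (the suite checks
  LAE(σ=2) > LAE(σ=0.5) in ≥95% of seeded draws). Alternatives (Perlin
  noise, blob processes) were rejected as adding parameters without adding
  a clearer dial. Note that because discretization is range-based and
  scale-invariant, LAE does *not* converge to the constant-image value N²
  as σ → ∞; it plateaus once σ exceeds the ROI scale. HC fields use
  σ = 1.6, patients start at σ = 1.25 (a coarseness deficit whose
  normalized LAE sits near −1 HC-sd, matching the magnitude of published
  patient–control differences this design emulates), and at follow-up the
  ECT group's σ rises by `texture_effect` (default 0.22, ≈ +0.5 HC-sd of
  LAE) toward the HC value while MED is unchanged in expectation.
* **Volumes** carry an analogous planted group×time increment in mm³
  (default 45) implemented by rescaling the ellipsoid semi-axes to the
  target analytic volume; voxelization adds integer-count noise but tracks
  the planted effect with near-unit slope.
* **Clinical scores** draw baselines from group-specific normal
  distributions with the means and sds of the target cohort description;
  in the ECT group the change in each score is linearly coupled
  (negative slope) to the subject's standardized planted texture change in
  the coupling ROI plus noise, while MED changes are independent noise.
  Scores are clipped to their valid ranges (PANSS total 30–210, subscales,
  CGI-S 1–7) with clipping logged.
* **Determinism:** one `numpy` Generator seeded from the spec drives
  everything; identical specs produce bit-identical arrays and NIfTI
  bytes (uncompressed `.nii`, so no gzip timestamps).

A second, outcome-level simulator (`simulate_feature_table`) draws
two-timepoint values directly from the mixed model above (subject sd 1.0,
residual sd 0.7, small nonzero covariate effects, interaction expressed in
units of the change-score sd). It exists for Monte Carlo calibration —
type-I error, bias, power — where rendering images would add runtime but
no information about the model under test.

### What the generator does and does not emulate

It reproduces the *statistical* structure the analysis assumes: group
sizes, two timepoints, HC-referenced normalization, a texture effect that
is monotone in a single latent coarseness parameter, volume effects in
mm³, and ECT-only texture–clinical coupling. It does not attempt brain
anatomy, scanner noise spectra, bias fields, motion, partial-volume mixing
at ROI borders, or segmentation error. Passing tests therefore demonstrate
that the pipeline recovers effects of the assumed form at realistic sample
sizes — not that any particular acquired dataset satisfies those
assumptions.

## Calibration results computed by the suite

The acceptance layer (tests and `scripts/acceptance.py`) recomputes, from
scratch at fixed seeds: exact agreement of zones and features with a
brute-force flood-fill + direct-formula oracle on random grids (≤ 6³,
Ng ≤ 4); bit-identical features under all 24 axis-aligned rotations;
the constant-ROI closed forms; mixed-model type-I error within
[0.035, 0.065] at α = 0.05 over 1000 null replicates; recovery of a
planted δ = 1.0·sd interaction at n = 36/27 with |relative bias| < 5% and
power ≥ 0.8 over 500 replicates (texture- and volume-scaled outcomes);
rmcorr r = ±1 in noiseless collinear data and simulation means within
0.05 of the analytic within-subject correlation; and the end-to-end
ECT-only coupling contrast on image cohorts. Monte Carlo problem sizes in
the standalone script (600/300/300 replicates, three image cohorts of
20/20/24 subjects × 4 ROIs on a 40³ grid) are chosen so the whole script
reruns in a few minutes on one CPU; the test suite uses the full replicate
counts above.

## Known limitations

* Discretization settings for published feature values vary between
  studies; no parity with any specific published absolute feature value is
  promised (the bin count is configurable).
* statsmodels provides no Satterthwaite df; outside the balanced
  two-timepoint design the between–within df is an approximation.
* The FDR family partition and the scope of rmcorr correction (across
  clinical variables within a pair) are conventions; both are documented
  here and configurable rather than asserted as the only defensible
  choice.
* HC subjects are treated as single-timepoint; the reference is assumed
  stable over the study interval.
* Volumes are voxel counts — systematically different from surface-based
  estimates, though interaction tests are unaffected by a consistent
  offset or scale.
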