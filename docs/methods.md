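# Methods

This note documents the models, conventions and numerical choices behind
`lungvar`, and what the synthetic experiments do and do not demonstrate.

## Coordinate and rotation conventions

All positions are millimetres in a patient-based right-handed frame:
RL = x (toward patient left), AP = y (toward posterior), CC = z (toward
superior) — the DICOM patient (LPS) convention.  Rotations are intrinsic
rotations about RL, AP, CC in that order, reported in degrees.  All modules
share this frame.

## Synthetic cohort model

The generator emulates the statistical structure the analysis assumes, not
the imaging physics.  Per subject, a canonical landmark template (spinal
reference Ref_SC, apex, carina, diaphragm, six vessels in three
cranio-caudal bands with one left and one right vessel each, plus four
auxiliary paravertebral spine points) is scaled by a sex-dependent factor
(mean 1.05 men / 0.93 women, SD 0.06) and jittered per structure
(SD 3 mm).  Per scan,

    position = setup transform (canonical) + anisotropic Gaussian noise,

where the rigid setup transform is shared by all scans of a visit (visit 1
is the identity reference) with translations N(0, 3 mm) and rotations
N(0, 1.5°) per axis — so a 3° rotation sits near the 95th percentile, an
upper-bound illustration rather than a typical value — applied about the
subject's Ref_SC.  Ref_SC and the spine points receive the setup transform
but no respiratory noise: they are motion-invariant by construction.

Respiratory/method noise is independent anisotropic Gaussian per method ×
structure × axis.  This is the simplest model consistent with per-axis SD
summaries, which is all such studies report.  Defaults (mm, RL/AP/CC) encode
the qualitative pattern of the reference design: noise largest in AP and CC;
HFPV ≈ 3× eDIBH at the diaphragm and ≈ 2× at the lower vessels; carina and
left-mid vessel moderately worse under HFPV; apex and upper vessels nearly
method-independent.  The magnitudes are package choices (roughly 1–3.5 mm
eDIBH, up to 5–10.5 mm HFPV at the diaphragm) — published summaries of this
kind are graphical, so the defaults are stated here and in `CohortConfig`
rather than claimed to match any measured dataset.  An optional
`percussion_extra_sd` adds isotropic HFPV micro-oscillation noise
(default 0: the effect is expected at millimetre scale but unmeasured).

Lung volumes: per-scan volume = method/sex mean + subject effect + visit
effect + scan noise.  Defaults: eDIBH 6.5 L (men) / 4.5 L (women), HFPV
about 1 L lower (5.4 / 3.6 L); between-subject SD 1.25 / 0.8 L, between-
visit SD 0.15 L, within-visit SD 0.20 L (eDIBH) and 0.40 L (HFPV) — HFPV
twice as variable within a visit.  The subject effect is shared between
methods (same lungs).  Intra-breath-hold drift is modelled separately
(`simulate_volume_drift`) as linear in time with a default bound of 5 % per
70 s — the minimal model consistent with endpoint fractions; it is not
added to per-scan landmark noise.

Not modelled, hence not demonstrated by passing tests: per-subject
differences in *method response* (every synthetic subject shares the same
noise model, so synthetic cohorts favour eDIBH more uniformly than a real
cohort, where a minority of subjects do better under HFPV); breath-hold
physiology (durations, SpO₂, gas exchange); MRI artefacts beyond additive
Gaussian intensity noise in phantoms; deformation (all motion is additive
noise about a rigid transform).

## Phantoms

`render_phantom` produces a bright body ellipsoid on a dark background with
two dark ellipsoidal lung compartments and six bright vessel blobs
(radius 4 mm).  Lung semi-axes are scaled uniformly so the analytic air
volume (two ellipsoids minus blobs) equals the requested target exactly;
geometry that would overlap the lungs or breach the body raises an error
rather than silently corrupting the ground truth.  Default grid: 512 × 512
× 100 voxels at 0.7617 × 0.7617 × 2.2 mm, coronal planes stacked along AP.

## Segmentation

Per-plane threshold: Otsu's two-class between-variance criterion —
deterministic and parameter-free; the air compartment is *below* threshold
(lungs are dark on T2-weighted MRI).  Constant-intensity planes are flagged
degenerate and left empty.  Per-plane components touching the image border
are removed (suppresses background air around the body) along with
components under 50 pixels (noise floor; configurable).  3D clustering uses
26-connectivity; up to the two largest clusters are kept (one if the lungs
merge at the hila), with a 100-voxel cluster floor.  All retained air
clusters count toward "lung volume"; trachea/airways are not subtracted.
On noisy phantoms the recovered volume is within a few hundredths of a
percent of the analytic truth — far inside both the 2 % bound the tests
assert and the 10 % accuracy usually considered sufficient for automated
lung volumetry.

## Registration and translation-only correction

Setup transforms are estimated per subject × method × visit × scan against
scan 1 of visit 1 by closed-form least-squares point matching (Kabsch SVD
with reflection guard) on the spine landmarks; visit-1 transforms are taken
as identity (the within-visit repositioning between two consecutive scans
is negligible by design).  At least three non-collinear spine points are
required; the generator emits four auxiliary points around Ref_SC.

The translation component of a rigid transform depends on the coordinate
origin.  `estimate_rigid` therefore anchors the rotation at the fixed
spine-point centroid, making the translation component the displacement of
the spine region — exactly the quantity a translation-only couch correction
nulls.  After correction, the residual displacement of a structure at lever
arm L from the spine under an uncorrected rotation θ is L·sin θ
(≈ L·θ for small angles): 100 mm and 3° give ≈ 5 mm, the worked example
`rotation_residual_offset` reproduces, and
`rotation_contribution_estimate` uses the same geometry to attribute a
fraction of observed per-axis SD to uncorrected rotations.

## Statistics

* Fractional variation: sample SD (n−1 denominator, n = 8 scans) over mean
  of the radial distances.  The radial distance is computed within a scan,
  so it is invariant to the scan's rigid setup transform; the γ analysis
  therefore runs on uncorrected landmarks.
* γ uses log base 10.  Only the sign is interpreted, so the base is a free
  choice; 10 keeps magnitudes readable.  γ = 0 (a tie) favours neither
  method and is excluded from negative counts; undefined entries (a zero
  fractional variation) are excluded and reported.
* Wilcoxon signed-rank: two-sided, exact null distribution for n ≤ 25,
  zero differences dropped (standard convention); identical paired samples
  give a degenerate test reported as p = 1.  Fewer than 6 pairs flags the
  p-value unreliable.  Per-subject fractional variations are the paired
  observations (n = 21 pairs per structure in the reference design).  No
  multiple-testing correction is applied across the nine structures (raw
  p-values are reported, as is conventional for this table).
* Binomial preference model: the pooled MLE is total negatives / total
  trials (10 per subject).  A published value of 0.87 for a comparable
  grid is not derivable from pooled counts (140/200 = 0.70); the package
  additionally reports a truncated-binomial MLE fitted on clearly
  distinguished subjects only (counts ≥ 8 or ≤ 3; 0.001 grid search),
  without claiming either estimator reproduces that figure.

## Volumes of variability

Clusters of corrected positions (8 per structure × method) are summarised
by per-axis sample SDs.  The 95 % CL ellipsoid is axis-aligned with
semi-axes k·σ_axis, k = √χ²₀.₉₅(3 df) ≈ 2.7955 — chosen to match the
Cartesian per-axis SD reporting; a covariance-eigenvector (PCA) variant is
available via `ellipsoid_volume_95(..., use_pca=True)`.  Whether a
particular published analysis scaled by k or used raw SDs is immaterial for
the reported *ratios* of volumes, which are k-invariant.  Degenerate
clusters (any zero SD) get VolOfVar 0, are flagged, and are excluded from
ratio counts.  Normalisation uses the subject's per-method mean lung
volume (consistent with the per-method VolOfVar; generator-true volumes by
default, segmented volumes when images are supplied).  Only the six vessel
structures enter the ratio analysis (apex/carina/diaphragm appear in the
axis-SD tables only).

## Problem sizes and controlled conditions of the validation experiments

The recovery experiments in `tests/test_acceptance.py` and
`scripts/acceptance.py` use conditions chosen to isolate the quantity being
validated:

* γ recovery: 20 subjects × 100 seeds, isotropic noise with HFPV/eDIBH SD
  ratio κ = 2; median γ ≈ −log₁₀ 2 = −0.301.  The median of a log-ratio of
  equal-df sample SDs is unbiased, so no small-sample correction is needed.
* VolOfVar recovery: same design with setup rotations disabled and equal
  method volume means, because the shared rotation residual would inflate
  both methods' clusters and the method volume offset would shift the
  fractional ratio — both would confound the σ³ scaling being checked
  (median log-ratio ≈ −3 log₁₀ 2 = −0.903).
* Null calibration: κ = 1 over 2250 subject-structures (negative-γ fraction
  0.50 ± 0.03) and 1000 replicates of the 21-subject signed-rank test
  (type-I error 0.05 ± 0.02); the reduced two-structure cohort keeps the
  replicate loop fast without changing the statistic.
* Ellipsoid coverage: 10⁵ Gaussian samples; expected inside-fraction
  0.950 ± 0.005 validates the χ² quantile.
* Phantom recovery: 10 phantoms with targets uniform in 3–7 L at the
  default acquisition grid, intensity noise SD 3 on a 10–200 intensity
  scale; asserted within 2 % of analytic truth.

Unit tests use coarser grids (e.g. 192 × 192 × 100 at ~2 mm in-plane) and
smaller cohorts; these sizes are package choices balancing statistical
resolution against a quick default test run.

## Known limitations

* Landmark tables replace image registration: the rigid fit consumes
  explicit spine points, not image intensities.  Sensitivity to the number
  of spine points is exercised in tests (3 is the minimum; the default 5
  including Ref_SC makes noisy recovery comfortably stable).
* NIfTI is the supported image format; DICOM series are out of scope.
* The γ and VolOfVar analyses assume equal scan counts per method and
  ignore within-visit correlation beyond the shared setup transform.
* Cohort-level inference beyond the signed-rank table (ANOVA, correlation
  analyses, demographics) is out of scope.
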