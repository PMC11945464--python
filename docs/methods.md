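# Methods

## Model and assumptions

`relaxnorm` operates entirely in a standardized voxel space: every volume of
an analysis (control R1 maps, WM probability maps, subject maps, atlas
coefficient maps) must share one grid, and the package verifies shapes and
affines (relative tolerance 1e-6) at every entry point rather than
resampling. Registration, segmentation and skull stripping are upstream
concerns.

The normative model is an independent ordinary-least-squares fit per voxel
of R1 on `[1, a, a²]` with `a = age − ā`, `ā` the unrounded mean age of the
control cohort. Centering makes the intercept map directly interpretable as
the expected R1 at the cohort's mean age and decorrelates the intercept from
the age terms. The quadratic captures the inverse-U adult trajectory of R1;
no sex term is fit (the reference cohort is male-only), but
`fit_atlas(extra_covariates=...)` accepts additional design columns. The fit
requires ≥4 subjects and ≥3 distinct ages (otherwise the quadratic design is
rank-deficient) and is solved by QR-based least squares vectorized across
voxels; the test suite checks it against an explicit normal-equations solver
to 1e-8.

Single-subject deviation is `z(r) = (R1(r) − E{R1}(r; age)) / RMSE(r)`. The
model treats residuals as voxel-wise Gaussian with age-independent variance;
under that assumption z is approximately standard normal for a healthy
held-out subject, inflated slightly by estimation error of the coefficients
and the RMSE (the pooled held-out SD is ≈1.05–1.13 at n = 25, approaching 1
as the cohort grows — the cross-validation tests quantify this).

## Tunable parameters

| parameter | default | units | rationale |
|---|---|---|---|
| WM mask threshold | 0.5 | probability | mean WM probability must *strictly* exceed it; at 50% the GP is included, cortex is not |
| z threshold | 6 | SD | one-sided (Mn only raises R1); high because single-subject inference over ~10⁵ voxels needs a strong per-voxel guard |
| minimum cluster extent | 100 | voxels | retained iff size ≥ 100; suppresses isolated exceedances |
| connectivity | 26 | neighbors | face+edge+corner adjacency, the common default of neuroimaging cluster tools; 6 and 18 selectable |
| RMSE denominator | n−3 | — | residual degrees of freedom (unbiased variance convention); `rmse_denominator="n"` gives strict root-mean-square semantics |
| CV folds k | 10 | — | near-equal deterministic folds; every fold must leave ≥4 training subjects |
| FPR flagging threshold | 2 | SD | deliberately distinct from the detection threshold: at z₀ = 2 the voxel FPR has a clean analytic anchor, the Gaussian tail 1−Φ(2) ≈ 2.28% |
| CEI_3M threshold | 0.04 | mg/m³·yr | HEX iff strictly exceeded; compared as parsed, no epsilon |

Degenerate voxels — any subject non-finite, or residual SD numerically zero
(a perfect fit, e.g. noiseless synthetic data) — keep their coefficients in
the atlas maps but are removed from the analysis mask, because the z-score
divides by RMSE. A fully degenerate cohort therefore yields a valid atlas
with an empty scorable mask, and a held-out FPR of 0 by convention (no
scorable voxels, no false positives).

The false-positive rate is defined at the voxel level: flagged in-mask
voxels over total in-mask voxels per held-out subject, averaged over
subjects. A cluster-filtered variant (`min_extent=...`) counts only voxels
inside retained clusters. Both are exposed because published FPR figures for
this family of methods do not always state which convention (or threshold)
was used; at the detection defaults (z > 6, ≥100 voxels) the Gaussian null
FPR is bounded by the tail probability ≈1e-9 per voxel and is measured at 0.

## The phantom

The generator emulates exactly the structure the analysis assumes:

- **Geometry** — nested ellipsoids: background, a GM shell, a WM core, and
  two mirrored GP spheres (radius 6 mm, ±12 mm lateral offset). Default grid
  64³ at 1 mm isotropic; tests use 20³–32³.
- **Baselines** — R1 at the reference age (39 y): WM 1.07 s⁻¹, GP 1.10 s⁻¹,
  GM shell 0.77 s⁻¹, matching typical 3 T values for deep WM, pallidum and
  cortex.
- **Age dependence** — global coefficients (β_age 0.002 s⁻¹/yr, β_age²
  −0.0002 s⁻¹/yr²) applied inside the brain: a gentle rise around midlife
  with downward curvature, the inverse-U shape at magnitudes small against
  the tissue contrast. Per-voxel coefficient arrays may be substituted.
- **Residual noise** — per-subject Gaussian fields, SD 0.15 s⁻¹ (the
  frontal-WM population RMSE magnitude), smoothed with a 4 mm FWHM kernel to
  mimic the spatial correlation that registration and partial-volume effects
  induce in real residual maps; unsmoothed white noise would make
  cluster-extent correction trivially powerful. The smoothed field is
  renormalized by the L2 norm of the (periodic) smoothing kernel so the
  marginal per-voxel SD equals `noise_sd` exactly — the atlas RMSE then
  estimates a known truth, which the n = 200 recovery test exploits.
- **Lesions** — additive spheres (`delta_R1 ≥ 0`, Mn only raises R1);
  welders draw 0–3 lesions with radius 3–6 mm and ΔR1 0.4–1.2 s⁻¹, a range
  chosen so lesions span "clearly sub-threshold" to "unambiguous" against
  noise SD 0.15; no published per-lesion ΔR1 calibration exists.
- **WM probability maps** — the WM∪GP indicator blurred by a 1-voxel
  Gaussian, so the 50%-threshold rule reproduces the intended mask behavior
  (GP in, boundary softly eroded).
- **Metadata** — ages uniform whole years over (20, 61); exposure indices
  drawn from ranges typical of welding cohorts (welder air Mn
  0.05–0.48 mg/m³, CEI_3M up to 0.18, CEI_Life up to 4.8 mg/m³·yr; controls
  near zero).

What the phantom does *not* emulate: anatomical realism, acquisition physics
(B1 inhomogeneity, noise rician-ness), registration error, per-tissue or
age-dependent residual variance, and cortical misalignment. Passing tests
therefore demonstrate the statistical machinery — mask logic, regression,
calibration, cluster correction, CV — not robustness to real-data artifacts.

## Numerical choices

- Volumes are promoted to float64 on read and written as float32; affines
  are preserved exactly. 4D files with a singleton last axis are squeezed.
- Thresholds are strict everywhere they appear (mean WM probability > 0.5,
  z > threshold, CEI_3M > 0.04), with the extent rule inclusive
  (size ≥ min_extent).
- Cluster labels are ordered by decreasing size, ties by smallest linear
  (C-order) voxel index; border-touching clusters are ordinary clusters.
  Peak reporting uses the first maximum in C order.
- The VFA fitter uses the exact two-point DESPOT1 linearization; slopes
  outside (0, 1) have no physical R1 and are marked NaN, which downstream
  stages treat as outside the mask. Nominal flip angles are trusted (no B1
  correction), appropriate for synthetic signals.
- Fold partition: one seeded permutation split into k nearly equal parts —
  deterministic, disjoint, covering.
- The pipeline runner writes uncompressed NIfTI so artifact hashes are
  byte-stable; rerunning a config reproduces every hash.

## Problem sizes

Tests and the acceptance script run on 16³–32³ grids with cohorts of 8–200
subjects: large enough that WM masks hold thousands of voxels and
Monte-Carlo estimates are stable (noise-SD and RMSE recovery use n = 200;
the Gaussian-tail FPR check uses n = 150 controls so finite-sample inflation
of cross-validated residuals stays small; lesion detection uses 40
independently seeded subjects against a 25-control atlas). The full suite
completes in well under a minute.

## Known limitations

- Norms are only as good as the reference cohort: n = 25 gives RMSE maps
  with ~15% relative error per voxel and held-out z SD ≈ 1.1; covariates
  beyond age (sex, scanner) require user-supplied design columns.
- No cluster-level p-values (random-field or permutation); the extent rule
  is a heuristic guard, not an error-rate guarantee.
- One-sided detection by design; the `two_sided` flag exists for exploratory
  use, e.g. R1-lowering pathology.
- The exposure classifier consumes CEI values as inputs; the exposure model
  that produces them (air-sampling extrapolation over work histories) is out
  of scope.
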