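# Methods

This note documents the models and procedures implemented in `blendspec`,
the defaults chosen where the design was genuinely open, and what the
synthetic study conditions do and do not establish about real data.

## Problem and model

A blended plant material is a physical mixture of K = 4 components whose
mass fractions sum to 1, with the dominant component constrained to
[0.60, 1.00] and each minor component to [0, 0.20].  Reflectance spectra of
the blend are acquired in two instrument ranges (Vis-NIR, 460–1020 nm, 400
bands; NIR, 975–1713 nm, 220 bands).  The working assumption throughout is
*approximate linearity*: the blend spectrum is close to the
proportion-weighted sum of pure-component (endmember) spectra, distorted by
per-scan multiplicative scatter and baseline effects.  That assumption is
what makes partial least squares regression an adequate calibration model
and multiplicative scatter correction a meaningful preprocessing step; the
package never clips reflectance to [0, 1] for the same reason (clipping
would break linearity).

## Reflectance calibration and ROI

Raw counts are converted per pixel per band as
R = (I_raw − I_dark)/(I_ref − I_dark).  Dark and white references may be
single frames broadcast across scan lines (push-broom practice: one
reference pair per session).  A zero denominator is a hard error naming the
offending band, since it indicates reference saturation.  The packaged
region-of-interest rule is an intensity threshold against the dark
background (band-averaged reflectance > 0.15 by default); real studies may
segment differently, and the threshold is exposed.

## Preprocessing

* Moving average (default window 5): uniform kernel, window shrinking
  symmetrically at the edges.
* Savitzky–Golay (default window 11, polynomial order 2): local
  least-squares polynomial fit; derivatives are SG derivatives scaled by
  the median wavelength step (units: reflectance/nm) and require a uniform
  grid.  Edges use polynomial extrapolation from the first/last full
  window.  Window sizes are conventional defaults, exposed in every plan.
* SNV: per-spectrum standardisation (n−1 denominator); constant rows are
  an error naming the sample.
* MSC: per-spectrum ordinary-least-squares regression on a reference
  (default: calibration-set mean); corrected spectrum (x − a)/b.  On
  prediction data the *stored* calibration reference is reused via
  `fit_plan`, never recomputed, to avoid leakage.

Plans are ordered step lists validated up front (odd windows, order <
window, derivative ≤ order, at most one scatter step).  An empty plan is
the identity and is a legal, sometimes winning, grid cell.

## Fusion

Feature-level fusion concatenates the per-range matrices (after any
per-range preprocessing) into one predictor block, keeping a per-column
source tag.  No resampling to a common grid and no per-block scaling is
applied.  The 975–1020 nm overlap is deliberately retained from both
instruments — the two detectors disagree there, and the
wavelength-selection stage is the arbiter of which columns carry signal.
Because nm values are ambiguous across instruments, fused columns are
addressed by a unified variable index plus (tag, wavelength) labels.

## Outlier screening

Spectra are projected onto the first two principal components (mean-centred
PCA, no variance scaling; k = 2 is the default because in this data class
PC1–PC2 carry the overwhelming share of variance, and it is exposed as a
parameter).  FAST-MCD then seeks the h = ⌊0.75 n⌋ subset with minimal
covariance determinant: 500 random elemental starts of size 3, two
concentration steps each, and the best 10 candidates iterated to
convergence.  Each C-step provably never increases the determinant; the
implementation asserts this per iteration and records the determinant
trace.  The estimator is deterministic given its seed, which is stored in
the report.

The raw h-subset covariance systematically underestimates the scatter of
the clean population (for 2 df and h/n = 0.75 by a factor of ≈ 1.86), so
distances measured against it would flag roughly 14% of clean samples at
the 97.5% ellipse.  `flag_outliers` therefore rescales the raw scatter by
the distance-median consistency factor median(d²)/χ²₀.₅(2) before applying
the cutoff √χ²₀.₉₇₅(2) ≈ 2.716.  This keeps the clean-data flag rate near
its nominal 2.5% level (measured ≈ 4% at n = 90; small-sample inflation
remains because no reweighting step is applied — the cutoff acts directly
on the consistency-scaled MCD estimates, and the screen over-flags somewhat
more at small n).  Ties at the cutoff are kept (strict inequality flags).
Screening runs once per spectra source on raw spectra; each source may drop
different samples, and all downstream models use each source's own kept
subset.

## Wavelength selection

* **VIP**: scores from a PLS fit,
  VIP_j = √(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a) with SSY_a = q_a² t_aᵀt_a;
  Σ VIP² = p by construction.  Selection keeps VIP > 1.0 by default.
* **SPA**: forward chains maximising the norm of the projection onto the
  orthogonal complement of the selected span; chain lengths 1..max_vars are
  compared by the exact LOOCV (PRESS) error of an intercept-included
  least-squares fit.  The default start policy scans all start columns and
  keeps the best chain; ties break toward fewer variables, then the lower
  start index.
* **CARS**: N = 50 Monte-Carlo runs; each run fits PLSR on a random 80%
  calibration subsample of the retained variables (LV count capped at 10),
  shrinks the retained set to an exponentially decreasing schedule count
  (all p variables at run 1, exactly 2 at run N) by weighted sampling
  *without* replacement with weights ∝ |regression coefficient|, and scores
  the run's subset by 5-fold cross-validation.  The subset with minimal
  RMSECV wins.  Sampling without replacement of exactly the scheduled count
  keeps the schedule endpoints exact while preserving the
  coefficient-driven competition.  All hyperparameters are exposed.

"No selection" is evaluated by the same protocol and is a legal winner.
Every selector records the RMSECV of its chosen subset and the seed that
reproduces it.

## PLSR and validation

Single-response NIPALS on mean-centred data (no autoscaling — reflectance
variables share units): per component w ∝ Xᵀy (unit norm), t = Xw,
p = Xᵀt/tᵀt, q = yᵀt/tᵀt, deflate.  Coefficients are collapsed to original
units via W(PᵀW)⁻¹q.  With a single response the inner iteration converges
in one step, so the fit is deterministic.  Zero-variance columns receive
exactly zero weight.

Validation is full leave-one-out cross-validation (no hold-out set, as is
standard at n ≈ 90).  Because NIPALS extracts components sequentially, one
per-fold fit at l_max yields held-out predictions at every smaller LV count
by truncation.  The LV count is chosen by the *first local minimum* rule on
the RMSECV curve: the smallest k with rmsecv(k) < rmsecv(k−1) and
rmsecv(k) ≤ rmsecv(k+1), with k = 1 qualifying when rmsecv(1) ≤ rmsecv(2);
if no local minimum exists the global minimum is used and the fallback is
recorded, never silent.  l_max defaults to min(20, n−2, rank(X)).

Metrics: R² = 1 − SSE/SST on the cross-validated predictions (may be
negative), RMSE with divisor n, RPD = sd(y; n−1)/RMSECV.  RPD is undefined
(error) at RMSE = 0.  Proportions are modelled as fractions throughout;
percentages appear only in rendered output.

Preprocessing (including the MSC reference) is frozen on the full
calibration block *before* cross-validation; the per-fold refit of
preprocessing is not performed.  This is a small optimistic bias shared by
most published calibrations of this type and is deliberate, documented
behaviour.

## Study orchestration

Three stages: raw models (4 targets × 3 sources), MCD-screened models
(per-source kept subsets), and an exhaustive grid over
{identity, MA(5), SG(11,2), MA(5)+1st derivative, SG(11,2)+MSC,
SG(11,2)+SNV} × {none, VIP, SPA, CARS}, scored by RMSECV with ties broken
toward fewer variables.  The grid replaces any automated
preprocessing-search framework with a fully enumerated, reproducible
comparison; the complete grid trace is persisted so selection optimism can
be audited (no multiple-testing correction is applied across the grid).
For the fused source the per-range blocks are restricted to the fused
screen's kept samples, preprocessed per range, then fused.  Identical
config and seeds give byte-identical output tables.

## Synthetic study conditions

The generator emulates the study structure: 30 recipes × 3 replicate scans
(replicates share the recipe's exact proportions, as when one physical
blend is remixed and rescanned); rejection sampling draws the minor
components uniformly and accepts when the dominant remainder is in range
(rejection occurs exactly when the minors exceed 0.40 in total).
Endmembers are smooth range baselines minus component-specific Gaussian
absorption bands: the dominant component carries a deep 650–700 nm
chlorophyll-like valley, all components share a 1450–1500 nm
water/cellulose trough with differing depths, and a 1650–1700 nm feature
stands in for the nicotine/polyphenol signature.  A `complementary` layout
makes one minor component spectrally invisible in each range, the
configuration used to demonstrate the fusion gain.

Default noise (additive sd 0.005, scatter slope sd 0.05, scatter offset sd
0.01, baseline amplitude 0.01, replicate jitter sd 0.003, all in
reflectance units) was fixed once so that raw-spectra models for the
dominant component land in a realistic high-but-imperfect accuracy band;
all amplitudes are config-exposed.  What the generator does *not* emulate:
scattering physics, particle-size/texture effects, detector-specific
artefacts in the overlap region, spatial structure beyond a uniform ROI,
and real between-replicate remixing variability (the jitter term is a
stand-in).  Passing tests therefore establish the *algorithmic* properties
of the pipeline (oracle equivalence, detector validity, recovery under the
stated mixing model), not instrument-level performance on real tobacco.

## Problem sizes and numerical choices

Tests and the acceptance script run at the study's native scale (n = 90,
620 fused variables) but bound the Monte-Carlo repetitions: 100 seeds for
detector recall, 200 score-level trials for the clean flag rate, 50 seeds
for the fusion-gain comparison (with l_max = 10 and 150–200 MCD starts in
the repeated studies).  These sizes were chosen to make the statistical
checks stable while keeping a full run in the low minutes on one core.
Degenerate inputs are errors, not silent repairs: collinear MCD scores,
constant SNV rows, MSC slopes below 1e-12, zero-variance responses, and
LV requests beyond the extractable rank all raise with the offending
sample/band named.  Floating-point tolerances in the contracts (1e-10 to
1e-12) reflect accumulation at these matrix sizes.

## Known limitations

* Robust screening uses raw-MCD-plus-consistency scaling without the
  reweighting/refinement step of reweighted MCD; at small n it over-flags
  mildly (documented above).
* The linear mixing law is an idealisation; strongly scattering or
  moisture-varying samples violate it in ways MSC only partly corrects.
* LOOCV with frozen preprocessing carries a small optimism; external
  validation on an independent batch is out of scope.
* Geometric/spectral co-registration of the two cameras and instrument
  control are out of scope; the package starts from cubes or spectra
  tables.
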