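# blendspec

Dual-range hyperspectral chemometrics for estimating the component
proportions of plant-material blends — built around the four-component
cut-tobacco blending problem, where a dominant component (tobacco silk,
60–100%) is mixed with up to three minor components (cut stem, fermented
cut stem, expanded tobacco silk, 0–20% each, summing to exactly 100%) and
scanned by two push-broom imagers: Vis-NIR (460–1020 nm, 400 wavelengths)
and NIR (975–1713 nm, 220 wavelengths).

The package is aimed at chemometricians and spectroscopists who want a
fully scripted, reproducible version of this kind of calibration study:
every stage is an importable function, every stochastic step takes a seed,
and a synthetic-data module generates study-shaped data so the whole
pipeline is testable without instrument access.

## What it implements

* **Reflectance calibration** of ENVI-style hypercubes,
  `R = (I_raw − I_dark)/(I_ref − I_dark)`, ROI mean-spectrum extraction and
  wavelength trimming (`blendspec.hsi_io`).
* **Preprocessing**: moving average, Savitzky–Golay smoothing and
  derivatives, SNV, MSC, and validated ordered chains of them
  (`blendspec.preprocess`).
* **Feature-level fusion** of the two ranges into one 620-variable matrix
  with per-column provenance; the 975–1020 nm overlap is kept from both
  instruments (`blendspec.fusion`).
* **Robust outlier screening**: PCA to the PC1–PC2 plane, FAST-MCD with
  h = ⌊0.75 n⌋, robust Mahalanobis distances, and the 97.5% chi-square
  (2 df) tolerance-ellipse cutoff (`blendspec.outliers`).
* **Wavelength selection**: VIP scores
  (`VIP_j = √(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a)`), the Successive
  Projections Algorithm, and Competitive Adaptive Reweighted Sampling
  (`blendspec.selection`).
* **PLSR** (single-response NIPALS, centring only) with leave-one-out
  cross-validation, the *first local minimum of RMSECV* rule for choosing
  the number of latent variables, and the standard calibration metrics

  `R² = 1 − Σ(yᵢ − ŷᵢ)² / Σ(yᵢ − ȳ)²`,  `RMSE = √(Σ(yᵢ − ŷᵢ)²/n)`,
  `RPD = sd(y)/RMSECV`  (`blendspec.plsr`).
* **Study orchestration**: raw-spectra models → MCD-screened models → an
  exhaustive (preprocessing × selector) grid scored by RMSECV, with CSV
  tables and a seed-recording manifest (`blendspec.pipeline`).
* **Synthetic data**: Gaussian-band endmembers, the constrained
  30-recipe × 3-scan blend design, linear mixing with multiplicative
  scatter / baseline drift / additive noise, and gross-outlier injection
  (`blendspec.synthetic`).

## Worked example

```sh
python examples/01_simulate_and_fuse.py
```

```
Vis-NIR block : (90, 400) over 460-1020 nm
NIR block     : (90, 220) over 975-1713 nm
Fused block   : (90, 620) (400 Vis-NIR + 220 NIR variables)
Design        : 90 samples, row sums 1.000000000000-1.000000000000
split(Fused, NIR) identical to NIR block: True
```

Ninety simulated scans (30 blend recipes, three replicate scans each, all
proportions summing to exactly 1) yield the two instrument matrices, fused
into the 620-variable predictor block.  Screening that session's Vis-NIR
block after injecting five gross-offset spectra
(`examples/03_outlier_screen.py`):

```
n = 90, h-subset size = 67, cutoff = 2.716 (97.5% chi-square, 2 df)
flagged 6 samples; injected outliers caught: 5/5
kept block: 84 samples feed the downstream models
```

All five corrupted scans sit far outside the tolerance ellipse (robust
distances ≈ 23–26 against a cutoff of 2.72) and are removed; one borderline
clean scan is also flagged, consistent with the 2.5% nominal false-flag
level of the ellipse.  `examples/05_full_study.py` then runs the complete
three-stage study and prints the per-component winners, e.g.

```
tobacco_silk           Fused   identity  CARS     95  11  0.9920  0.0072 11.252
```

— for the dominant component the fused 620-variable spectrum, reduced to 95
CARS-selected variables and modelled with 11 latent variables, reaches
LOOCV R² = 0.992 with RMSECV = 0.0072 (fractional proportion units) and
RPD ≈ 11; RPD > 2 conventionally marks a usable calibration.

The remaining examples cover cube calibration (`02`) and a side-by-side of
the selection methods (`04`).

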