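# Methods

This note records the modelling choices, default parameters, and known
limitations of `msfa_design`, in enough detail to judge what results
from the package do and do not mean.

## 1. Synthetic reflectance model

Each spectrum is a linear mixture on a shared wavelength grid
(default 470–720 nm, 1 nm spacing, 251 samples):

    R(λ) = cHb·εHb(λ) + cHbO2·εHbO2(λ) + cH2O·εH2O(λ)
           + cs·S(λ) + b + n(λ),   S(λ) = (λ/500)^(−1.3)

- Concentrations are drawn uniformly per class from configured
  `(lo, hi)` ranges; the draws are recorded as per-spectrum ground
  truth, which makes exact forward–inverse tests possible.
- `b` is a flat offset (baseline signal); `n` is i.i.d. Gaussian noise
  per wavelength (default sd 0 — the default datasets are noiseless and
  class overlap comes from the concentration ranges alone).
- Negative values after noise are clipped to zero.

**Chromophore curves.** The bundled extinction/absorption tables
(`src/msfa_design/data/*.csv`) are *synthetic*: hand-tabulated anchor
points reproducing the canonical qualitative features of Hb, HbO2 and
water (Soret region, 545/577 nm HbO2 double peak vs. single 556 nm Hb
peak, isosbestic crossings near 527/545/570/584 nm, water absorption
rising beyond 700 nm), interpolated with a monotone piecewise cubic
(PCHIP) and scaled to unit maximum. They preserve the *structure* that
drives band selection but not absolute molar values; any concentration
output is in arbitrary units. Do not use these curves for quantitative
oximetry. (PCHIP avoids the overshoot/negative lobes a natural cubic
spline produces between sharp anchors.)

**Cohorts.** Two preset generators mirror typical study dimensions:
esophageal — 715 spectra (236 neoplasia / 320 Barrett's / 159
squamous) over 15 patients; colon — 14,065 spectra over 7 patients,
including a flat "specular" class modelled as offset-only. Spectra are
assigned round-robin to patients. A `scale` factor shrinks counts
proportionally (floor, minimum 1 per class) for fast experiments.
Train/test splits are stratified with `floor(count/5)` test samples per
class.

## 2. Filters, mosaics, demosaicking

- A band is `(center, FWHM)` with a Gaussian transmission
  `σ = FWHM / (2√(2 ln 2))`; a boxcar profile is available. A
  measurement is the transmission-weighted mean `Σ R·T / Σ T`, so a
  constant spectrum measures exactly its constant value regardless of
  band shape.
- The design grid defaults to centers 450–700 nm (step 1) and FWHM
  10–30 nm (step 2); the SAM preset restricts centers to ≥ 470 nm so
  every band is fully supported by the spectral grid.
- A mosaic tile is the smallest square `s×s` with `s² ≥ n` bands; valid
  layouts are the surjective assignments (every band appears). On a
  2×2 tile there are 36, 24 and 14 layouts for 3, 4 and 2 bands
  (inclusion–exclusion; unit-tested against brute force). Enumeration
  is exhaustive up to a cap (default 10,000), then a seeded uniform
  subsample.
- Demosaicking is per-band bilinear interpolation on the band's knot
  lattice. When a band's pixels form a complete row×column product
  lattice the separable `np.interp` path is used with constant
  extension outside the knot hull; otherwise `scipy.interpolate.griddata`
  (linear) with nearest-neighbour fill. Knot pixels are reproduced
  exactly; planar images are reconstructed exactly in the interior.
  Because the border is extrapolated by constant extension, a fixed
  5-pixel margin is cropped before any evaluation (80→70, 96→86,
  196→186 for the three phantoms).

## 3. Phantoms

- Esophageal (80×80): concentric discs — neoplasia core, Barrett's
  annulus, squamous background — with radii solved so class pixel
  fractions match the cohort proportions (236/320/159 of 715).
- Colon (96×96 classification, 196×196 unmixing): background tissue,
  two lesion discs scaled with the image, plus two radius-3 specular
  discs drawn last (they overwrite).
- Population is block-coherent: per `block × block` tile (2 for
  classification, 8 for unmixing) and per class present in it, one
  pool spectrum is drawn with replacement and assigned to all matching
  pixels. This creates the piecewise-constant texture a real scene's
  spatial correlation induces, which is what makes demosaicking errors
  task-relevant.

## 4. Merits and statistics

- **Classification**: kNN (k = 5, majority vote; ties broken by smaller
  mean neighbour distance, then class order), SVM (RBF, C = 1000,
  `gamma='scale'`), SAM (minimum spectral angle to class-mean
  references; angle ties go to the first class). Spectral merit is the
  mean held-out accuracy over seeded stratified 5-fold CV. Spatial
  merit repeats the fold structure: the phantom is populated from the
  fold's training pool, mosaicked, demosaicked, cropped, and classified
  per pixel against the fold's training data.
- **Unmixing**: least-squares fit of (Hb, HbO2, H2O, scattering,
  offset) per pixel. With ≥ 5 measurements a conditioning check names
  the most collinear basis pair on failure. With *fewer* than 5
  measurements (3–4 band designs) the system is underdetermined; the
  minimum-norm least-squares solution is reported deliberately, since
  scoring low-band-count designs is the point of the tool — the
  resulting bias is exactly what the NRMSE merit measures.
- **NRMSE** between reduced-band and full-spectrum haemoglobin maps:
  `sqrt(mean[(ΔcHb)² + (ΔcHbO2)²]) / sqrt(mean(cHb)·mean(cHbO2))`
  with the per-pixel means of the reference inside the radical
  (default); a `global` convention normalising by the global product of
  means is available as a config switch. NRMSE(x, x) = 0 and the
  measure is invariant to joint rescaling of both maps.
- **Per-patient CI**: accuracies averaged within patient, then a
  Student-t 95% interval over patient means.

## 5. Optimization

Two-stage discrete search per band count *n*:

1. **Screen**: `n_screen` (default 10,000) random filter sets with
   distinct centers; scored on one fold (configurable) for speed; the
   top `n_keep` (default 5) are re-scored on all folds.
2. **Descent**: best-improvement hill climbing; neighbours move one
   grid step in a single band's center (±1 nm) or FWHM (±2 nm).
   Monotone by construction, capped at `max_iterations` (default 500).
   Agreement among the refined candidates is reported as a convergence
   diagnostic.
3. **Layout**: exhaustive (capped) enumeration of surjective layouts,
   ranked by the fold-mean spatial merit.

All randomness flows from a single integer seed; fold re-seeding uses
`(seed·1000 + fold) mod 2³¹`. Re-running a saved manifest reproduces
`results.csv` byte-for-byte.

## 6. Problem sizes and runtime

Defaults used in tests and examples: 715-spectrum esophageal pool
(generation ≈ 0.06 s); one kNN spectral merit ≈ 0.05 s; one esophageal
spatial fold (80×80, 3 bands) ≈ 0.17 s, so a full 36-layout × 5-fold
layout search ≈ 30 s; a 196×196 unmixing spatial fold ≈ 1.8 s. Screens
of 10,000 candidates are practical for spectral merits only; the demo
configs in the test suite use 6–600.

## 7. Limitations

- Chromophore curves are qualitative stand-ins (§1); concentrations,
  sO2 and NRMSE values are internally consistent but not physiological.
- The forward model is linear in reflectance; it ignores the nonlinear
  coupling of absorption and scattering in real diffuse reflectance, so
  optimal bands here reflect the linear-mixture geometry only.
- Phantoms are piecewise-constant; demosaicking penalties on scenes
  with gradients or texture within a class are not modelled.
- Gaussian filter profiles idealise real interference-filter
  transmission (no side lobes, no angular shift).
- The hill climb is local; with small screens it can return a local
  optimum, flagged by the candidate-agreement diagnostic rather than
  prevented.
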