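# Methods

This note documents the models, conventions and numerical choices behind
`aquanir`, and what the synthetic-data generator does and does not
emulate.

## Data model and pretreatment

Spectra are absorbance (log 1/T) on a strictly increasing, regularly
spaced wavelength grid in nm (spacing tolerance 1e-9 nm).  The processing
order is fixed: **smoothing → wavelength-range selection → mean centering
→ OSC → latent model**.  Smoothing and range selection are sample-wise,
y-free operations and are applied once to the data set; centering and OSC
use the training set (OSC uses y itself), so they are part of the
calibration and are refit inside every cross-validation fold.  Smoothing
is a windowed mean (boxcar) by default, with a quadratic Savitzky–Golay
variant, both with symmetric-reflection edge padding so the grid never
shifts; the 21- and 45-point windows used for liquid NIR work are typical
inputs.  Wavelength intervals are closed (`1300–1600 nm` keeps both
endpoints), matching how the water-band table is written.

## Orthogonal signal correction

OSC removes spectral variation orthogonal to the reference values before
regression.  The fitted variant (recorded in the model as `wold-ls`) is
the Wold-style iteration: start from the leading principal-component
score, orthogonalize it against centered y, regress a weight vector w
mapping the centered spectra onto the orthogonalized score, renormalize,
and iterate until the score direction changes by less than 1e-10 (at most
500 iterations); then deflate X by the converged score t = Xw and its
loading p = Xᵀt/tᵀt.  The weight regression is min-norm least squares —
the full-component limit of the inner-PLS variants.  Numerically the
iteration runs through a truncated-SVD projector (singular values below
1e-12 of the largest are dropped) rather than a fresh pseudo-inverse per
pass; both have the same fixed point, but the projector avoids amplifying
roundoff along near-null directions, which otherwise stalls convergence
around 1e-5.  For wide spectral matrices the centered y lies in the
column space, so training scores are orthogonal to y to machine
precision.  Degenerate input whose every column is proportional to y has
nothing orthogonal to remove; the component is then stored inert (zero
vectors) so that applying the model removes nothing — this keeps
fit/apply consistency exact in the limit case.

When comparing calibrations with and without OSC, the comparison is made
**at equal factor count**.  OSC is part of the calibration: it absorbs
structured y-orthogonal variation that the regression would otherwise
spend latent variables on.  With a generous factor budget a no-OSC PLSR
simply models a strong rank-one confounder with extra factors, so the
informative comparison — and the one reported by the acceptance script —
is SECV at the same k (k = 2, the factor count of the dose calibrations).

## Latent-variable models

* **PCA** — deterministic SVD; loadings orthonormal, ordered by explained
  variance, sign fixed so each loading's largest-magnitude element is
  positive.
* **PLSR** — NIPALS PLS1: w ∝ Xᵀy (unit norm), t = Xw, p = Xᵀt/tᵀt,
  q = yᵀt/tᵀt, deflating both X and y (y-deflation does not change PLS1
  predictions but fixes the scores, making score-level tests exact);
  regression vector b = W(PᵀW)⁻¹q.  Factors are nested, so one fit at
  k_max yields the coefficient vectors for all smaller k.
* **PCR** — least squares of centered y on the first k PCA scores.
* **PLS-DA** — PLS1 on a {0, 1} dummy coding of exactly two classes
  (sorted label order); classification threshold 0.5, with an exact 0.5
  left unassigned.
* **SIMCA** — one PCA submodel per class on the class's own mean.
  Residual standard deviations pool the residual sums of squares with
  df = (nᵢ−kᵢ−1)(m−kᵢ) for a class projected on itself and nᵢ(m−kⱼ) for
  cross projections.  A sample is accepted by class j when its residual
  variance ratio against s(j→j)² is below the F quantile (default 0.95)
  with (m−k, (nⱼ−kⱼ−1)(m−kⱼ)) degrees of freedom; no score-range
  (leverage) limit is applied — residual distance is the common core of
  all SIMCA variants, and the choice is recorded in the model metadata.
  The interclass distance d(i,j) = √((s(i→j)²+s(j→i)²)/(s(i→i)²+s(j→j)²))
  is the plain square-root ratio whose null value is 1 (not the "−1"
  variant); discriminating power applies the same formula per wavelength.
  Under the stated df conventions two *identical* classes give a distance
  of √(n/(n−k−1)) rather than exactly 1, which is why the null checks use
  Monte-Carlo tolerances (±0.2 on distance, ±0.15 on DP at n = 200)
  rather than exact equality.  "Correctly classified" is strict: a sample
  accepted by several classes, or by none, counts as incorrect.

## Validation and metrics

The factor cap is ⌊n/10⌋ (minimum 1), the usual guard against overfitting
small NIR calibration sets.  Leave-one-out CV refits centering, OSC and
the model on every fold; leave-one-group-out does the same per batch or
class and reduces exactly to LOO when every sample is its own group.
SEC = √(RSS_cal/(n−k−1)) — the intercept absorbed by centering costs one
degree of freedom — and SECV = √(RSS_cv/n); neither convention is
universal, so both are recorded in the result metadata.  The optimum
factor count is the argmin of per-factor SECV, ties to the smaller k.
"Active class validation", a validation mode found in commercial
chemometrics software, is not publicly documented;
`group_holdout_validate` with class labels or batches as groups is the
package's clearly-labelled stand-in.

## Water bands and peak annotation

The band table is the fifteen first-overtone bands C1–C12 and W1–W3 with
their nm ranges and assignments (C5 = S0 free water 1398–1418 nm,
C11 = S4 1482–1495 nm, etc.).  Bands overlap (C1/W1; C10 and C11 share
1482 nm), so annotation maps a peak to *every* band whose closed range
contains it — no tie-breaking, matching how band attributions are
discussed in the field.  Peaks are signed local extrema whose prominence
reaches a configurable fraction (default 0.1) of the vector's maximum
absolute value.

## Synthetic-data generator

The generator emulates the statistical structure of NIR measurements of
dilute aqueous DNA, not water physics.  Per sample:

```
spectrum = water_baseline
         + Σ_bands dna_effect_b · dna_conc · G_b
         + Σ_bands tt_effect_b  · tt_conc  · G_b
         + offset + slope·(λ − λ_mid) + amplitude·confounder_shape + noise
```

with G_b a unit Gaussian at the band midpoint (sd = half-width/2).  The
baseline is one broad Gaussian (1450 nm, 1.0 AU, sd 60 nm) plus twelve
0.05 AU sub-bands of sd 4 nm at the C-band midpoints — narrow enough that
all twelve resolve as local maxima (midpoints are 10–24 nm apart, and
equal Gaussians merge below a 2·sd separation).  Defaults, chosen once to
sit in the qualitative windows the analysis is meant to reproduce and
documented as configuration rather than physical claims:

| parameter | default | units / meaning |
|---|---|---|
| design | {5,10,15,20} µM × {0,5,10,15,20} kJ/m² | the study layout |
| dimer_yield | 0.0075 | µM dimer per (kJ/m² · µM DNA); 3 µM at 20 µM / 20 kJ/m² |
| dimer_noise_sd | 0.25 | µM, truncated at zero; puts the dose-response R² near 0.87 (10 µM) and 0.96 (20 µM) at n = 10 |
| dna band effects | +2e-4 (C5), −2e-4 (C11) | AU/µM: DNA frees water, depletes S4 |
| tt band effects | −4e-3 (C5), +4e-3 (C11) | AU/µM: dimers rebuild strongly H-bonded water |
| noise_sd | 1e-4 | AU white noise per wavelength |
| baseline offset / slope sd | 5e-4 / 2e-6 | AU, AU/nm drift |
| confounder_amplitude_sd | 5e-4 | AU; shape = fixed broad differential curve, amplitude i.i.d. per sample |
| batches | 8 | cycled sample → batch assignment |

Randomness comes from one `numpy.random.default_rng(seed)` stream in a
fixed order (per-sample dimer noise; then per-sample drift offset, drift
slope, confounder amplitude, noise vector), so a config is bit-reproducible
and seeds are portable given the same generator algorithm (PCG64, recorded
here).

What passing tests on this generator show: that the pipeline recovers
band-localised, linearly acting solute signals from a dominated baseline
under drift, noise and structured confounding, with correct CV
bookkeeping.  What they do not show: performance on real instrument data,
whose band shifts are temperature-dependent, whose confounders are not
rank-one, and whose noise is not white — none of which the generator
models.  The dose-response check asserts the *mean* linear-fit R² over 20
seeded replicates of the n = 10 design, because a single n = 10 draw of
R² has sampling spread comparable to the target interval's width itself.

## Problem sizes

All tests and the acceptance script run on simulated sets of 20–40
samples × 601–1501 wavelengths (0.5 nm grid), the scale of the original
experiments; the full suite takes a few seconds on one CPU.

## Known limitations

* PLS-DA is two-class only; SIMCA handles any number of classes but
  discriminating power is reported per class pair.
* The SIMCA acceptance threshold and distance formula of proprietary
  chemometrics packages are not public; the variants implemented are
  flagged in model metadata rather than asserted to match any vendor.
* OSC with several components removes them sequentially; no joint
  optimisation across components is attempted.
* No MSC/SNV/derivative pretreatments and no venetian-blind CV — they are
  outside this pipeline's scope.
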