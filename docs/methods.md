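# Methods

This note records the models, algorithms, defaults and design choices
behind `kmnir`, and what the synthetic benchmark does and does not show.

## Kubelka–Munk model

The package treats a powder bed as an optically thick, homogeneous,
isotropically scattering layer, for which the diffuse reflectance R∞
satisfies the Kubelka–Munk relation f(R∞) = (1 − R∞)²/(2 R∞) = k/s, with
*k* the absorption and *s* the scatter coefficient (a shared, arbitrary
inverse-length unit; only the ratio is optically meaningful). Apparent
absorbance uses the base-10 convention A = −log₁₀ R∞, i.e. reflectance
measured against a non-absorbing (air) reference; natural-log variants are
deliberately not offered. Assumptions worth stating: infinite optical
thickness, no specular component, no lateral losses, wavelength-independent
scattering anisotropy. Multi-layer, finite-thickness and Mie-theoretic
models are out of scope.

The inverse map uses the quadratic root in (0, 1] written as
R∞ = 1/(1 + x + √(x² + 2x)), which is algebraically identical to
1 + x − √(x² + 2x) but immune to catastrophic cancellation at large x, so
forward/inverse round trips hold to ~1e−12 relative across the whole
usable range (k/s up to 1e8 was exercised).

**Linear region.** A(x) has curvature ∝ 1/x² for large x (first-order
expansion: A ≈ log₁₀(2x + 2)), so straight-line fits on sliding k/s
windows improve monotonically with the window start. The linearity profile
reports the fit R² and maximum absolute residual per window; the "linear
region onset" is the smallest window start reaching a configurable R²
threshold. Defaults: range [0, 20], window width 4, grid step 0.01,
threshold 0.995 — with these the onset lands at k/s ≈ 4.6, i.e. linearity
is declared just beyond k/s = 4. The threshold is a *definition*, not a
physical constant: lowering it moves the onset down (monotonically, which
is asserted in tests).

## Preprocessing operators

All operators act row-wise on absorbance matrices and preserve shape and
wavelength grid. Methods with a fitted state (MSC, EMSC) take their
reference — the mean calibration spectrum — from calibration rows only and
apply it frozen to validation rows; this is the leakage boundary the
pipeline enforces and mutation-tests.

- MSC regresses each spectrum on the reference (x ≈ a + b·ref, OLS) and
  returns (x − a)/b.
- EMSC adds a wavelength polynomial on the axis scaled to [−1, 1]
  (default order 2; order 0 reduces exactly to MSC and is allowed for that
  reason). The model contains no analyte-spectrum term. Note the known
  caveat: when the reference itself contains the analyte signature, the
  reference loading b absorbs part of the concentration signal; division
  by b then attenuates it. This is inherent to EMSC, mild when the matrix
  dominates the reference (the realistic case), and visible in the
  synthetic study if the matrix background is made artificially smooth.
- SNV standardises each row to mean 0, sample SD 1 (n−1), and is
  idempotent and affine-invariant by construction.
- Savitzky–Golay uses a nine-point window by default ("SG9"); smoothing
  and first derivative use polynomial order 2, second derivative order 3
  (a cubic is the minimum sensible local model for curvature). Derivative
  pipelines ("1D+SG", "2D+SG") are a single SG convolution with the
  corresponding derivative order — mathematically the smoothed derivative,
  with fewer edge artefacts than smooth-then-difference. Edges are handled
  by evaluating the first/last window's fitted polynomial
  (scipy's `mode="interp"`), keeping output aligned with the grid.
  Derivatives are scaled by the wavelength spacing (per nm).
- Normalisation defaults to the unit (L2) vector; `max` and `area` modes
  exist. Baseline subtraction defaults to per-row linear detrending in λ;
  `offset` subtracts the row minimum. Both are per-row and parameter-free.

## Chemometrics

**Kennard–Stone split.** Fully deterministic maximin selection in raw
absorbance space: seed with the maximal-distance pair, then repeatedly add
the sample maximising the minimum distance to the selected set; all ties
break to the smallest index. The split is computed once per fraction set
on RAW spectra and reused for every preprocessing method, so method
comparisons share calibration/validation membership and the comparison is
not confounded by split variance. Default ratio 2:1
(e.g. 210 → 140/70; 30 → 20/10 per fraction).

**PLS.** Mean-centred (never variance-scaled — standard for absorbance
spectra) NIPALS PLS1. With a single response the weight vector has a
closed form per component, so each component is one pass; the regression
vector B = W(PᵀW)⁻¹q reproduces the sequential deflation model exactly and
is verified against pseudoinverse least squares at full rank and against
scikit-learn's PLS implementation as independent cross-checks. If the
residual covariance is exhausted before the requested component count
(exactly fitted response, e.g. noise-free data), extraction stops; callers
opt into the truncated model with `allow_fewer` (the pipeline does),
otherwise the error names the component.

**Latent-variable choice.** Leave-one-out PRESS: each sample is held out,
the model refit on the remainder, and the held-out prediction recorded for
every LV count up to `max_latent` (default 10, capped at n−2); the
selected count is the PRESS argmin with ties broken toward fewer latent
variables. RMSECV = √(PRESS(selected)/n). Preprocessing is fitted once on
the full calibration set before CV rather than inside each fold; for
MSC/EMSC this leaks the held-out row into the reference mean — a
deliberate, documented simplification (the reference is an average over
~20+ spectra, so the effect is O(1/n)) matching common practice.

**Metrics.** RMSEC/RMSEP are plain RMS errors on calibration/validation;
R² is 1 − SS_res/SS_tot against the respective set's own mean (not squared
Pearson correlation; values can be negative for pathological predictions
and are stored as computed). RPD = SD(y_val, n−1)/RMSEP; a perfect
validation fit reports RPD = inf rather than being dropped. "Best" method
per fraction set = maximal RPD, ties to fewer latent variables, then
method order.

## Synthetic sieved-powder generator

The generator emulates a sieving study: `n_base_samples` powders (default
30, batched 3-per-batch into 10 batches), each with one true analyte
content shared across all 7 sieve fractions (355–850, 250–355, 180–250,
150–180, 125–150, 90–125, <90 μm; representative diameter = arithmetic
mean of the bounds, 45 μm for <90), measured in triplicate on a 780–2500 nm
grid. Spectra are built as:

1. k(λ) = c · ε(λ) + k_bg(λ): analyte absorptivity ε is a sum of Gaussians
   (defaults at 1200, 1700, 2270 nm — second-overtone, first
   combination-overtone and combination regions of C–H stretches); the
   matrix background is a smooth curve rising toward long wavelengths plus
   broad O–H bands at 1450 and 1940 nm, the water/cellulose signature that
   dominates real plant-powder NIR and keeps the MSC/EMSC reference
   matrix-driven rather than analyte-driven.
2. s(λ) = s₀ · d_ref/d per fraction (s₀ = 1.5 at d_ref = 100 μm),
   constant across wavelength and across samples within a fraction.
3. R∞ = f⁻¹(k/s); per replicate the measured reflectance is
   R∞·(1+ε_mult) + ε_add clipped to (1e−6, 1], where ε_mult is one scalar
   per replicate spectrum (repacking/packing-density variation — exactly
   the per-spectrum multiplicative effect MSC-type corrections target) and
   ε_add is per-channel detector noise; replicate absorbances are
   averaged. Scan averaging (the instrument's 64 co-added scans) is folded
   into the additive SD rather than simulated per scan.
4. The reference value is c·(1+η), η ~ N(0, hplc_cv), an unbiased stand-in
   for the HPLC assay error.

Defaults: concentration ~ truncated Normal(1.5, 0.5²) mg·g⁻¹ with floor
0.2 (magnitude chosen so that RMSEPs of order 0.1 mg·g⁻¹ correspond to
RPDs of order 3–5); additive noise SD 5e−4, multiplicative 2e−3 on the
reflectance scale; hplc_cv 1.5 %; grid step 2 nm (861 points — the
instrument's 0.5 nm is available by config but quadruples every matrix
for no methodological gain at desk scale). A `pure_scatter_dataset`
variant holds chemistry constant so that any between-fraction spectral
variance is particle-size scatter by construction.

What the generator reproduces: the baseline offset growing with particle
size (coarser powder → smaller s → larger k/s → higher apparent
absorbance, uniformly in wavelength), concentration-dependent peak
absorption, replicate averaging and assay noise. What it omits: real
absorptivities of harpagoside, instrument line shape, detector
nonlinearity, moisture/temperature drift, scattering anisotropy, and any
within-fraction diameter distribution (one representative diameter per
fraction). Passing tests therefore demonstrate the *machinery* —
physics inversion, leakage-free model selection, the direction of
particle-size and preprocessing effects — not quantitative agreement with
any particular instrument or plant material. With the default (small)
noise the synthetic RPDs run well above the 2–5 band typical of real
herbal-powder assays; the structure, not the absolute RPD level, is the
point of the benchmark.

## Study pipeline

Single-fraction study: per fraction (skipped with a warning below 6
samples), Kennard–Stone split, then per method: fit preprocessing on
calibration rows → LOOCV PRESS → LV selection → fit → evaluate. Mixed
study: pool each 3-fraction union (defaults 180–850, 150–355, 125–250,
90–180, 0–150 μm, unions of adjacent sieve fractions by label — no
re-sieving is simulated) and repeat. Cross-prediction: apply each fitted
90–180 μm mixed model to its member fractions' samples *from the mixed
split's own validation partition* — a guard refuses any sample from the
model's calibration partition, so the literal reading "predict the single
fraction's validation set" can never leak mixed-calibration samples. The
single-vs-mixed comparison table pairs each target fraction's best single
model (own validation metrics) with the best mixed-model cross-prediction
(best = maximal mean RPD across the set's targets).

A particle-size response (predicting the representative diameter instead
of content) needs no separate code path: pass the diameters as the
reference column.

Everything downstream of the data is deterministic; report files are
written with an exact float format (`%.17g`), so a fixed config and seed
give byte-identical outputs, and write→read round trips are exact to the
double. All randomness flows from the single config seed through one
`numpy` Generator.

## Known limitations

- s is only *estimable* when k is known (synthetic truth); for real
  powders k is unknown and no estimation procedure is provided — the
  generator-based closed loop is a physics self-check, not an assay.
- LOOCV preprocesses once per method before the loop (see above).
- The EMSC analyte-in-reference attenuation noted above.
- The mixed-set "best method" and cross-prediction winners on synthetic
  data depend on the seed at the margins; only the directional claims
  (scatter correction helps pooled models; cross-prediction is competitive
  with single-fraction models) are asserted, at the default seed.
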