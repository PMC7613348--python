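# Methods

## Emulation model

The emulator approximates an expensive spectrum-to-spectrum computation —
spectral-fitting SIF retrieval — by a statistical surrogate trained on
paired examples. Radiance spectra (B_in = 1024 bands, 669.5–781.9 nm) and
reference SIF spectra (B_out = 27 bands, 751–777 nm at 1 nm) are each
compressed by principal component analysis; a kernel ridge regression (KRR)
learns the map between score spaces; predicted output scores are inverted
through the output PCA to reconstruct SIF spectra.

Assumptions worth stating plainly:

* the radiance→SIF relation is smooth enough in the retained score space
  for a Gaussian-kernel regressor to interpolate it;
* the reference SIF used for training is itself a noisy product; the
  emulator learns its conditional mean, so held-out error cannot fall below
  the reference noise floor;
* an emulator is only valid for radiance statistically similar to its
  training distribution — land-cover types or illumination conditions
  absent from training extrapolate poorly (the motivation for stratified
  sampling and multi-scene pooling).

### PCA conventions

Spectra are mean-centered, not variance-scaled; covariance uses 1/(n−1).
Eigenvectors are computed from the economy SVD of the centered data,
ordered by descending eigenvalue, with the sign fixed so each component's
largest-magnitude entry is positive (first such entry on ties). PCAs are
fit on the training split only, never on validation pixels.

### KRR conventions

Input scores are standardized per feature; output scores are regressed
unstandardized so the inverse-PCA path stays exact. The kernel is the
Gaussian RBF `exp(−‖a−b‖²/2σ²)`; the regularizer enters as `λI` (not
`nλI`). Both λ and σ are tuned by grid search — λ over 10 log-spaced values
in [1e−8, 10], σ over median-heuristic multiples {0.25, 0.5, 1, 2, 4} —
with 5-fold cross-validation, deterministic fold assignment, and ties
resolved to the smaller λ then smaller σ, independent of grid order. For
each (fold, σ) the training kernel is eigendecomposed once and all λ reuse
the factorization. One Cholesky solve on the full data serves every output
component (multi-output pathway); a per-output loop exists for plugin
regressors that cannot train multi-output.

### Numerical and determinism choices

* Prediction processes pixels in fixed 256-row blocks, padding the last
  partial block, so every BLAS call sees identical shapes; cube emulation
  is therefore bit-identical for any `chunk_rows`, and batch prediction
  equals row-by-row prediction exactly.
* All randomness flows through `numpy` Generators seeded from explicit
  integers; one scene/plan/emulator seed fully determines the run. CLI
  reruns reproduce reports bit-for-bit.
* Zero-variance training spectra are rejected with an error naming the
  offending side; a kernel system singular beyond its regularization
  surfaces the offending (λ, σ).
* Percentiles use linear interpolation between order statistics; the
  760 nm reporting band is the output band nearest 760.0 nm, ties to the
  lower wavelength.
* NRMSE uses one global denominator — max minus min over *all* entries of
  the reference matrix — for the overall value and for every per-band
  value. Signed error maps are emulated − reference.

## Synthetic scenes

The generator emulates the *structure* of an airborne FLUO acquisition,
not its radiometry:

```
radiance(λ) = g · E(λ) · T(λ) · ρ(λ)/π + a · s(λ) + ε
```

with `E(λ) = 520·exp(−((λ−560)/290)²)·(1 + 0.04·cos(2π(λ−669.5)/35))` a
smooth solar-like curve of arbitrary absolute scale, `T(λ)` a Gaussian O₂A
dip at 760.5 nm (width 0.65 nm, depth 0.85 by default), and
`s(λ)` a Gaussian fluorescence shape centred at 740 nm (sd 18 nm)
normalized to 1 at 760 nm, so the amplitude `a` *is* SIF at 760 nm. The
same normalized shape enters the radiance and defines the truth on the
output grid. Scenes are Voronoi mosaics of `n_classes` contiguous patches;
5 of 8 classes fluoresce by default (vegetation fraction 0.61), with
red-edge reflectance spectra and amplitudes drawn uniformly from 0–6
mW m⁻² sr⁻¹ nm⁻¹ — the range spanned by the reference product the method
targets. Within a class, pixels get an amplitude jitter (sd 0.5) and a
multiplicative brightness jitter (sd 0.05); both enter the radiance, so
they are learnable signal, not noise. Sensor noise (sd 0.5) is added per
radiance band; the "reference" SIF adds i.i.d. Gaussian noise (sd 0.3) to
the truth, which lets reference values go slightly negative as real
retrieval output does. Illumination drift between scenes is a single
scalar `g` per scene.

What the generator deliberately omits: real atmospheric radiative
transfer, BRDF/directional effects, sensor PSF and spectral response,
spatially correlated noise, and reflectance features beyond a logistic red
edge. Passing tests on these scenes demonstrate that the pipeline is
implemented correctly and behaves as the method predicts under its own
assumptions; they do not certify accuracy on real imagery.

## Sensitivity study (scaled)

The study in `sifemu.sensitivity` runs at desk scale: 300 × 300-pixel
scenes, 8 land-cover classes. The optimal emulator (20/5 PCs, 3000
samples, absolute sampling over a 40-class k-means segmentation) is
trained on one scene and transferred to a second scene with a different
vegetated share (0.5 vs 0.61) and +4% illumination. Two design choices
keep the scaled-down sweeps interpretable rather than split-noise
dominated:

* sample-size points train on *nested* subsets of one random pixel pool
  and are all scored against one common held-out set of 3000 pixels;
* (λ, σ) are tuned once at the optimal configuration and then held fixed
  across sweep points, so each sweep isolates its own variable.

Sweep sizes are 200–7000 samples (200, 500, 1000, 1500, 2000, 3000, 5000,
7000) and 1–10 output PCs at 1000 samples. Because the synthetic SIF
output is spectrally smooth, held-out NRMSE is expected (and observed) to
be nearly flat in the output-PC count, and the learning curve flattens
once the class/amplitude space is covered — the reference-noise floor
(≈0.3 over a ≈11-unit range, i.e. ≈2.7%) bounds it from below.

## Segmentation and sampling conventions

k-means runs on the top-10 input-PCA scores (PCA fit on ≤10,000 randomly
subsampled pixels) with k-means++ initialization, 5 restarts, 300 max
iterations; the clustered feature space is a package choice, as is quota
rounding (floor+remainder for absolute, largest-remainder for relative)
and proportional iterative redistribution when a class is smaller than its
quota. Sampling is always without replacement within a scene; the 70/30
train/validation split is applied after drawing.

## Known limitations

* The ENVI dialect is deliberately narrow: float32/float64 read, float32
  BSQ little-endian write, no geo-keys.
* The emulator carries no uncertainty estimate; a Gaussian-process plugin
  could provide one through the regressor registry.
* The synthetic illumination model (one scalar per scene) cannot produce
  within-scene gradients; multi-scene pooled training is exercised, but
  across-track effects are out of reach of the generator.
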