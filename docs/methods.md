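# Methods

`sanqitrace` implements two linked analyses of *Panax notoginseng* quality
and provenance: (i) chemometric modelling of how bioclimatic conditions
relate to the four quality-marker saponins, and (ii) geographic-origin
traceability by classifying synchronous two-dimensional correlation
(2D-COS) images of near-infrared (NIR) spectra with a 32-layer residual
CNN. This note records the models, the defaults and why they were chosen,
and what the synthetic data can and cannot demonstrate.

## Spectra model and conventions

All spectra live on one strictly descending wavenumber grid, by default
10000–4000 cm⁻¹ at 4 cm⁻¹ steps, the scanning range and resolution of a
diffuse-reflectance FT-NIR instrument. Each sample is scanned in
duplicate and the replicate-average spectrum is carried forward. Grids
are never interpolated: spectra from different grids are an error, since
a single-instrument study has a single grid. Band windowing (default
7000–4000 cm⁻¹, the NIR fingerprint region where the correlation images
carry their feature peaks) uses a closed interval on both ends.

The synthetic generator writes each class-mean spectrum as a sum of
Gaussian bands at the characteristic wavenumbers of root-powder NIR
spectra — 8320 (C–H second overtone), 6800 and 6356 (O–H/N–H first
overtones), 5168 (O–H stretch + C–O deformation combination), 4756
(O–H deformation + C–O stretch), and 4300 cm⁻¹ (C–H/C–C combination) —
with fixed FWHM 120 cm⁻¹ (a typical NIR overtone bandwidth; only centers
are physically anchored). Band amplitudes rise toward low wavenumber,
mimicking the strong combination-band envelope of carbohydrate-rich
material. Classes differ by ±8–10 % amplitude shifts on two designated
bands per class: raw spectra of different origins differ only subtly, so
the classes are deliberately faint in the 1-D spectra but systematic.
Replicate artefacts are a per-replicate multiplicative gain 1 + N(0,
0.02) (diffuse-reflectance scatter), a linear baseline, and i.i.d.
Gaussian noise with sd 0.004 absorbance units (roughly 0.5 % of the
strongest band). The study's own within-class variances are unpublished;
these values are fixed once as field-plausible and are tunable config
fields, not calibrated constants.

What the generator does **not** emulate: instrument line-shape and
detector nonlinearity, water-band drift, particle-size-dependent scatter
curvature (only a scalar gain), or between-plot ecological covariance.
Passing tests therefore demonstrate correctness of the pipeline and
learnability of subtle class structure, not field-data performance.

## Synchronous 2D correlation maps

For a perturbation series of m spectra the dynamic spectra subtract the
series-mean reference, and the synchronous intensity is
Φ(v₁,v₂) = (m−1)⁻¹ Σₜ S(v₁,t)·S(v₂,t) — the covariance of intensity
variation at the two wavenumbers. Φ is symmetric, its diagonal
(autopeaks) non-negative, and it satisfies the Cauchy–Schwarz bound
Φ(v₁,v₂)² ≤ Φ(v₁,v₁)Φ(v₂,v₂); the tests assert all three plus
equivalence with a brute-force double-loop evaluation.

**Per-sample maps.** A classifier needs one image per sample, but a
single sample is not a perturbation series, and the acquisition protocol
does not state how the published per-sample images were formed. Two
constructions are provided and the choice is a config key:

* `self-outer` (default): center the replicate-averaged spectrum about
  its mean intensity *over wavenumbers* and take the outer product with
  itself. This is a rank-1 symmetric map whose autopeak pattern sits on
  the absorption bands, preserves chemical band structure, and is
  deterministic per sample.
* `replicates`: treat the duplicate scans as the series (m = 2). This
  uses only genuine replicate variation but is noise-dominated when
  replicates differ mainly by scatter.

**Rendering.** Maps are min–max normalized to [0,1] (a constant map maps
to 0), passed through a 256-entry rainbow lookup table shipped as an
explicit CSV (`data/jet256.csv`, the classic piecewise-linear formula;
shipping the table keeps renders bit-exact with no plotting-library
dependence, nearest-index lookup), bilinearly resampled to 128×128 with
the align-corners convention (output corners sample input corners
exactly), and quantized to 8-bit RGB. Normalization is per-image — the
dataset-global alternative would leak split-wide statistics into single
images. PNG is the default export (lossless, so golden-image tests are
exact); JPEG (quality 95) is available for interchange.

## Climate chemometrics

* **Collinearity screen.** Pearson correlations among the Bio1–Bio19
  variables; while any retained pair has |R| > 0.8, the pair with the
  largest |R| is resolved by dropping the member with the larger mean
  absolute correlation to the remaining variables (tie: higher Bio
  index). The original study additionally weighed "significance for the
  distribution", which is not reproducible without its distribution
  model; the greedy mean-|R| rule is the documented stand-in and the
  full correlation matrix is always emitted for inspection.
* **Content summary.** Per-origin mean ± sample SD (n−1) of each
  saponin; the "total" column is the arithmetic mean of the four
  per-saponin group means — the only reading consistent with the
  published table's arithmetic (e.g. (8.26+31.28+19.95+6.71)/4 = 16.55),
  despite that table's header writing "sum". Report rounding is decimal
  half-up to 2 places.
* **PCA.** Correlation-matrix PCA (centered, scaled by sd with n−1);
  explained-variance percentages are reported for all components so the
  >80 % cumulative-variance criterion can be applied by the caller.
* **PLSR + VIP.** Partial least squares (NIPALS, standardized X,
  centered y) with coefficients back-transformed to one raw-unit linear
  equation (intercept + slopes). VIP uses the standard weight-normalized
  projection formula
  vipⱼ = √(p·Σₐ SSYₐ(wⱼₐ/‖wₐ‖)² / Σₐ SSYₐ), so Σ vip² = p identically;
  variables with VIP strictly > 1 are selected. The default component
  count is the smallest reaching 95 % leave-one-out explained variance
  (capped at p); the pipeline's equation report uses the full-rank fit,
  which on full-rank data coincides with ordinary least squares — this
  is how the printed seven-slope equations are recovered exactly from
  noiseless regenerated tables.

## Residual network and training protocol

The classifier is a 32-weighted-layer residual CNN implemented on the
package's own numpy layer engine (im2col convolutions, batch
normalization, ReLU, max/global-average pooling, softmax cross-entropy,
SGD with momentum): stem 3×3 convolution (stride 2) + BN + ReLU + 2×2
max pool, then four stages each opened by a projection ("conv") residual
block and followed by identity blocks — 4 conv and 11 identity blocks,
two 3×3 convolutions each — then global average pooling and one fully
connected layer. Stem + 30 block convolutions + FC = 32 weighted layers;
1×1 projection shortcuts are excluded from the count by the usual
residual-network convention. Only the block totals are architecturally
fixed; stage widths default to 8/16/32/64 with identity blocks
distributed 2/3/3/3, sized so a full training run takes minutes on one
CPU core. The layout is recorded in `NetSpec` and auditable via
`audit_weighted_layers`.

Training: SGD, learning rate 0.01, weight decay 0.0001 (applied to
convolution/FC weights, not BN parameters or biases — standard
practice), momentum 0.9 (a design choice; only lr and decay are
protocol-anchored), batch size 16, up to 100 epochs with early stop once
the evaluated training cross-entropy falls below 1e-4. Accuracy and loss
are logged per epoch on the train and test partitions; the exponential
smoothing factor 0.6 is applied to *exported display curves only*, never
to the optimized loss. Samples are split 60/30/10 into train/test/
external-validation partitions, stratified per class by
largest-remainder apportionment (tie priority train > test > external)
with seeded shuffling; the external partition is untouched until the
final confusion matrix. All randomness (weight init, batch order) is
generator-seeded, and retraining with the same seed reproduces the
curves exactly in a fixed BLAS configuration.

Default problem size: 4 classes × 32 samples (128 images of 128×128×3),
i.e. 76/40/12 per partition — a deliberate desk-scale stand-in for the
original 229-sample field collection, whose raw data are not deposited.
On this fixture the default run converges to 100 % accuracy on all three
partitions with training cross-entropy below 10⁻³ in ~15–50 epochs
depending on seed.

## Numerical and degenerate-input choices

* Ascending input grids are silently reversed (with intensities) to the
  descending convention; non-monotone grids are errors.
* A constant correlation map renders as the colormap's 0-color; a
  constant climate column is dropped from screening with a warning
  (its correlation is undefined).
* Groups of size 1 report SD 0 and carry a `singleton` flag.
* The loss turning non-finite aborts training with the epoch index
  rather than returning a poisoned report.
* float32 throughout the network; float64 in all chemometrics.

## Known limitations

* The per-sample map construction for the published images is
  under-specified upstream; both implemented modes are labelled and
  results may differ between them.
* The external-validation protocol at the published scale (152/54/23
  images) is not exactly 60/30/10 of 229; the apportionment rule here is
  documented, deterministic, and config-overridable rather than an
  attempt to reverse-engineer the original rounding.
* PCA variance shares, confusion matrices on real samples, epoch counts,
  and wall-clock times are data- and hardware-bound quantities of the
  original study and are not claims of this package.
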