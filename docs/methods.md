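# Methods

This note records the models implemented in `ramanquant`, the reasoning
behind the defaults, the numerical choices that matter for reproducibility,
and what the synthetic data generator does and does not emulate.

## The calibration problem

Each observation is a Raman spectrum: intensities on a shared, strictly
increasing wavenumber grid (M channels, cm⁻¹), paired with a scalar
reference value (here glucose concentration, mmol/L or mg/dL; the two units
convert at 18.016 mg/dL per mmol/L, from the 180.16 g/mol molar mass of
glucose). A dataset is the M×N intensity matrix, the shared grid, and the
N targets. The task is supervised calibration: learn a map from spectrum to
concentration that holds on spectra never used for training or model
selection.

## Preprocessing chain

Fixed order: crop → interpolate → median despike → baseline → smoothing →
normalization. Crop and interpolation come first because every later stage
assumes the final grid. All stages preserve the (M, N) pairing and never
touch the targets.

- **Crop**: closed interval [lo, hi] in cm⁻¹; at least 3 surviving points
  required.
- **Interpolation**: linear, no extrapolation (a request outside the data
  span is an error, not a silent fill).
- **Despike**: centered median filter, default window 5 points, nearest
  padding at the edges. A cosmic-ray spike occupies one or two channels,
  so a window of 5 removes it while a genuine band (≥ 6 points wide at the
  default resolution of ~1 cm⁻¹/channel) passes through.
- **Polynomial baseline** (default): iterative clip-to-fit. Fit a
  least-squares polynomial, clip the working spectrum to the pointwise
  minimum of spectrum and fit, refit; stop when consecutive fits differ by
  less than `poly_tol` in relative L2 norm, or after `poly_max_iter`
  iterations (then warn and use the last iterate). Plain least squares
  would be pulled up by the Raman peaks; the clipping excludes them so the
  fit converges to the smooth fluorescence floor. Defaults: degree 5 (broad
  fluorescence is low-order; higher degrees start wiggling at the spectrum
  edges where the clipping cannot constrain the fit), `poly_max_iter` 100,
  `poly_tol` 1e-4. The 1e-4 tolerance is the numerically meaningful
  stopping point: the iteration contracts quickly to the background and
  then creeps for hundreds of iterations at the noise floor, so a much
  tighter tolerance buys no accuracy, only iterations. The wavenumber axis
  is mapped affinely to [−1, 1] before fitting to condition the Vandermonde
  system.
- **EMSC**: each spectrum is regressed on [reference, 1, w, w², …] with
  w ∈ [−1, 1]; the corrected spectrum is (x − additive part)/b. A fitted
  multiplicative factor b ≤ 0 (or |b| < 1e-8) is reported as a degenerate
  fit rather than silently inverted. The reference defaults to the mean
  spectrum of the *training* partition; when a fitted workflow is archived,
  the reference vector is stored so held-out data is corrected identically.
- **Savitzky–Golay**: default window 11, order 3, mirror padding. SG
  reproduces polynomials up to its order exactly, so band shapes up to
  cubic curvature survive while high-frequency noise is averaged out.
- **Area normalization**: divide by the plain intensity sum. On the uniform
  default grid this differs from a trapezoid integral only by a constant
  factor, and it keeps the Σ = 1 invariant exact and idempotent. A zero-sum
  spectrum is an error naming the offending spectrum.

## Partitioning, leakage, and augmentation

The protocol holds out `n_prediction` spectra (default 10) as a prediction
set, then splits the remainder into training and test at `train_fraction`
(default 0.8; |train| is rounded to nearest, ties to even — for 75 spectra
this yields exactly 52/13/10). Partitions are uniformly random,
seed-reproducible, disjoint and exhaustive.

The workflow splits by index on the raw data and fits any data-dependent
preprocessing state (the EMSC reference) on the training partition only,
then applies it unchanged to test and prediction spectra. For the default
chain every stage is per-spectrum, so this is mathematically identical to
preprocessing first and splitting afterwards — but it stays leakage-free
when EMSC is selected.

**Standard-deviation-shift augmentation** computes σ(w), the per-wavenumber
standard deviation across the training spectra, and appends `factor − 1`
shifted copies of each spectrum. The default deterministic scheme uses the
cycling coefficients +s, −s, +2s, −2s, … (s = 0.5), which is reproducible
and mean-preserving whenever the copy count is even; a stochastic variant
adds s·ε⊙σ with ε i.i.d. standard normal per wavenumber. Copies inherit
their source spectrum's target. Augmentation is applied to the training
partition only, after splitting — augmenting before the split would place
near-copies of training spectra into the test set and inflate every score.

## Model families

**PLSR.** Single-response NIPALS: weights w ∝ Xᵀy, scores t = Xw, loadings
p = Xᵀt/tᵀt, response loading q = yᵀt/tᵀt, deflation of both X and y;
coefficients B = W(PᵀW)⁻¹q on centered data. Successive scores are
orthogonal, and with as many components as the rank of centered X the
predictions coincide with ordinary least squares (both facts are tested).
If deflation collapses (zero-norm weight), the model keeps the components
found and warns. The latent-variable count is chosen as the argmin of the
mean k-fold CV MSE over 1..max_components (default max = min(20, N−1, M),
k = 5), ties toward fewer components. Folds are seeded shuffled contiguous
blocks; the same fold engine serves the SVR grid search, so both families
see identical folds for a given seed.

**ε-SVR.** The dual quadratic program is solved by libsvm (through
scikit-learn); the fitted model is stored as a plain dual expansion
(support vectors, signed dual coefficients bounded by C, bias), and
prediction, the KKT bound check and the primal/dual duality-gap diagnostic
are computed from those arrays independently of the solver. Features are
standardized to zero mean / unit variance internally — a Gaussian kernel on
raw arbitrary-unit intensities would put all pairwise distances in the
saturated tail — and γ applies in the standardized space. Default search
grid: C ∈ {0.01, 0.1, 1, 10, 100, 1000}, ε ∈ {0.01, 0.1, 0.5},
γ ∈ {10⁻⁴ … 1} by decades; exhaustive CV over the Cartesian product, best =
smallest mean MSE, ties to the earlier grid point, full table returned for
logging.

**MLP.** Architecture [M, H, 1] with tansig (= tanh) hidden and linear
output units. Inputs and targets are min-max scaled to [−1, 1] — the
classic companion of tansig, which saturates outside roughly ±2 — and the
target scaling is inverted at prediction. Training is full-batch gradient
descent on the MSE of scaled targets, matching the plain gradient-descent
description of the training rule, with weights initialized uniformly in
[−0.5, 0.5] from a seeded generator. Early stopping: training halts at the
first epoch whose loss reaches the goal. Defaults: H = 4, 100 epochs,
learning rate 0.001, loss goal 0.0001. The backpropagation gradients are
verified against central finite differences at 1e-6 relative tolerance.

**1D CNN.** Four blocks of conv(same zero-padding, odd kernel, ReLU) +
non-overlapping max-pool(2); then flatten, a ReLU fully connected layer,
and one linear output neuron. The input length must be divisible by the
pooling product (16 by default; the error message says to interpolate to a
compatible grid). Defaults — filters (8, 16, 32, 64), kernel width 5,
dense 32, Adam (β₁ 0.9, β₂ 0.999), batch 16, 1000 optimizer steps at
learning rate 0.001 — are implementation choices exposed in config; filter
counts and kernel widths have no canonical values for spectra of this
length. "Iterations" means optimizer steps; the log records each step's
epoch too. A per-step progress callback can stop training (the programmatic
analogue of an interactive pause button). Convolution is cross-correlation
(tested against a brute-force double loop), and every parameter group's
gradient is finite-difference checked.

Both neural families scale inputs per-channel; constant channels map to 0
rather than dividing by zero.

## Evaluation

For n ≥ 2 paired values: SSE, MSE = SSE/n (divisor n, not n−1 — these are
descriptive errors of a fixed prediction, not variance estimates), RMSE,
MAE, R² = 1 − SSE/Σ(yᵢ−ȳ)², and Pearson COR. R² is computed against the
observed mean and can be negative — a model worse than predicting ȳ.
COR is undefined (reported as NaN / `null`) when either argument has zero
variance, e.g. a constant predictor. The implementation is tested against
a naive-summation oracle at 1e-12 relative on 1000 random pairs.

**Persistence.** Archives are single JSON documents: a self-describing
header (format tag, version, family, creation time) plus the numeric
payload and the preprocessing provenance (config, EMSC reference if any,
training grid). No executable content is serialized. JSON round-trips
Python floats exactly, so a reloaded model predicts bit-identically; the
archived grid lets `predict` refuse incompatible inputs explicitly.

## Synthetic data generator

Each raw spectrum is built as

    spectrum(w) = background(w) + Σ fixed bands + β·c·G(w; 1125, σ)
                  + spikes + noise

with every component recorded, so the emitted matrix equals the component
sum exactly and any pipeline stage can be audited against ground truth.

- Grid: 1024 points, 800–1800 cm⁻¹ (the biological fingerprint region).
- Design: 15 subjects × 7 spectra = 105 raw; a curated subset of 75 keeps
  the lowest-artifact realizations (smallest RMS of noise + spikes) — an
  explicit, mechanical stand-in for manual quality screening of unstable
  in vivo signals.
- Targets: glucose c ~ Uniform(4.6, 10.0) mmol/L (82.8–180 mg/dL).
- Glucose band: Gaussian at 1125 cm⁻¹, σ = 10 cm⁻¹, height β·c with
  β = 0.05 a.u. per mmol/L — a small feature relative to the fixed tissue
  bands (heights 0.7–1.1 a.u.), as in tissue.
- Fixed bands near 1003, 1305, 1450, 1655 cm⁻¹: generic fingerprint-region
  features chosen as plumbing, not claimed band assignments.
- Background: a smooth positive quadratic in the normalized wavenumber,
  scaled per subject (amplitude 5 ± 20%) — an order of magnitude above the
  Raman bands, as fluorescence is.
- Artifacts: Poisson(0.3) cosmic-ray spikes per spectrum of amplitude
  ~15 a.u. on single channels; i.i.d. Gaussian noise, σ = 0.01 a.u.

**What it does not emulate:** photon-count (Poisson) statistics, instrument
response and wavelength calibration drift, subject physiology (the glucose
band is exactly linear in c and perfectly positioned), band overlap with
the analyte, and matrix effects. Passing the recovery tests therefore shows
the *pipeline* is correct — preprocessing removes what it should, models
calibrate and generalize on data satisfying their assumptions — not that
any model reaches a particular accuracy on real in vivo spectra, which are
far noisier and nonlinear. On the generator's defaults, preprocessing +
CV-selected PLSR reaches held-out R² ≈ 0.998; an MLP at its protocol
defaults (4 hidden neurons, 100 epochs) underfits into the negative-R²
regime, which is the expected behavior of that configuration, not a defect.

## Problem sizes

The test suite and the acceptance script run at desk scale by choice:
recovery experiments use 200 simulated spectra at 1024 channels;
pipeline-determinism and CLI checks use 75 spectra at 256 channels;
gradient checks use instances of a few dozen parameters, where central
finite differences at h = 1e-6 are accurate to ~1e-10. The full acceptance
run completes in under a minute on one CPU.

## Known limitations

- PLSR is single-response; multi-analyte calibration is out of scope.
- The SVR kernel menu is linear/Gaussian only.
- The CNN and MLP run on CPU in numpy; they are faithful and verified, not
  fast, and no architecture search is provided.
- Curation by lowest injected artifact is a simulator construct; real
  quality screening is a judgment call the package does not model.
- The CLI's text containers (HDF5, two-column text) cover common exports;
  proprietary spectrometer formats are not parsed.
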