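# ramanquant

Quantitative regression on Raman spectra for biomedical calibration tasks —
the worked application is non-invasive blood-glucose estimation from in vivo
nailfold spectra.

Raman spectroscopy reads out molecular vibrations label-free, which makes it
attractive for quantifying analytes such as glucose directly in tissue. In
practice the analyte signal (e.g. the glucose band near 1125 cm⁻¹) is a tiny
feature riding on a fluorescence background orders of magnitude larger,
contaminated by cosmic-ray spikes and detector noise, and spread over ~10³
strongly collinear spectral channels. Turning such spectra into
concentrations therefore takes a full chain: preprocessing, careful
train/test/prediction partitioning, a multivariate calibration model, and
honest evaluation on spectra the model never saw. `ramanquant` implements
that chain as a tested, headless library with a CLI, plus a synthetic
nailfold-spectrum generator so the whole pipeline runs at desk scale with no
external data.

## What is inside

**Preprocessing** (`ramanquant.preprocess`), applied in fixed order:
crop → interpolate → median despike → baseline correction → Savitzky–Golay
smoothing → area normalization. Baseline correction is either iterative
polynomial fitting (ModPoly-style clip-to-fit) or extended multiplicative
signal correction (EMSC), which models each spectrum *x* against a
reference *m* as *x = b·m + Σₖ pₖ wᵏ + e* and returns
*(x − Σₖ pₖ wᵏ)/b*.

**Partitioning and augmentation** (`ramanquant.datasets`): hold out a
prediction set (default 10 spectra), split the remainder 80/20 into
training/test, and optionally enlarge the training set by
standard-deviation shift — copies of each spectrum displaced by multiples
of the per-wavenumber standard deviation σ(w) (default 4× enlargement).

**Four regression families**:

- **PLSR** (`ramanquant.chemometrics`): *Y = X·B + E* via NIPALS latent
  variables; the latent-variable count is chosen by the smallest mean
  cross-validated MSE.
- **ε-SVR**: minimizes ½‖w‖² + C Σᵢ(ξᵢ + ξᵢ\*) subject to the ε-insensitive
  constraints, with linear or Gaussian kernels and cross-validated grid
  search over (C, ε, γ).
- **MLP** (`ramanquant.neuralnets`): one hidden layer, tansig hidden /
  purelin output transfer functions, full-batch gradient-descent
  backpropagation with early stopping on a loss goal (defaults: 4 hidden
  neurons, 100 epochs, learning rate 0.001, loss goal 0.0001).
- **1D CNN**: four conv(same padding, ReLU) + max-pool(2) blocks, a fully
  connected layer and a single regression neuron, trained by mini-batch
  adaptive-moment descent (defaults: 1000 iterations, learning rate 0.001).
  Both networks are plain numpy with analytic backpropagation, verified
  against finite differences in the test suite.

**Evaluation** (`ramanquant.evaluation`): SSE, MSE (= SSE/n), RMSE, MAE,
R² = 1 − SSE/Σ(yᵢ−ȳ)² (negative when the model underperforms the mean) and
the Pearson correlation COR, plus JSON model archives that round-trip with
bit-identical predictions and carry their preprocessing provenance.

**Simulation** (`ramanquant.simulate`): a seeded generator emulating the
study dataset — 15 subjects × 7 spectra on 1024 points over 800–1800 cm⁻¹,
a curated 75-spectrum subset, glucose targets spanning 4.6–10.0 mmol/L
(82.8–180 mg/dL), a glucose-proportional band at 1125 cm⁻¹, smooth
fluorescence background, cosmic-ray spikes and noise — with the exact
additive ground-truth decomposition returned alongside for testing.

## Worked example

```python
from ramanquant import RamanRegression, SimConfig, generate

dataset, _ = generate(SimConfig(seed=0))          # 75 synthetic nailfold spectra
task = RamanRegression(dataset, family="plsr", seed=0)
results = task.fit()
print(results.summary())
```

prints

```
Raman quantitative regression results
======================================================
model family:     plsr
dataset:          N=75 spectra, M=1024 points
target unit:      mmol/L
partitions:       {'train': 52, 'test': 13, 'prediction': 10}
latent variables: 2 (CV-selected)
------------------------------------------------------
                    train         test   prediction
n                      52           13           10
SSE                0.1332       0.1387       0.0430
MSE                0.0026       0.0107       0.0043
RMSE               0.0506       0.1033       0.0656
MAE                0.0398       0.0910       0.0461
R2                 0.9991       0.9944       0.9984
COR                0.9995       0.9975       0.9994
======================================================
```

The 75 spectra were split into 52 training, 13 test and 10 prediction
spectra; cross-validation picked 2 latent variables (the synthetic data has
one glucose-proportional band on a subject-scaled background, so two
directions suffice). The prediction-set RMSE of 0.066 mmol/L against a
4.6–10 mmol/L target range (R² = 0.998) says the calibration transfers to
spectra never used for training or model selection — on clean synthetic
data; in vivo spectra are far harder. `results.save("model.json")`
archives the model together with its preprocessing provenance, and
`results.plot_predictions("prediction")` draws the observed-vs-predicted
scatter.

The same workflow runs from the shell:

```bash
ramanquant train --config config.yaml --out run/
ramanquant predict --model run/model.json --in run/prediction_set.h5 --out pred.txt
```

with a config such as

```yaml
seed: 0
simulate: {seed: 0}            # or: input: {container: data.h5}
preprocess: {poly_degree: 5}
split: {n_prediction: 10, train_fraction: 0.8}
model:
  family: plsr
  plsr: {}
```

## Documentation

`docs/methods.md` describes the models, the synthetic-data generator and
its limitations, the numerical choices, and the defaults in detail.
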