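"""Neural-network regressors: a one-hidden-layer MLP and a 1D CNN.

Both are implemented directly in numpy with analytic backpropagation (the
gradients are verified against finite differences in the test suite).

* The MLP uses the classic ``tansig`` (hyperbolic tangent) hidden activation
  and a linear (``purelin``) output neuron, trained by full-batch gradient
  descent on the MSE with early stopping on a loss goal.  Inputs and targets
  are min-max scaled to [-1, 1] — the standard companion of tansig/purelin —
  and the scaling is inverted at prediction time.
* The CNN stacks four conv(same padding, ReLU) + maxpool(2) blocks, then a
  fully connected layer feeding a single regression neuron, trained by
  mini-batch adaptive-moment (Adam) gradient descent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .exceptions import ConfigError, TrainingError, ValidationError
from .io import SpectralDataset

__all__ = [
    "tansig",
    "relu",
    "conv1d_forward",
    "MLPTrainSpec",
    "MLPModel",
    "fit_mlp",
    "CNNTrainSpec",
    "CNNModel",
    "build_cnn",
    "fit_cnn",
    "predict_nn",
    "DEFAULT_CNN_BLOCKS",
]

#: Default CNN architecture: (filters, kernel width, pool width) per block.
DEFAULT_CNN_BLOCKS = ((8, 5, 2), (16, 5, 2), (32, 5, 2), (64, 5, 2))


def tansig(x):
    """Hyperbolic-tangent sigmoid transfer function, 2/(1+e^(-2x)) - 1.

    Algebraically identical to tanh(x); range (-1, 1).
    """
    return np.tanh(x)


def relu(x):
    """Rectified linear unit, max(0, x) elementwise."""
    return np.maximum(0.0, np.asarray(x))


def conv1d_forward(signal: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Cross-correlate a 1-D signal with an odd-width kernel (zero same-padding).

    Output length equals input length. This is the single-channel primitive
    the CNN's convolutional layers generalize.
    """
    signal = np.asarray(signal, dtype=float).ravel()
    kernel = np.asarray(kernel, dtype=float).ravel()
    if kernel.size % 2 == 0:
        raise ConfigError(f"kernel width must be odd, got {kernel.size}")
    pad = kernel.size // 2
    padded = np.pad(signal, pad)
    return np.correlate(padded, kernel, mode="valid")


# ---------------------------------------------------------------------------
# Min-max scaling to [-1, 1]
# ---------------------------------------------------------------------------

@dataclass
class MinMaxScaler:
    """Per-feature affine map onto [-1, 1]; constant features map to 0."""

    center: np.ndarray
    halfspan: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "MinMaxScaler":
        X = np.atleast_2d(np.asarray(X, dtype=float))
        lo = X.min(axis=0)
        hi = X.max(axis=0)
        center = (hi + lo) / 2.0
        halfspan = (hi - lo) / 2.0
        halfspan[halfspan == 0] = 1.0
        return cls(center=center, halfspan=halfspan)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) / self.halfspan

    def inverse(self, Xs: np.ndarray) -> np.ndarray:
        return np.asarray(Xs, dtype=float) * self.halfspan + self.center


# ---------------------------------------------------------------------------
# MLP
# ---------------------------------------------------------------------------

@dataclass
class MLPTrainSpec:
    """MLP training hyperparameters (protocol defaults)."""

    hidden_neurons: int = 4
    epochs: int = 100
    learning_rate: float = 0.001
    loss_goal: float = 0.0001
    seed: int = 0
    init_range: float = 0.5  # weights drawn uniformly in [-init_range, init_range]

    def validate(self) -> None:
        if self.hidden_neurons < 1:
            raise ConfigError("hidden_neurons must be >= 1")
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.learning_rate <= 0 or self.loss_goal <= 0:
            raise ConfigError("learning_rate and loss_goal must be > 0")


@dataclass
class MLPModel:
    """One-hidden-layer regression MLP with tansig/purelin transfer functions.

    The forward pass on scaled input ``x`` is
    ``purelin(W2 @ tansig(W1 @ x + b1) + b2)``; input and target min-max
    scalers are stored and inverted at prediction.
    """

    params: dict  # W1 (H, M), b1 (H,), W2 (1, H), b2 (1,)
    x_scaler: MinMaxScaler
    y_scaler: MinMaxScaler
    training_log: list[dict] = field(default_factory=list)
    stopped_early: bool = False
    spec: MLPTrainSpec | None = None

    family = "mlp"

    @property
    def hidden_neurons(self) -> int:
        return self.params["W1"].shape[0]

    @property
    def n_features(self) -> int:
        return self.params["W1"].shape[1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise ValidationError(
                f"X has {X.shape[1]} features; model was trained with {self.n_features}"
            )
        Xs = self.x_scaler.transform(X)
        a1 = tansig(Xs @ self.params["W1"].T + self.params["b1"])
        out = a1 @ self.params["W2"].T + self.params["b2"]
        return self.y_scaler.inverse(out).ravel()


def mlp_init(n_features: int, hidden: int, seed: int,
             init_range: float = 0.5) -> dict:
    """Seed-reproducible uniform weight initialization in [-r, r]."""
    rng = np.random.default_rng(seed)
    r = init_range
    return {
        "W1": rng.uniform(-r, r, size=(hidden, n_features)),
        "b1": rng.uniform(-r, r, size=hidden),
        "W2": rng.uniform(-r, r, size=(1, hidden)),
        "b2": rng.uniform(-r, r, size=1),
    }


def mlp_loss_and_grads(params: dict, Xs: np.ndarray, ys: np.ndarray
                       ) -> tuple[float, dict]:
    """MSE loss on scaled data and its analytic gradients.

    Exposed separately so the gradients can be checked against a
    finite-difference oracle.
    """
    n = Xs.shape[0]
    z1 = Xs @ params["W1"].T + params["b1"]  # (n, H)
    a1 = np.tanh(z1)
    yhat = a1 @ params["W2"].T + params["b2"]  # (n, 1)
    resid = yhat - ys.reshape(-1, 1)
    loss = float(np.mean(resid ** 2))
    d = 2.0 * resid / n  # dL/dyhat
    grads = {
        "W2": d.T @ a1,
        "b2": d.sum(axis=0),
        "b1": None,
        "W1": None,
    }
    da1 = d @ params["W2"]  # (n, H)
    dz1 = da1 * (1.0 - a1 ** 2)
    grads["W1"] = dz1.T @ Xs
    grads["b1"] = dz1.sum(axis=0)
    return loss, grads


def fit_mlp(train: SpectralDataset, spec: MLPTrainSpec | None = None,
            validation: SpectralDataset | None = None) -> MLPModel:
    """Train the MLP by full-batch gradient descent with early stopping.

    Training stops at the first epoch whose (pre-update) MSE on scaled
    targets reaches or falls below ``loss_goal``; otherwise it runs the full
    epoch budget. The per-epoch loss trajectory is logged; a validation set,
    if given, is monitored and logged but does not influence stopping.
    """
    spec = spec or MLPTrainSpec()
    spec.validate()
    if train.targets is None:
        raise ValidationError("training dataset has no targets")
    X = train.to_rows()
    y = train.targets
    x_scaler = MinMaxScaler.fit(X)
    y_scaler = MinMaxScaler.fit(y.reshape(-1, 1))
    Xs = x_scaler.transform(X)
    ys = y_scaler.transform(y.reshape(-1, 1)).ravel()
    val = None
    if validation is not None and validation.targets is not None:
        val = (x_scaler.transform(validation.to_rows()),
               y_scaler.transform(validation.targets.reshape(-1, 1)).ravel())

    params = mlp_init(X.shape[1], spec.hidden_neurons, spec.seed, spec.init_range)
    log: list[dict] = []
    stopped = False
    for epoch in range(1, spec.epochs + 1):
        loss, grads = mlp_loss_and_grads(params, Xs, ys)
        if not np.isfinite(loss):
            raise TrainingError(f"MLP training diverged at epoch {epoch}")
        entry = {"epoch": epoch, "train_mse": loss}
        if val is not None:
            vloss, _vg = mlp_loss_and_grads(params, val[0], val[1])
            entry["val_mse"] = vloss
        log.append(entry)
        if loss <= spec.loss_goal:
            stopped = True
            break
        for k in params:
            params[k] = params[k] - spec.learning_rate * grads[k]
    return MLPModel(params=params, x_scaler=x_scaler, y_scaler=y_scaler,
                    training_log=log, stopped_early=stopped, spec=spec)


# ---------------------------------------------------------------------------
# 1D CNN
# ---------------------------------------------------------------------------

@dataclass
class CNNTrainSpec:
    """CNN training hyperparameters (protocol defaults)."""

    iterations: int = 1000
    learning_rate: float = 0.001
    batch_size: int = 16
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    adam_eps: float = 1e-8

    def validate(self) -> None:
        if self.iterations < 1 or self.batch_size < 1:
            raise ConfigError("iterations and batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Batched multi-channel cross-correlation with zero same-padding.

    x: (B, C_in, L); W: (C_out, C_in, k); returns (B, C_out, L).
    """
    k = W.shape[2]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    win = sliding_window_view(xp, k, axis=2)  # (B, C_in, L, k)
    return np.einsum("bcik,ock->boi", win, W, optimize=True) + b[None, :, None]


def _conv_backward(dout: np.ndarray, x: np.ndarray, W: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gradients of the same-padded cross-correlation. Returns (dx, dW, db)."""
    k = W.shape[2]
    pad = k // 2
    L = x.shape[2]
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    win = sliding_window_view(xp, k, axis=2)
    dW = np.einsum("boi,bcik->ock", dout, win, optimize=True)
    db = dout.sum(axis=(0, 2))
    dxp = np.zeros_like(xp)
    for j in range(k):
        dxp[:, :, j:j + L] += np.einsum("boi,oc->bci", dout, W[:, :, j], optimize=True)
    dx = dxp[:, :, pad:pad + L]
    return dx, dW, db


def _maxpool_forward(x: np.ndarray, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping max pooling along the last axis; returns (out, argmax)."""
    B, C, L = x.shape
    xr = x.reshape(B, C, L // width, width)
    arg = xr.argmax(axis=3)
    out = np.take_along_axis(xr, arg[..., None], axis=3)[..., 0]
    return out, arg


def _maxpool_backward(dout: np.ndarray, arg: np.ndarray, width: int,
                      in_length: int) -> np.ndarray:
    B, C, Lp = dout.shape
    dxr = np.zeros((B, C, Lp, width))
    np.put_along_axis(dxr, arg[..., None], dout[..., None], axis=3)
    return dxr.reshape(B, C, in_length)


@dataclass
class CNNModel:
    """A 1D convolutional regression network.

    Architecture: ``blocks`` repetitions of conv(same padding, ReLU) +
    maxpool, then flatten, a ReLU fully connected layer, and a single
    linear output neuron. ``feature_length`` is the spectral length after
    all pooling stages.
    """

    blocks: tuple  # ((filters, kernel_width, pool_width), ...)
    input_length: int
    dense_units: int
    params: dict  # conv{i}_W, conv{i}_b, dense_W, dense_b, out_w, out_b
    x_scaler: MinMaxScaler | None = None
    y_scaler: MinMaxScaler | None = None
    training_log: list[dict] = field(default_factory=list)
    spec: CNNTrainSpec | None = None

    family = "cnn"

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def feature_length(self) -> int:
        length = self.input_length
        for _, _, pool in self.blocks:
            length //= pool
        return length

    def forward(self, Xs: np.ndarray) -> np.ndarray:
        """Forward pass on scaled (B, M) input; returns (B,) scaled outputs."""
        out, _ = _cnn_forward_cached(self.params, self.blocks, Xs)
        return out.ravel()

    def predict(self, X: np.ndarray, batch: int = 256) -> np.ndarray:
        if self.x_scaler is None or self.y_scaler is None:
            raise ValidationError("CNN model has not been trained (no scalers)")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_length:
            raise ValidationError(
                f"X has {X.shape[1]} features; model expects {self.input_length}"
            )
        Xs = self.x_scaler.transform(X)
        outs = [self.forward(Xs[i:i + batch]) for i in range(0, Xs.shape[0], batch)]
        ys = np.concatenate(outs)
        return self.y_scaler.inverse(ys.reshape(-1, 1)).ravel()


def build_cnn(input_length: int, blocks_config=None, dense_units: int = 32,
              seed: int = 0) -> CNNModel:
    """Construct an untrained CNN for spectra of the given length.

    The input length must be divisible by the product of the pool widths
    (16 for the default four blocks of pool 2), so that every pooling stage
    sees an even split.
    """
    blocks = tuple(tuple(b) for b in (blocks_config or DEFAULT_CNN_BLOCKS))
    pool_product = 1
    for filters, kernel, pool in blocks:
        if kernel % 2 == 0:
            raise ConfigError(f"conv kernel width must be odd, got {kernel}")
        if filters < 1 or pool < 1:
            raise ConfigError("filter count and pool width must be >= 1")
        pool_product *= pool
    if input_length % pool_product != 0:
        raise ConfigError(
            f"input length {input_length} is not divisible by the pooling "
            f"product {pool_product}; interpolate the spectra to a compatible "
            f"grid (e.g. {input_length - input_length % pool_product} points) first"
        )
    rng = np.random.default_rng(seed)
    params: dict = {}
    c_in = 1
    length = input_length
    for i, (filters, kernel, pool) in enumerate(blocks):
        fan_in = c_in * kernel
        params[f"conv{i}_W"] = rng.standard_normal((filters, c_in, kernel)) * np.sqrt(2.0 / fan_in)
        params[f"conv{i}_b"] = np.zeros(filters)
        c_in = filters
        length //= pool
    flat = c_in * length
    params["dense_W"] = rng.standard_normal((dense_units, flat)) * np.sqrt(2.0 / flat)
    params["dense_b"] = np.zeros(dense_units)
    params["out_w"] = rng.standard_normal((1, dense_units)) * np.sqrt(1.0 / dense_units)
    params["out_b"] = np.zeros(1)
    return CNNModel(blocks=blocks, input_length=input_length,
                    dense_units=dense_units, params=params)


def _cnn_forward_cached(params: dict, blocks: tuple, Xs: np.ndarray):
    """Forward pass returning (output (B, 1), cache for backprop)."""
    x = Xs[:, None, :]  # (B, 1, M)
    cache = {"inputs": [], "pre": [], "pooled_arg": [], "pre_pool_len": []}
    for i, (filters, kernel, pool) in enumerate(blocks):
        cache["inputs"].append(x)
        z = _conv_forward(x, params[f"conv{i}_W"], params[f"conv{i}_b"])
        a = np.maximum(z, 0.0)
        cache["pre"].append(z)
        cache["pre_pool_len"].append(a.shape[2])
        x, arg = _maxpool_forward(a, pool)
        cache["pooled_arg"].append(arg)
    B = x.shape[0]
    flat = x.reshape(B, -1)
    cache["flat_shape"] = x.shape
    cache["flat"] = flat
    zd = flat @ params["dense_W"].T + params["dense_b"]
    hd = np.maximum(zd, 0.0)
    cache["zd"] = zd
    cache["hd"] = hd
    out = hd @ params["out_w"].T + params["out_b"]
    return out, cache


def cnn_loss_and_grads(params: dict, blocks: tuple, Xs: np.ndarray,
                       ys: np.ndarray) -> tuple[float, dict]:
    """MSE loss on scaled data and analytic gradients for every parameter."""
    out, cache = _cnn_forward_cached(params, blocks, Xs)
    n = Xs.shape[0]
    resid = out - ys.reshape(-1, 1)
    loss = float(np.mean(resid ** 2))
    d = 2.0 * resid / n  # (B, 1)
    grads: dict = {}
    grads["out_w"] = d.T @ cache["hd"]
    grads["out_b"] = d.sum(axis=0)
    dhd = d @ params["out_w"]
    dzd = dhd * (cache["zd"] > 0)
    grads["dense_W"] = dzd.T @ cache["flat"]
    grads["dense_b"] = dzd.sum(axis=0)
    dflat = dzd @ params["dense_W"]
    dx = dflat.reshape(cache["flat_shape"])
    for i in range(len(blocks) - 1, -1, -1):
        _, _, pool = blocks[i]
        da = _maxpool_backward(dx, cache["pooled_arg"][i], pool,
                               cache["pre_pool_len"][i])
        dz = da * (cache["pre"][i] > 0)
        dx, dW, db = _conv_backward(dz, cache["inputs"][i], params[f"conv{i}_W"])
        grads[f"conv{i}_W"] = dW
        grads[f"conv{i}_b"] = db
    return loss, grads


def fit_cnn(train: SpectralDataset, spec: CNNTrainSpec | None = None,
            progress_callback: Callable[[int, float], bool] | None = None,
            blocks_config=None, dense_units: int = 32) -> CNNModel:
    """Train the CNN by mini-batch Adam for ``spec.iterations`` optimizer steps.

    ``progress_callback(step, loss)`` is invoked once per step (after the
    step's log entry is recorded); returning a truthy value stops training —
    the programmatic analogue of an interactive pause/terminate control.
    The log records each step's mini-batch loss together with its epoch
    (a pass over the shuffled training set).
    """
    spec = spec or CNNTrainSpec()
    spec.validate()
    if train.targets is None:
        raise ValidationError("training dataset has no targets")
    X = train.to_rows()
    y = train.targets
    model = build_cnn(X.shape[1], blocks_config=blocks_config,
                      dense_units=dense_units, seed=spec.seed)
    x_scaler = MinMaxScaler.fit(X)
    y_scaler = MinMaxScaler.fit(y.reshape(-1, 1))
    Xs = x_scaler.transform(X)
    ys = y_scaler.transform(y.reshape(-1, 1)).ravel()
    n = Xs.shape[0]
    batch_size = min(spec.batch_size, n)
    steps_per_epoch = int(np.ceil(n / batch_size))

    rng = np.random.default_rng(spec.seed)
    m_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    v_state = {k: np.zeros_like(v) for k, v in model.params.items()}
    log: list[dict] = []
    step = 0
    order = rng.permutation(n)
    pos = 0
    while step < spec.iterations:
        if pos >= n:
            order = rng.permutation(n)
            pos = 0
        idx = order[pos:pos + batch_size]
        pos += batch_size
        step += 1
        loss, grads = cnn_loss_and_grads(model.params, model.blocks, Xs[idx], ys[idx])
        if not np.isfinite(loss):
            raise TrainingError(f"CNN training diverged at step {step}")
        t = step
        for k in model.params:
            g = grads[k]
            m_state[k] = spec.beta1 * m_state[k] + (1 - spec.beta1) * g
            v_state[k] = spec.beta2 * v_state[k] + (1 - spec.beta2) * g ** 2
            mhat = m_state[k] / (1 - spec.beta1 ** t)
            vhat = v_state[k] / (1 - spec.beta2 ** t)
            model.params[k] = model.params[k] - spec.learning_rate * mhat / (
                np.sqrt(vhat) + spec.adam_eps)
        log.append({"step": step, "epoch": 1 + (step - 1) // steps_per_epoch,
                    "batch_mse": loss})
        if progress_callback is not None and progress_callback(step, loss):
            break
    model.x_scaler = x_scaler
    model.y_scaler = y_scaler
    model.training_log = log
    model.spec = spec
    return model


def predict_nn(model, X: np.ndarray) -> np.ndarray:
    """Shared prediction entry point for MLP and CNN models (target units)."""
    if not isinstance(model, (MLPModel, CNNModel)):
        raise ValidationError(f"object of type {type(model).__name__} is not a neural model")
    out = model.predict(np.atleast_2d(np.asarray(X, dtype=float)))
    if not np.all(np.isfinite(out)):
        raise ValidationError("model produced non-finite predictions")
    return out
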