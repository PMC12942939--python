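"""Classical chemometric regressors: PLSR and epsilon-SVR.

Partial least squares regression models ``Y = X B + E`` through latent
variables — linear combinations of spectral channels chosen to maximize
covariance with the response — which makes it the standard tool for
high-dimensional, collinear spectra.  The latent-variable count is chosen
by cross-validation (smallest mean MSE).

Epsilon-SVR minimizes ``1/2 ||w||^2 + C sum(xi + xi*)`` subject to residuals
exceeding the insensitivity half-width ``epsilon`` only through the slack
variables.  The quadratic program is solved by libsvm (via scikit-learn);
prediction and the KKT / duality diagnostics are computed here from the
stored dual expansion, so fitted models are plain numeric payloads.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVR as _SklearnSVR

from .datasets import kfold_indices
from .exceptions import ConfigError, TrainingError, ValidationError

__all__ = [
    "PLSRModel",
    "SVRModel",
    "fit_plsr",
    "select_plsr_components",
    "fit_svr",
    "grid_search_svr",
    "predict",
    "svr_objectives",
    "DEFAULT_SVR_GRID",
]

#: Default hyperparameter grid for SVR grid search.
DEFAULT_SVR_GRID = {
    "C": [0.01, 0.1, 1.0, 10.0, 100.0, 1000.0],
    "epsilon": [0.01, 0.1, 0.5],
    "gamma": [1e-4, 1e-3, 1e-2, 1e-1, 1.0],
}


# ---------------------------------------------------------------------------
# PLSR (NIPALS)
# ---------------------------------------------------------------------------

@dataclass
class PLSRModel:
    """A fitted single-response PLSR model.

    ``coef`` maps centered X to centered y: predictions are
    ``(X - x_mean) @ coef + y_mean``. Weights ``W``, loadings ``P`` and the
    response loadings ``q`` are retained for inspection (e.g. linking
    spectral bands to the response); training scores ``T`` have mutually
    orthogonal columns.
    """

    n_components: int
    x_mean: np.ndarray
    y_mean: float
    coef: np.ndarray
    weights: np.ndarray  # W, (M, A)
    loadings: np.ndarray  # P, (M, A)
    y_loadings: np.ndarray  # q, (A,)
    scores: np.ndarray | None = None  # T, (N, A), training scores

    family = "plsr"

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean.size:
            raise ValidationError(
                f"X has {X.shape[1]} features; model was trained with {self.x_mean.size}"
            )
        return (X - self.x_mean) @ self.coef + self.y_mean


def fit_plsr(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSRModel:
    """Fit single-response PLSR by NIPALS with X and y deflation.

    Parameters
    ----------
    X : ndarray, shape (N, M)
        Design matrix, one spectrum per row.
    y : ndarray, shape (N,)
        Response values.
    n_components : int
        Number of latent variables, ``1 <= A <= min(N-1, M)``.

    Notes
    -----
    If deflation collapses (zero-norm weight vector) before ``n_components``
    components are extracted, the model keeps the components found so far
    and a warning is emitted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValidationError(f"X shape {X.shape} inconsistent with y length {y.size}")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValidationError("X and y must be finite")
    n, m = X.shape
    limit = min(n - 1, m)
    if not 1 <= n_components <= limit:
        raise ConfigError(
            f"n_components must lie in [1, min(N-1, M)] = [1, {limit}]; got {n_components}"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_mean
    yd = y - y_mean

    W, P, Q, T = [], [], [], []
    for _ in range(n_components):
        w = Xd.T @ yd
        norm_w = float(np.linalg.norm(w))
        if norm_w < 1e-12:
            warnings.warn(
                f"PLSR deflation collapsed after {len(W)} components; "
                f"model uses {len(W)} instead of {n_components}",
                RuntimeWarning,
            )
            break
        w = w / norm_w
        t = Xd @ w
        tt = float(t @ t)
        if tt < 1e-24:
            warnings.warn(
                f"PLSR score vector vanished after {len(W)} components",
                RuntimeWarning,
            )
            break
        p = Xd.T @ t / tt
        q = float(yd @ t) / tt
        Xd = Xd - np.outer(t, p)
        yd = yd - q * t
        W.append(w)
        P.append(p)
        Q.append(q)
        T.append(t)

    if not W:
        raise TrainingError("PLSR found no usable components (X'y is zero)")
    Wm = np.column_stack(W)
    Pm = np.column_stack(P)
    qv = np.asarray(Q)
    Tm = np.column_stack(T)
    coef = Wm @ np.linalg.solve(Pm.T @ Wm, qv)
    return PLSRModel(
        n_components=Wm.shape[1],
        x_mean=x_mean,
        y_mean=y_mean,
        coef=coef,
        weights=Wm,
        loadings=Pm,
        y_loadings=qv,
        scores=Tm,
    )


def select_plsr_components(X: np.ndarray, y: np.ndarray, k_folds: int = 5,
                           max_components: int | None = None, seed: int = 0
                           ) -> tuple[int, np.ndarray]:
    """Choose the latent-variable count with the smallest mean CV MSE.

    Returns ``(best_count, mse_curve)`` where ``mse_curve[a-1]`` is the mean
    cross-validated MSE with ``a`` components. Ties break toward fewer
    components.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, m = X.shape
    if n < k_folds:
        raise ConfigError(f"N={n} samples cannot be split into {k_folds} folds")
    folds = kfold_indices(n, k_folds, seed)
    min_train = min(n - f.size for f in folds)
    limit = min(min_train - 1, m)
    if max_components is None:
        max_components = min(20, limit)
    max_components = int(max_components)
    if not 1 <= max_components <= limit:
        raise ConfigError(
            f"max_components must lie in [1, {limit}] for this fold layout; "
            f"got {max_components}"
        )
    mse = np.zeros(max_components)
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        # one fit at the maximum size; truncating NIPALS components is not
        # equivalent to refitting, so fit per component count (cheap at these sizes)
        for a in range(1, max_components + 1):
            model = fit_plsr(X[mask], y[mask], a)
            resid = y[fold] - model.predict(X[fold])
            mse[a - 1] += float(np.mean(resid ** 2)) / len(folds)
    best = int(np.argmin(mse)) + 1  # argmin returns the first (fewest) on ties
    return best, mse


# ---------------------------------------------------------------------------
# epsilon-SVR
# ---------------------------------------------------------------------------

@dataclass
class SVRModel:
    """A fitted epsilon-SVR model as a plain dual expansion.

    Features are standardized internally (zero mean, unit variance); the
    stored support vectors live in the standardized space. Predictions are
    ``g(x) = sum_i alpha_i k(sv_i, x~) + b`` with ``alpha`` the signed dual
    coefficients, each bounded by C in magnitude.
    """

    kernel: str
    C: float
    epsilon: float
    gamma: float | None
    support_vectors: np.ndarray  # (n_sv, M), standardized
    dual_coef: np.ndarray  # (n_sv,), signed alpha - alpha*
    intercept: float
    x_mean: np.ndarray
    x_scale: np.ndarray
    support_targets: np.ndarray = field(default_factory=lambda: np.empty(0))

    family = "svr"

    @property
    def n_support(self) -> int:
        return int(self.dual_coef.size)

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self.x_mean) / self.x_scale

    def _kernel_matrix(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        if self.kernel == "linear":
            return A @ B.T
        sq = (
            np.sum(A ** 2, axis=1)[:, None]
            + np.sum(B ** 2, axis=1)[None, :]
            - 2.0 * A @ B.T
        )
        return np.exp(-self.gamma * np.maximum(sq, 0.0))

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.x_mean.size:
            raise ValidationError(
                f"X has {X.shape[1]} features; model was trained with {self.x_mean.size}"
            )
        Xs = self._standardize(X)
        if self.n_support == 0:
            return np.full(X.shape[0], self.intercept)
        K = self._kernel_matrix(Xs, self.support_vectors)
        return K @ self.dual_coef + self.intercept


def fit_svr(X: np.ndarray, y: np.ndarray, kernel: str = "gaussian",
            C: float = 1.0, epsilon: float = 0.1,
            gamma: float | None = None, tol: float = 1e-6,
            max_iter: int = 2_000_000) -> SVRModel:
    """Solve the epsilon-SVR problem with a linear or Gaussian kernel.

    Features are standardized to zero mean / unit variance internally
    (recorded in the model), since Gaussian kernels on raw arbitrary-unit
    scales are degenerate. ``gamma`` applies in the standardized space.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValidationError(f"X rows {X.shape[0]} != y length {y.size}")
    if C <= 0:
        raise ConfigError(f"C must be > 0, got {C}")
    if epsilon < 0:
        raise ConfigError(f"epsilon must be >= 0, got {epsilon}")
    if kernel not in ("linear", "gaussian"):
        raise ConfigError(f"kernel must be 'linear' or 'gaussian', got {kernel!r}")
    if kernel == "gaussian":
        if gamma is None:
            gamma = 1.0 / X.shape[1]
        if gamma <= 0:
            raise ConfigError(f"gamma must be > 0 for the gaussian kernel, got {gamma}")
    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=0)
    x_scale[x_scale == 0] = 1.0
    Xs = (X - x_mean) / x_scale

    sk = _SklearnSVR(
        kernel="linear" if kernel == "linear" else "rbf",
        C=C, epsilon=epsilon,
        gamma=gamma if kernel == "gaussian" else "scale",
        tol=tol, max_iter=max_iter, cache_size=200,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=UserWarning)
        try:
            sk.fit(Xs, y)
        except UserWarning as exc:  # libsvm convergence warning
            raise TrainingError(
                f"SVR solver did not converge within {max_iter} iterations: {exc}"
            ) from exc
    return SVRModel(
        kernel=kernel, C=float(C), epsilon=float(epsilon),
        gamma=float(gamma) if kernel == "gaussian" else None,
        support_vectors=np.asarray(sk.support_vectors_, dtype=float),
        dual_coef=np.asarray(sk.dual_coef_, dtype=float).ravel(),
        intercept=float(sk.intercept_[0]),
        x_mean=x_mean, x_scale=x_scale,
        support_targets=y[sk.support_],
    )


def svr_objectives(model: SVRModel, X: np.ndarray, y: np.ndarray
                   ) -> tuple[float, float]:
    """Primal and dual objective values of a fitted SVR on its training data.

    The gap between them certifies optimality (it is zero at the exact
    solution). The RKHS norm term is computed from the dual expansion, so
    this diagnostic is independent of the solver.
    """
    y = np.asarray(y, dtype=float).ravel()
    f = model.predict(X)
    if model.n_support:
        K = model._kernel_matrix(model.support_vectors, model.support_vectors)
        wsq = float(model.dual_coef @ K @ model.dual_coef)
    else:
        wsq = 0.0
    slack = np.maximum(np.abs(y - f) - model.epsilon, 0.0)
    primal = 0.5 * wsq + model.C * float(slack.sum())
    dual = (
        -0.5 * wsq
        - model.epsilon * float(np.abs(model.dual_coef).sum())
        + float(model.support_targets @ model.dual_coef)
    )
    return primal, dual


def grid_search_svr(X: np.ndarray, y: np.ndarray, grids: dict | None = None,
                    kernel: str = "gaussian", k_folds: int = 5, seed: int = 0
                    ) -> tuple[dict, list[dict]]:
    """Exhaustive cross-validated grid search over SVR hyperparameters.

    Parameters
    ----------
    grids : dict
        Lists of candidate values per parameter name (``C``, ``epsilon``,
        and ``gamma`` for the Gaussian kernel). Missing keys fall back to
        :data:`DEFAULT_SVR_GRID`; ``gamma`` is ignored for the linear kernel.

    Returns
    -------
    (best_params, table)
        ``best_params`` minimizes the mean CV MSE (ties break toward the
        earlier grid point); ``table`` lists every combination with its
        per-fold and mean MSE, for logging.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    merged = dict(DEFAULT_SVR_GRID)
    if grids:
        merged.update({k: list(v) for k, v in grids.items()})
    names = ["C", "epsilon"] + (["gamma"] if kernel == "gaussian" else [])
    for name in names:
        if not merged.get(name):
            raise ConfigError(f"grid for {name!r} is empty")
    folds = kfold_indices(X.shape[0], k_folds, seed)
    table: list[dict] = []
    best: dict | None = None
    best_mse = np.inf
    for values in itertools.product(*(merged[n] for n in names)):
        params = dict(zip(names, values))
        fold_mse = []
        for fold in folds:
            mask = np.ones(X.shape[0], dtype=bool)
            mask[fold] = False
            model = fit_svr(X[mask], y[mask], kernel=kernel, **params)
            resid = y[fold] - model.predict(X[fold])
            fold_mse.append(float(np.mean(resid ** 2)))
        mean_mse = float(np.mean(fold_mse))
        table.append({**params, "kernel": kernel,
                      "fold_mse": fold_mse, "mean_mse": mean_mse})
        if mean_mse < best_mse:
            best_mse = mean_mse
            best = params
    assert best is not None
    return {**best, "kernel": kernel}, table


def predict(model, X: np.ndarray) -> np.ndarray:
    """Shared prediction entry point for PLSR and SVR models."""
    if not hasattr(model, "predict"):
        raise ValidationError(f"object of type {type(model).__name__} is not a model")
    out = model.predict(X)
    if not np.all(np.isfinite(out)):
        raise ValidationError("model produced non-finite predictions")
    return out
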