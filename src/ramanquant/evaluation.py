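"""Regression evaluation statistics and model persistence.

The six statistics reported for every (observed, predicted) pair are

    SSE  = sum (y_i - yhat_i)^2
    MSE  = SSE / n
    RMSE = sqrt(MSE)
    MAE  = mean |y_i - yhat_i|
    R^2  = 1 - SSE / sum (y_i - ybar)^2      (can be negative)
    COR  = Pearson correlation of y and yhat (undefined if either is constant)

Model archives are single self-describing JSON files: a header (family tag,
format version, creation time) plus the numeric parameter payload and the
preprocessing provenance. No executable content is serialized, so archives
are safe to exchange; JSON float round-tripping is exact, so a reloaded
model predicts bit-identically.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .chemometrics import PLSRModel, SVRModel
from .exceptions import ArchiveError, ValidationError
from .neuralnets import CNNModel, CNNTrainSpec, MinMaxScaler, MLPModel, MLPTrainSpec
from .io import SpectralDataset
from .preprocess import PreprocessConfig

__all__ = [
    "EvaluationReport",
    "compute_metrics",
    "evaluate_model",
    "ModelArchive",
    "save_model",
    "load_model",
    "ARCHIVE_VERSION",
]

ARCHIVE_VERSION = 1


@dataclass
class EvaluationReport:
    """The six regression statistics for one (y, yhat) pair."""

    n: int
    sse: float
    mse: float
    rmse: float
    mae: float
    r2: float
    cor: float  # NaN when undefined (zero variance in either argument)
    partition: str = ""

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "SSE": self.sse,
            "MSE": self.mse,
            "RMSE": self.rmse,
            "MAE": self.mae,
            "R2": self.r2,
            "COR": None if np.isnan(self.cor) else self.cor,
            "partition": self.partition,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def format_table(self) -> str:
        """Aligned plain-text table, one row per statistic."""
        rows = [("n", f"{self.n:d}")]
        for name, value in (("SSE", self.sse), ("MSE", self.mse),
                            ("RMSE", self.rmse), ("MAE", self.mae),
                            ("R2", self.r2), ("COR", self.cor)):
            rows.append((name, "undefined" if np.isnan(value) else f"{value:.6g}"))
        width = max(len(r[0]) for r in rows)
        header = f"partition: {self.partition or '-'}"
        body = "\n".join(f"{name:<{width}}  {val}" for name, val in rows)
        return f"{header}\n{body}"


def compute_metrics(y: np.ndarray, yhat: np.ndarray,
                    partition: str = "") -> EvaluationReport:
    """Compute the six regression statistics for observed vs predicted values.

    ``COR`` is reported as NaN when either argument has zero variance
    (the Pearson coefficient is then undefined).
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.size != yhat.size:
        raise ValidationError(f"length mismatch: y has {y.size}, yhat has {yhat.size}")
    if y.size < 2:
        raise ValidationError(f"need at least 2 samples, got {y.size}")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(yhat))):
        raise ValidationError("y and yhat must be finite")
    n = y.size
    resid = y - yhat
    sse = float(np.sum(resid ** 2))
    mse = sse / n
    rmse = float(np.sqrt(mse))
    mae = float(np.mean(np.abs(resid)))
    ybar = float(np.mean(y))
    ss_tot = float(np.sum((y - ybar) ** 2))
    r2 = 1.0 - sse / ss_tot if ss_tot > 0 else (1.0 if sse == 0 else float("nan"))
    dy = y - ybar
    dyh = yhat - float(np.mean(yhat))
    denom = float(np.sqrt(np.sum(dy ** 2) * np.sum(dyh ** 2)))
    cor = float(np.sum(dy * dyh) / denom) if denom > 0 else float("nan")
    return EvaluationReport(n=n, sse=sse, mse=mse, rmse=rmse, mae=mae,
                            r2=r2, cor=cor, partition=partition)


def evaluate_model(model, ds: SpectralDataset, partition: str = "") -> EvaluationReport:
    """Predict on a dataset and compute the six statistics against its targets."""
    if ds.targets is None:
        raise ValidationError("dataset has no targets; cannot evaluate")
    yhat = model.predict(ds.to_rows())
    return compute_metrics(ds.targets, yhat, partition=partition)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def _enc(a: np.ndarray) -> dict:
    a = np.asarray(a, dtype=float)
    return {"shape": list(a.shape), "data": a.ravel().tolist()}


def _dec(d: dict) -> np.ndarray:
    return np.asarray(d["data"], dtype=float).reshape(d["shape"])


def _serialize_model(model) -> dict:
    if isinstance(model, PLSRModel):
        return {
            "n_components": model.n_components,
            "x_mean": _enc(model.x_mean), "y_mean": model.y_mean,
            "coef": _enc(model.coef), "weights": _enc(model.weights),
            "loadings": _enc(model.loadings), "y_loadings": _enc(model.y_loadings),
        }
    if isinstance(model, SVRModel):
        return {
            "kernel": model.kernel, "C": model.C, "epsilon": model.epsilon,
            "gamma": model.gamma, "intercept": model.intercept,
            "support_vectors": _enc(model.support_vectors),
            "dual_coef": _enc(model.dual_coef),
            "support_targets": _enc(model.support_targets),
            "x_mean": _enc(model.x_mean), "x_scale": _enc(model.x_scale),
        }
    if isinstance(model, MLPModel):
        return {
            "params": {k: _enc(v) for k, v in model.params.items()},
            "x_scaler": {"center": _enc(model.x_scaler.center),
                         "halfspan": _enc(model.x_scaler.halfspan)},
            "y_scaler": {"center": _enc(model.y_scaler.center),
                         "halfspan": _enc(model.y_scaler.halfspan)},
            "spec": vars(model.spec) if model.spec else None,
        }
    if isinstance(model, CNNModel):
        return {
            "blocks": [list(b) for b in model.blocks],
            "input_length": model.input_length,
            "dense_units": model.dense_units,
            "params": {k: _enc(v) for k, v in model.params.items()},
            "x_scaler": {"center": _enc(model.x_scaler.center),
                         "halfspan": _enc(model.x_scaler.halfspan)},
            "y_scaler": {"center": _enc(model.y_scaler.center),
                         "halfspan": _enc(model.y_scaler.halfspan)},
            "spec": vars(model.spec) if model.spec else None,
        }
    raise ArchiveError(f"cannot serialize model of type {type(model).__name__}")


def _deserialize_model(family: str, payload: dict):
    if family == "plsr":
        return PLSRModel(
            n_components=int(payload["n_components"]),
            x_mean=_dec(payload["x_mean"]), y_mean=float(payload["y_mean"]),
            coef=_dec(payload["coef"]), weights=_dec(payload["weights"]),
            loadings=_dec(payload["loadings"]),
            y_loadings=_dec(payload["y_loadings"]),
        )
    if family == "svr":
        return SVRModel(
            kernel=payload["kernel"], C=float(payload["C"]),
            epsilon=float(payload["epsilon"]),
            gamma=None if payload["gamma"] is None else float(payload["gamma"]),
            support_vectors=_dec(payload["support_vectors"]),
            dual_coef=_dec(payload["dual_coef"]),
            intercept=float(payload["intercept"]),
            x_mean=_dec(payload["x_mean"]), x_scale=_dec(payload["x_scale"]),
            support_targets=_dec(payload["support_targets"]),
        )
    if family == "mlp":
        spec = MLPTrainSpec(**payload["spec"]) if payload.get("spec") else None
        return MLPModel(
            params={k: _dec(v) for k, v in payload["params"].items()},
            x_scaler=MinMaxScaler(center=_dec(payload["x_scaler"]["center"]),
                                  halfspan=_dec(payload["x_scaler"]["halfspan"])),
            y_scaler=MinMaxScaler(center=_dec(payload["y_scaler"]["center"]),
                                  halfspan=_dec(payload["y_scaler"]["halfspan"])),
            spec=spec,
        )
    if family == "cnn":
        spec = CNNTrainSpec(**payload["spec"]) if payload.get("spec") else None
        return CNNModel(
            blocks=tuple(tuple(b) for b in payload["blocks"]),
            input_length=int(payload["input_length"]),
            dense_units=int(payload["dense_units"]),
            params={k: _dec(v) for k, v in payload["params"].items()},
            x_scaler=MinMaxScaler(center=_dec(payload["x_scaler"]["center"]),
                                  halfspan=_dec(payload["x_scaler"]["halfspan"])),
            y_scaler=MinMaxScaler(center=_dec(payload["y_scaler"]["center"]),
                                  halfspan=_dec(payload["y_scaler"]["halfspan"])),
            spec=spec,
        )
    raise ArchiveError(f"unknown model family tag {family!r}")


@dataclass
class ModelArchive:
    """A loaded model archive: the model plus its provenance."""

    family: str
    model: object
    preprocess: PreprocessConfig | None
    preprocess_state: dict
    wavenumbers: np.ndarray | None
    unit: str
    created: str
    version: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(X)


def save_model(model, path, preprocess: PreprocessConfig | None = None,
               preprocess_state: dict | None = None,
               wavenumbers: np.ndarray | None = None,
               unit: str = "mmol/L") -> None:
    """Write a fitted model (and its preprocessing provenance) to a JSON archive."""
    family = getattr(model, "family", None)
    if family not in ("plsr", "svr", "mlp", "cnn"):
        raise ArchiveError(f"cannot archive object of type {type(model).__name__}")
    doc = {
        "format": "ramanquant-model",
        "version": ARCHIVE_VERSION,
        "family": family,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "unit": unit,
        "preprocess": preprocess.to_dict() if preprocess is not None else None,
        "preprocess_state": preprocess_state or {},
        "wavenumbers": None if wavenumbers is None
        else np.asarray(wavenumbers, dtype=float).tolist(),
        "payload": _serialize_model(model),
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True), encoding="utf-8")


def load_model(path) -> ModelArchive:
    """Load a model archive; raises :class:`ArchiveError` on any defect."""
    path = Path(path)
    if not path.exists():
        raise ArchiveError(f"archive {path} does not exist")
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ArchiveError(f"archive {path} is corrupted: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != "ramanquant-model":
        raise ArchiveError(f"{path} is not a ramanquant model archive")
    version = doc.get("version")
    if version != ARCHIVE_VERSION:
        raise ArchiveError(
            f"archive version {version} is not supported (expected {ARCHIVE_VERSION})"
        )
    family = doc.get("family")
    try:
        model = _deserialize_model(family, doc["payload"])
    except (KeyError, TypeError) as exc:
        raise ArchiveError(f"archive {path} payload is incomplete: {exc}") from exc
    cfg = None
    if doc.get("preprocess") is not None:
        cfg = PreprocessConfig.from_dict(doc["preprocess"])
    return ModelArchive(
        family=family,
        model=model,
        preprocess=cfg,
        preprocess_state=doc.get("preprocess_state", {}),
        wavenumbers=None if doc.get("wavenumbers") is None
        else np.asarray(doc["wavenumbers"], dtype=float),
        unit=doc.get("unit", "mmol/L"),
        created=doc.get("created", ""),
        version=version,
    )
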