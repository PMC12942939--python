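"""High-level modelling interface.

:class:`RamanRegression` bundles a spectral dataset with a preprocessing
configuration, a partitioning protocol, optional augmentation and a model
family; :meth:`RamanRegression.fit` executes the whole calibration workflow
(split, preprocess, augment, train, evaluate) and returns a
:class:`RamanRegressionResults` carrying the fitted model, the per-partition
evaluation reports, a text ``summary()``, prediction on new raw spectra, and
persistence with full preprocessing provenance.

The default protocol: hold out 10 spectra as the prediction set, split the
remainder 80/20 into training and test sets, preprocess with the standard
chain, and select model hyperparameters by cross-validation where the
family calls for it (PLSR latent variables, SVR grid search).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from . import chemometrics, neuralnets
from .datasets import AugmentSpec, SplitSpec, augment_std_shift, split
from .evaluation import EvaluationReport, ModelArchive, evaluate_model, save_model
from .exceptions import CompatibilityError, ConfigError, ValidationError
from .io import SpectralDataset, read_matrix_container
from .preprocess import PreprocessConfig, PreprocessReport, run_chain

__all__ = ["RamanRegression", "RamanRegressionResults", "predict_with_archive",
           "MODEL_FAMILIES"]

MODEL_FAMILIES = ("plsr", "svr", "mlp", "cnn")


def _child_seed(seed: int, stream: int) -> int:
    """Deterministic per-stage seed derived from the global seed (< 2^31)."""
    return int(np.random.SeedSequence([int(seed), int(stream)]).generate_state(1)[0]
               % (2 ** 31))


class RamanRegression:
    """A quantitative Raman regression task: data + configuration.

    Parameters
    ----------
    dataset : SpectralDataset
        Raw spectra with regression targets.
    family : {"plsr", "svr", "mlp", "cnn"}
        Model family to fit. Exactly one per task.
    preprocess : PreprocessConfig, optional
        Defaults to the standard chain (median despike, polynomial baseline,
        Savitzky-Golay smoothing, area normalization).
    split : SplitSpec, optional
        Defaults to the study protocol: 10 prediction spectra, 80/20
        train/test on the remainder.
    augment : AugmentSpec, optional
        Applied to the training partition only (after splitting), to avoid
        information leaking from test or prediction spectra into the
        augmentation statistics. ``None`` disables augmentation.
    hyperparams : dict, optional
        Family-specific settings (e.g. ``{"n_components": 5}`` for PLSR,
        ``{"kernel": "linear", "C": 10}`` or ``{"grid": {...}}`` for SVR,
        training-spec fields for the neural families).
    seed : int
        Global seed; per-stage seeds are derived from it deterministically.
    """

    def __init__(self, dataset: SpectralDataset, family: str = "plsr",
                 preprocess: PreprocessConfig | None = None,
                 split: SplitSpec | None = None,
                 augment: AugmentSpec | None = None,
                 hyperparams: dict | None = None,
                 seed: int = 0):
        if family not in MODEL_FAMILIES:
            raise ConfigError(
                f"family must be one of {MODEL_FAMILIES}, got {family!r}"
            )
        if dataset.targets is None:
            raise ValidationError("model fitting requires a dataset with targets")
        self.dataset = dataset
        self.family = family
        self.preprocess = preprocess if preprocess is not None else PreprocessConfig()
        self.preprocess.validate()
        self.split_spec = split if split is not None else SplitSpec(seed=_child_seed(seed, 0))
        self.augment_spec = augment
        self.hyperparams = dict(hyperparams or {})
        self.seed = int(seed)

    @classmethod
    def from_container(cls, path, **kwargs) -> "RamanRegression":
        """Build a task from an HDF5 matrix container on disk."""
        return cls(read_matrix_container(path), **kwargs)

    # ------------------------------------------------------------------
    def fit(self, progress_callback=None) -> "RamanRegressionResults":
        """Run the full calibration workflow and return the results."""
        ds = self.dataset
        train_raw, test_raw, pred_raw = split(ds, self.split_spec)

        train_pp, report = run_chain(train_raw, self.preprocess)
        emsc_ref = None
        for stage in report.stages:
            if stage["stage"] == "baseline_emsc":
                emsc_ref = np.asarray(stage["reference"], dtype=float)
        test_pp, _ = run_chain(test_raw, self.preprocess, emsc_reference=emsc_ref)
        pred_pp, _ = run_chain(pred_raw, self.preprocess, emsc_reference=emsc_ref)

        train_fit = train_pp
        if self.augment_spec is not None:
            train_fit = augment_std_shift(train_pp, self.augment_spec)

        model, selection = self._fit_family(train_fit, progress_callback)

        reports = {
            "train": evaluate_model(model, train_pp, partition="train"),
            "test": evaluate_model(model, test_pp, partition="test"),
            "prediction": evaluate_model(model, pred_pp, partition="prediction"),
        }
        state = {"train_grid": train_pp.wavenumbers.tolist()}
        if emsc_ref is not None:
            state["emsc_reference"] = emsc_ref.tolist()
        return RamanRegressionResults(
            task=self, model=model, reports=reports, selection=selection,
            preprocess_report=report, preprocess_state=state,
            partitions={"train": train_pp, "test": test_pp, "prediction": pred_pp,
                        "train_augmented": train_fit},
        )

    # ------------------------------------------------------------------
    def _fit_family(self, train: SpectralDataset, progress_callback):
        X = train.to_rows()
        y = train.targets
        hp = dict(self.hyperparams)
        if self.family == "plsr":
            n_comp = hp.pop("n_components", None)
            k_folds = hp.pop("k_folds", 5)
            max_comp = hp.pop("max_components", None)
            selection: dict[str, Any] = {}
            if n_comp is None:
                n_comp, curve = chemometrics.select_plsr_components(
                    X, y, k_folds=k_folds, max_components=max_comp,
                    seed=_child_seed(self.seed, 1))
                selection = {"cv_mse": curve.tolist(), "selected": n_comp}
            model = chemometrics.fit_plsr(X, y, n_comp)
            return model, selection
        if self.family == "svr":
            kernel = hp.pop("kernel", "gaussian")
            grid = hp.pop("grid", None)
            k_folds = hp.pop("k_folds", 5)
            if grid is not None or not {"C", "epsilon"} <= set(hp):
                best, table = chemometrics.grid_search_svr(
                    X, y, grids=grid, kernel=kernel, k_folds=k_folds,
                    seed=_child_seed(self.seed, 2))
                params = {k: v for k, v in best.items() if k != "kernel"}
                params.update(hp)  # explicit values win over searched ones
                model = chemometrics.fit_svr(X, y, kernel=kernel, **params)
                return model, {"best": best, "cv_table": table}
            model = chemometrics.fit_svr(X, y, kernel=kernel, **hp)
            return model, {}
        if self.family == "mlp":
            hp.setdefault("seed", _child_seed(self.seed, 3))
            spec = neuralnets.MLPTrainSpec(**hp)
            model = neuralnets.fit_mlp(train, spec)
            return model, {"epochs_run": len(model.training_log),
                           "stopped_early": model.stopped_early}
        # cnn
        blocks = hp.pop("blocks", None)
        dense_units = hp.pop("dense_units", 32)
        hp.setdefault("seed", _child_seed(self.seed, 4))
        spec = neuralnets.CNNTrainSpec(**hp)
        model = neuralnets.fit_cnn(train, spec, progress_callback=progress_callback,
                                   blocks_config=blocks, dense_units=dense_units)
        return model, {"steps_run": len(model.training_log)}


@dataclass
class RamanRegressionResults:
    """Results of a fitted :class:`RamanRegression` task."""

    task: RamanRegression
    model: object
    reports: dict[str, EvaluationReport]
    selection: dict
    preprocess_report: PreprocessReport
    preprocess_state: dict
    partitions: dict[str, SpectralDataset] = field(default_factory=dict)

    @property
    def family(self) -> str:
        return self.task.family

    def predict(self, dataset: SpectralDataset, preprocessed: bool = False
                ) -> np.ndarray:
        """Predict targets for new raw spectra (the chain is applied first).

        Pass ``preprocessed=True`` if the data has already been run through
        the identical chain.
        """
        if preprocessed:
            ds_pp = dataset
        else:
            ref = self.preprocess_state.get("emsc_reference")
            ds_pp, _ = run_chain(dataset, self.task.preprocess,
                                 emsc_reference=None if ref is None
                                 else np.asarray(ref, dtype=float))
        grid = np.asarray(self.preprocess_state["train_grid"])
        if ds_pp.n_points != grid.size or not np.allclose(
                ds_pp.wavenumbers, grid, rtol=0, atol=1e-9):
            raise CompatibilityError(
                "input grid after preprocessing does not match the grid the "
                "model was trained on"
            )
        return self.model.predict(ds_pp.to_rows())

    def save(self, path) -> None:
        """Archive the model with its preprocessing provenance."""
        save_model(self.model, path, preprocess=self.task.preprocess,
                   preprocess_state=self.preprocess_state,
                   wavenumbers=np.asarray(self.preprocess_state["train_grid"]),
                   unit=self.task.dataset.unit)

    def summary(self) -> str:
        """Human-readable summary: task setup plus the evaluation tables."""
        lines = []
        lines.append("Raman quantitative regression results")
        lines.append("=" * 54)
        lines.append(f"model family:     {self.family}")
        ds = self.task.dataset
        lines.append(f"dataset:          N={ds.n_spectra} spectra, M={ds.n_points} points")
        lines.append(f"target unit:      {ds.unit}")
        sizes = {k: v.n_spectra for k, v in self.partitions.items() if k != "train_augmented"}
        lines.append(f"partitions:       {sizes}")
        if "train_augmented" in self.partitions:
            aug = self.partitions["train_augmented"].n_spectra
            if aug != sizes.get("train"):
                lines.append(f"augmented train:  {aug}")
        if self.selection.get("selected"):
            lines.append(f"latent variables: {self.selection['selected']} (CV-selected)")
        if self.selection.get("best"):
            lines.append(f"svr parameters:   {self.selection['best']} (grid search)")
        lines.append("-" * 54)
        header = f"{'':<12}" + "".join(f"{p:>13}" for p in ("train", "test", "prediction"))
        lines.append(header)
        metric_names = ["n", "SSE", "MSE", "RMSE", "MAE", "R2", "COR"]
        for name in metric_names:
            row = f"{name:<12}"
            for part in ("train", "test", "prediction"):
                rep = self.reports[part].to_dict()
                val = rep[name]
                if val is None:
                    row += f"{'undef':>13}"
                elif name == "n":
                    row += f"{val:>13d}"
                else:
                    row += f"{val:>13.4f}"
            lines.append(row)
        lines.append("=" * 54)
        return "\n".join(lines)

    def plot_predictions(self, partition: str = "test", ax=None):
        """Scatter observed vs predicted with the identity line."""
        import matplotlib.pyplot as plt

        if partition not in self.partitions:
            raise ConfigError(f"unknown partition {partition!r}")
        ds = self.partitions[partition]
        yhat = self.model.predict(ds.to_rows())
        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.scatter(ds.targets, yhat, s=18, alpha=0.8)
        lo = min(ds.targets.min(), yhat.min())
        hi = max(ds.targets.max(), yhat.max())
        ax.plot([lo, hi], [lo, hi], "k--", lw=1)
        ax.set_xlabel(f"observed ({ds.unit})")
        ax.set_ylabel(f"predicted ({ds.unit})")
        ax.set_title(f"{self.family.upper()} — {partition} set")
        return ax


def predict_with_archive(archive: ModelArchive, dataset: SpectralDataset,
                         preprocessed: bool = False) -> np.ndarray:
    """Predict with a loaded archive, applying its archived preprocessing.

    Raises :class:`CompatibilityError` if the (preprocessed) input grid does
    not match the grid the archived model was trained on.
    """
    if preprocessed or archive.preprocess is None:
        ds_pp = dataset
    else:
        ref = archive.preprocess_state.get("emsc_reference")
        ds_pp, _ = run_chain(dataset, archive.preprocess,
                             emsc_reference=None if ref is None
                             else np.asarray(ref, dtype=float))
    if archive.wavenumbers is not None:
        if ds_pp.n_points != archive.wavenumbers.size or not np.allclose(
                ds_pp.wavenumbers, archive.wavenumbers, rtol=0, atol=1e-9):
            raise CompatibilityError(
                "input grid after preprocessing does not match the grid the "
                "archived model was trained on"
            )
    return archive.model.predict(ds_pp.to_rows())
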