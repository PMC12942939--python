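"""Partitioning and data augmentation.

The study protocol holds out a fixed-size *prediction* set (never touched
during training or model selection), then splits the remainder 80/20 into
training and test sets.  Small training sets are enlarged by the
standard-deviation-shift scheme: synthetic copies of each spectrum displaced
by multiples of the per-wavenumber standard deviation across the set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError
from .io import SpectralDataset

__all__ = ["SplitSpec", "AugmentSpec", "split", "augment_std_shift", "kfold_indices"]


@dataclass
class SplitSpec:
    """Prediction-set size, training fraction of the remainder, and seed."""

    n_prediction: int = 10
    train_fraction: float = 0.8
    seed: int = 0

    def validate(self, n: int) -> None:
        if not 0 < self.train_fraction < 1:
            raise ConfigError(f"train_fraction must lie in (0, 1), got {self.train_fraction}")
        if not 0 < self.n_prediction < n:
            raise ConfigError(
                f"n_prediction must lie in (0, N); got {self.n_prediction} with N={n}"
            )


@dataclass
class AugmentSpec:
    """Augmentation factor and shift scale.

    ``factor`` is the output-to-input size ratio (the protocol value is 4).
    In ``deterministic`` mode copy ``k`` of each spectrum is shifted by the
    cycling coefficients ``+s, -s, +2s, -2s, ...`` times the per-wavenumber
    standard deviation; in ``stochastic`` mode each copy adds
    ``s * eps * sigma`` with i.i.d. standard-normal ``eps`` per wavenumber.
    """

    factor: int = 4
    shift_scale: float = 0.5
    mode: str = "deterministic"
    seed: int = 0

    def validate(self) -> None:
        if int(self.factor) < 1:
            raise ConfigError(f"augmentation factor must be >= 1, got {self.factor}")
        if not self.shift_scale > 0:
            raise ConfigError(f"shift_scale must be > 0, got {self.shift_scale}")
        if self.mode not in ("deterministic", "stochastic"):
            raise ConfigError(f"unknown augmentation mode {self.mode!r}")


def split_indices(n: int, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seed-reproducible (train, test, prediction) index partition of ``range(n)``.

    ``|prediction| = n_prediction``; ``|train|`` is ``train_fraction`` of the
    remainder rounded to nearest (ties to even); the rest is the test set.
    Indices within each partition are returned sorted, so each partition
    preserves the original column order.
    """
    spec.validate(n)
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    pred = perm[: spec.n_prediction]
    rest = perm[spec.n_prediction:]
    n_train = round(spec.train_fraction * rest.size)
    if n_train < 1 or rest.size - n_train < 1:
        raise ConfigError(
            f"split of N={n} leaves an empty partition "
            f"(train={n_train}, test={rest.size - n_train}, prediction={pred.size})"
        )
    train = rest[:n_train]
    test = rest[n_train:]
    return np.sort(train), np.sort(test), np.sort(pred)


def split(ds: SpectralDataset, spec: SplitSpec
          ) -> tuple[SpectralDataset, SpectralDataset, SpectralDataset]:
    """Partition a dataset into disjoint (train, test, prediction) sets."""
    train, test, pred = split_indices(ds.n_spectra, spec)
    return ds.select(train), ds.select(test), ds.select(pred)


def _deterministic_coefficients(n_copies: int, s: float) -> np.ndarray:
    """The cycling shift coefficients +s, -s, +2s, -2s, ... (length n_copies)."""
    out = np.empty(n_copies)
    for k in range(n_copies):
        magnitude = (k // 2 + 1) * s
        out[k] = magnitude if k % 2 == 0 else -magnitude
    return out


def augment_std_shift(train: SpectralDataset, spec: AugmentSpec) -> SpectralDataset:
    """Enlarge a training set to ``factor`` times its size by sigma-shifted copies.

    The per-wavenumber standard deviation ``sigma(w)`` is computed across the
    input spectra; the output holds the originals followed by ``factor - 1``
    blocks of shifted copies, each copy inheriting the target value of its
    source spectrum.
    """
    spec.validate()
    if train.n_spectra < 2:
        raise ConfigError(
            "augmentation needs at least 2 spectra to define the per-wavenumber "
            f"standard deviation; got {train.n_spectra}"
        )
    factor = int(spec.factor)
    if factor == 1:
        return train.copy()
    sigma = train.intensities.std(axis=1, ddof=0)
    n_copies = factor - 1
    blocks = [train.intensities]
    ids = list(train.ids)
    if spec.mode == "deterministic":
        coeffs = _deterministic_coefficients(n_copies, spec.shift_scale)
        for k in range(n_copies):
            blocks.append(train.intensities + coeffs[k] * sigma[:, np.newaxis])
            ids.extend(f"{i}+aug{k + 1}" for i in train.ids)
    else:
        rng = np.random.default_rng(spec.seed)
        for k in range(n_copies):
            eps = rng.standard_normal((train.n_points, train.n_spectra))
            blocks.append(train.intensities + spec.shift_scale * eps * sigma[:, np.newaxis])
            ids.extend(f"{i}+aug{k + 1}" for i in train.ids)
    intensities = np.concatenate(blocks, axis=1)
    targets = None if train.targets is None else np.tile(train.targets, factor)
    return SpectralDataset(
        wavenumbers=train.wavenumbers.copy(),
        intensities=intensities,
        targets=targets,
        ids=ids,
        unit=train.unit,
    )


def kfold_indices(n: int, k: int, seed: int) -> list[np.ndarray]:
    """Seeded shuffled contiguous-block k-fold partition of ``range(n)``.

    Shared fold engine for PLSR latent-variable selection and SVR grid
    search, so both model families see identical folds for a given seed.
    """
    if k < 2:
        raise ConfigError(f"k_folds must be >= 2, got {k}")
    if n < k:
        raise ConfigError(f"cannot make {k} folds from {n} samples")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [fold for fold in np.array_split(perm, k)]
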