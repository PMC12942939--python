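"""Reading and writing Raman spectral data.

Two on-disk layouts are supported, mirroring common spectrometer exports:

* **Two-column text files** — one spectrum per file, columns
  ``(wavenumber, intensity)``, whitespace- or comma-delimited, ``#`` comments
  ignored.  A batch of such files plus a one-value-per-line targets file
  assembles into a :class:`SpectralDataset`.
* **A matrix container** — a single HDF5 file holding the intensity matrix
  ``M x N`` (one column per spectrum), the shared wavenumber vector
  (length ``M``) and the regression targets (length ``N``).

``M`` is the number of spectral channels, ``N`` the number of spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np

from .exceptions import GridMismatchError, ParseError, ValidationError

__all__ = [
    "Spectrum",
    "SpectralDataset",
    "read_text_spectrum",
    "read_targets",
    "read_batch",
    "read_matrix_container",
    "write_matrix_container",
    "mgdl_to_mmoll",
    "mmoll_to_mgdl",
    "MGDL_PER_MMOLL",
]

#: Glucose molar mass is 180.16 g/mol, so 1 mmol/L = 18.016 mg/dL.
MGDL_PER_MMOLL = 18.016

CONTAINER_VERSION = 1


def mgdl_to_mmoll(values):
    """Convert glucose concentrations from mg/dL to mmol/L."""
    return np.asarray(values, dtype=float) / MGDL_PER_MMOLL


def mmoll_to_mgdl(values):
    """Convert glucose concentrations from mmol/L to mg/dL."""
    return np.asarray(values, dtype=float) * MGDL_PER_MMOLL


def _check_grid(wavenumbers: np.ndarray, what: str = "wavenumbers") -> None:
    if wavenumbers.ndim != 1:
        raise ValidationError(f"{what} must be one-dimensional")
    if not np.all(np.isfinite(wavenumbers)):
        raise ValidationError(f"{what} contain non-finite values")
    if wavenumbers.size >= 2 and not np.all(np.diff(wavenumbers) > 0):
        raise ValidationError(f"{what} must be strictly increasing")


@dataclass
class Spectrum:
    """A single Raman spectrum: intensity versus Raman shift.

    Wavenumbers are in cm^-1 and strictly increasing; intensities are in
    arbitrary detector units. Construction validates the invariants, so an
    invalid ``Spectrum`` never exists.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    id: str = ""

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.shape != self.intensities.shape:
            raise ValidationError(
                f"spectrum {self.id!r}: wavenumber and intensity lengths differ "
                f"({self.wavenumbers.size} vs {self.intensities.size})"
            )
        _check_grid(self.wavenumbers, f"spectrum {self.id!r}: wavenumbers")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError(f"spectrum {self.id!r}: non-finite intensities")

    def __len__(self) -> int:
        return self.wavenumbers.size


@dataclass
class SpectralDataset:
    """A set of spectra on a shared wavenumber grid, with regression targets.

    Attributes
    ----------
    wavenumbers : ndarray, shape (M,)
        Shared Raman-shift grid in cm^-1, strictly increasing.
    intensities : ndarray, shape (M, N)
        One column per spectrum, arbitrary units.
    targets : ndarray, shape (N,), or None
        Regression values (e.g. glucose concentration). ``None`` for
        prediction-only data that carries no reference values.
    ids : list of str
        One label per spectrum.
    unit : str
        Declared unit of the targets (e.g. ``"mmol/L"`` or ``"mg/dL"``).
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    targets: np.ndarray | None = None
    ids: list[str] = field(default_factory=list)
    unit: str = "mmol/L"

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValidationError("intensities must be a 2-D (M x N) matrix")
        m, n = self.intensities.shape
        if m == 0 or n == 0:
            raise ValidationError("dataset must contain at least one point and one spectrum")
        _check_grid(self.wavenumbers)
        if self.wavenumbers.size != m:
            raise ValidationError(
                f"wavenumber length {self.wavenumbers.size} does not match "
                f"intensity row count {m}"
            )
        if self.targets is not None:
            self.targets = np.asarray(self.targets, dtype=float)
            if self.targets.ndim != 1 or self.targets.size != n:
                raise ValidationError(
                    f"target count {self.targets.size} does not match spectrum count {n}"
                )
            if not np.all(np.isfinite(self.targets)):
                raise ValidationError("targets contain non-finite values")
        if not self.ids:
            self.ids = [f"s{i}" for i in range(n)]
        self.ids = [str(i) for i in self.ids]
        if len(self.ids) != n:
            raise ValidationError(f"id count {len(self.ids)} does not match spectrum count {n}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValidationError("intensities contain non-finite values")

    # -- basic accessors -------------------------------------------------
    @property
    def n_points(self) -> int:
        """M, the number of wavenumber channels."""
        return self.intensities.shape[0]

    @property
    def n_spectra(self) -> int:
        """N, the number of spectra."""
        return self.intensities.shape[1]

    def to_rows(self) -> np.ndarray:
        """Return the data as an (N, M) design matrix (one spectrum per row)."""
        return self.intensities.T.copy()

    def select(self, indices: Sequence[int]) -> "SpectralDataset":
        """Return the sub-dataset holding the given spectrum columns (in order)."""
        idx = np.asarray(indices, dtype=int)
        return SpectralDataset(
            wavenumbers=self.wavenumbers.copy(),
            intensities=self.intensities[:, idx].copy(),
            targets=None if self.targets is None else self.targets[idx].copy(),
            ids=[self.ids[i] for i in idx],
            unit=self.unit,
        )

    def with_intensities(self, intensities: np.ndarray,
                         wavenumbers: np.ndarray | None = None) -> "SpectralDataset":
        """Copy of this dataset with replaced intensity matrix (and optionally grid)."""
        return SpectralDataset(
            wavenumbers=self.wavenumbers.copy() if wavenumbers is None else wavenumbers,
            intensities=intensities,
            targets=None if self.targets is None else self.targets.copy(),
            ids=list(self.ids),
            unit=self.unit,
        )

    def copy(self) -> "SpectralDataset":
        return self.with_intensities(self.intensities.copy())

    def convert_targets(self, to_unit: str) -> "SpectralDataset":
        """Convert glucose targets between mg/dL and mmol/L (factor 18.016)."""
        if self.targets is None:
            raise ValidationError("dataset has no targets to convert")
        key = (self.unit.lower(), to_unit.lower())
        if key[0] == key[1]:
            return self.copy()
        if key == ("mg/dl", "mmol/l"):
            new = mgdl_to_mmoll(self.targets)
        elif key == ("mmol/l", "mg/dl"):
            new = mmoll_to_mgdl(self.targets)
        else:
            raise ValidationError(f"unsupported unit conversion {self.unit!r} -> {to_unit!r}")
        out = self.copy()
        out.targets = new
        out.unit = to_unit
        return out

    def equals(self, other: "SpectralDataset") -> bool:
        """Exact numeric and label equality."""
        if self.targets is None != (other.targets is None):
            return False
        tgt_ok = (self.targets is None and other.targets is None) or np.array_equal(
            self.targets, other.targets
        )
        return (
            np.array_equal(self.wavenumbers, other.wavenumbers)
            and np.array_equal(self.intensities, other.intensities)
            and tgt_ok
            and self.ids == other.ids
            and self.unit == other.unit
        )


# ---------------------------------------------------------------------------
# Two-column text spectra
# ---------------------------------------------------------------------------

def _parse_numeric_lines(path: Path, min_columns: int = 1):
    """Yield (line_number, [floats]) for every non-comment, non-blank line."""
    rows = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.replace(",", " ").split()
            if len(tokens) < min_columns:
                raise ParseError(f"{path}: line {lineno}: expected at least "
                                 f"{min_columns} columns, found {len(tokens)}")
            try:
                values = [float(t) for t in tokens]
            except ValueError:
                raise ParseError(f"{path}: line {lineno}: non-numeric value in {line!r}")
            rows.append((lineno, values))
    return rows


def _is_monotone(x: np.ndarray) -> bool:
    d = np.diff(x)
    return bool(np.all(d > 0) or np.all(d < 0))


def read_text_spectrum(path, columns: tuple[int, int] | None = None) -> Spectrum:
    """Read a two-column text spectrum.

    Parameters
    ----------
    path : path-like
        File with at least two numeric columns. Lines starting with ``#``
        are ignored; fields may be separated by whitespace or commas.
    columns : (int, int), optional
        Explicit ``(wavenumber_column, intensity_column)`` indices. When
        absent the first column is assumed to be the wavenumber, unless the
        second column is the only monotone one, in which case the columns
        are swapped (covers exports that print intensity first).

    Returns
    -------
    Spectrum
        Sorted by ascending wavenumber; ``id`` is the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    need = 2 if columns is None else max(columns) + 1
    rows = _parse_numeric_lines(path, min_columns=need)
    if len(rows) < 3:
        raise ValidationError(f"{path}: a spectrum needs at least 3 rows, found {len(rows)}")
    data = np.array([vals[:need] for _, vals in rows], dtype=float)
    if columns is None:
        col_w, col_i = 0, 1
        c0, c1 = data[:, 0], data[:, 1]
        if not _is_monotone(c0) and _is_monotone(c1):
            col_w, col_i = 1, 0
    else:
        col_w, col_i = columns
    w = data[:, col_w]
    y = data[:, col_i]
    order = np.argsort(w, kind="stable")
    w, y = w[order], y[order]
    if np.any(np.diff(w) <= 0):
        dup = w[np.where(np.diff(w) <= 0)[0][0]]
        raise ValidationError(f"{path}: duplicate or non-increasing wavenumber near {dup}")
    return Spectrum(wavenumbers=w, intensities=y, id=path.stem)


def read_targets(path) -> np.ndarray:
    """Read a one-value-per-line targets file (``#`` comments allowed)."""
    rows = _parse_numeric_lines(Path(path), min_columns=1)
    return np.array([vals[0] for _, vals in rows], dtype=float)


def read_batch(paths: Sequence, targets_path, unit: str = "mmol/L",
               columns: tuple[int, int] | None = None) -> SpectralDataset:
    """Assemble a dataset from per-spectrum text files plus a targets file.

    All files must share an identical wavenumber grid; the targets file
    supplies one regression value per spectrum, in path order.
    """
    if not paths:
        raise ValidationError("read_batch requires at least one spectrum file")
    spectra = [read_text_spectrum(p, columns=columns) for p in paths]
    grid = spectra[0].wavenumbers
    for sp, p in zip(spectra, paths):
        if not np.array_equal(sp.wavenumbers, grid):
            raise GridMismatchError(
                f"wavenumber grid of {p} does not match the grid of {paths[0]}"
            )
    targets = read_targets(targets_path)
    if targets.size != len(spectra):
        raise ValidationError(
            f"targets file has {targets.size} values for {len(spectra)} spectra"
        )
    intensities = np.column_stack([sp.intensities for sp in spectra])
    return SpectralDataset(
        wavenumbers=grid.copy(),
        intensities=intensities,
        targets=targets,
        ids=[sp.id for sp in spectra],
        unit=unit,
    )


# ---------------------------------------------------------------------------
# HDF5 matrix container
# ---------------------------------------------------------------------------

def read_matrix_container(path) -> SpectralDataset:
    """Read a dataset from the HDF5 matrix container.

    The container must hold datasets ``wavenumbers`` (M,), ``intensities``
    (M x N) and — unless written from a target-free dataset — ``targets``
    (N,). A missing required array raises :class:`KeyError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        for name in ("wavenumbers", "intensities"):
            if name not in f:
                raise KeyError(f"container {path} is missing array {name!r}")
        has_targets = bool(f.attrs.get("has_targets", "targets" in f))
        if has_targets and "targets" not in f:
            raise KeyError(f"container {path} is missing array 'targets'")
        wavenumbers = f["wavenumbers"][()]
        intensities = f["intensities"][()]
        targets = f["targets"][()] if has_targets else None
        ids = [s.decode() if isinstance(s, bytes) else str(s) for s in f["ids"][()]] \
            if "ids" in f else []
        unit = f.attrs.get("unit", "mmol/L")
        if isinstance(unit, bytes):
            unit = unit.decode()
    return SpectralDataset(wavenumbers=wavenumbers, intensities=intensities,
                           targets=targets, ids=ids, unit=str(unit))


def write_matrix_container(ds: SpectralDataset, path) -> None:
    """Write a dataset to the HDF5 matrix container (bit-exact round trip)."""
    if ds.n_spectra == 0:
        raise ValidationError("refusing to write an empty dataset")
    path = Path(path)
    try:
        with h5py.File(path, "w") as f:
            f.attrs["format"] = "ramanquant-container"
            f.attrs["version"] = CONTAINER_VERSION
            f.attrs["unit"] = ds.unit
            f.attrs["has_targets"] = ds.targets is not None
            f.create_dataset("wavenumbers", data=ds.wavenumbers.astype(np.float64))
            f.create_dataset("intensities", data=ds.intensities.astype(np.float64))
            if ds.targets is not None:
                f.create_dataset("targets", data=ds.targets.astype(np.float64))
            f.create_dataset("ids", data=np.array(ds.ids, dtype=h5py.string_dtype()))
    except OSError as exc:
        raise OSError(f"cannot write container to {path}: {exc}") from exc
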