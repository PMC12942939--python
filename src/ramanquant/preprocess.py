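"""The spectral preprocessing chain.

Raw in vivo Raman spectra are dominated by a broad fluorescence background
and contaminated by cosmic-ray spikes and detector noise.  The chain applied
here, in fixed order, is

    crop -> interpolate (optional) -> median despike -> baseline correction
         -> Savitzky-Golay smoothing -> area normalization (optional)

Baseline correction is either iterative polynomial fitting (ModPoly-style
"clip to fit") or extended multiplicative signal correction (EMSC), which
models each spectrum as a multiplicative scaling of a reference plus
additive polynomial terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter

from .exceptions import (
    ConfigError,
    DegenerateFitError,
    NormalizationError,
    RangeError,
    ValidationError,
)
from .io import SpectralDataset, Spectrum

__all__ = [
    "PreprocessConfig",
    "PreprocessReport",
    "crop",
    "interpolate_to_grid",
    "despike_median",
    "baseline_polynomial",
    "baseline_polynomial_dataset",
    "baseline_emsc",
    "smooth_savitzky_golay",
    "normalize_area",
    "run_chain",
]


@dataclass
class PreprocessConfig:
    """Ordered parameters of the preprocessing chain.

    Set a stage's parameter to ``None`` (or ``baseline_method="none"``,
    ``normalize=False``) to skip that stage; a config with every stage
    disabled is the identity transform.

    Parameters
    ----------
    crop_lo, crop_hi : float or None
        Closed wavenumber interval (cm^-1) to retain.
    target_grid : ndarray or None
        Optional grid to interpolate onto (linear interpolation, no
        extrapolation).
    despike_window : odd int or None
        Median-filter window in points for cosmic-ray removal. Default 5.
    baseline_method : {"polynomial", "emsc", "none"}
        Background-subtraction method. Default ``"polynomial"``.
    poly_degree : int
        Degree of the iterative polynomial baseline. Default 5.
    poly_max_iter, poly_tol : int, float
        Iteration budget and relative convergence tolerance of the
        clip-to-fit loop.
    emsc_degree : int
        Degree of the additive polynomial terms in the EMSC model. Default 2.
    emsc_reference : "mean" or ndarray
        EMSC reference spectrum; ``"mean"`` uses the mean of the data the
        chain is run on (the facade passes the training-partition mean).
    sg_window, sg_order : odd int or None, int
        Savitzky-Golay window (points) and polynomial order. Defaults 11, 3.
    normalize : bool
        Divide each spectrum by the sum of its intensities. Default True.
    """

    crop_lo: float | None = None
    crop_hi: float | None = None
    target_grid: np.ndarray | None = None
    despike_window: int | None = 5
    baseline_method: str = "polynomial"
    poly_degree: int = 5
    poly_max_iter: int = 100
    poly_tol: float = 1e-4
    emsc_degree: int = 2
    emsc_reference: Any = "mean"
    sg_window: int | None = 11
    sg_order: int = 3
    normalize: bool = True

    def validate(self) -> None:
        if (self.crop_lo is None) != (self.crop_hi is None):
            raise ConfigError("crop_lo and crop_hi must be set together")
        if self.crop_lo is not None and not self.crop_lo < self.crop_hi:
            raise ConfigError(f"crop_lo ({self.crop_lo}) must be < crop_hi ({self.crop_hi})")
        if self.despike_window is not None:
            w = int(self.despike_window)
            if w < 3 or w % 2 == 0:
                raise ConfigError(f"despike_window must be an odd integer >= 3, got {w}")
        if self.baseline_method not in ("polynomial", "emsc", "none"):
            raise ConfigError(f"unknown baseline_method {self.baseline_method!r}")
        if self.poly_degree < 0:
            raise ConfigError("poly_degree must be >= 0")
        if self.emsc_degree < 0:
            raise ConfigError("emsc_degree must be >= 0")
        if self.sg_window is not None:
            w = int(self.sg_window)
            if w < 3 or w % 2 == 0:
                raise ConfigError(f"sg_window must be an odd integer >= 3, got {w}")
            if not 0 <= self.sg_order < w:
                raise ConfigError(
                    f"sg_order ({self.sg_order}) must be non-negative and < sg_window ({w})"
                )

    def to_dict(self) -> dict:
        d = {
            "crop_lo": self.crop_lo,
            "crop_hi": self.crop_hi,
            "target_grid": None if self.target_grid is None
            else np.asarray(self.target_grid, dtype=float).tolist(),
            "despike_window": self.despike_window,
            "baseline_method": self.baseline_method,
            "poly_degree": self.poly_degree,
            "poly_max_iter": self.poly_max_iter,
            "poly_tol": self.poly_tol,
            "emsc_degree": self.emsc_degree,
            "emsc_reference": "mean" if isinstance(self.emsc_reference, str)
            else np.asarray(self.emsc_reference, dtype=float).tolist(),
            "sg_window": self.sg_window,
            "sg_order": self.sg_order,
            "normalize": self.normalize,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        d = dict(d)
        if d.get("target_grid") is not None:
            d["target_grid"] = np.asarray(d["target_grid"], dtype=float)
        ref = d.get("emsc_reference", "mean")
        if not isinstance(ref, str) and ref is not None:
            d["emsc_reference"] = np.asarray(ref, dtype=float)
        known = {f for f in cls.__dataclass_fields__}
        cfg = cls(**{k: v for k, v in d.items() if k in known})
        cfg.validate()
        return cfg


@dataclass
class PreprocessReport:
    """Per-stage record of what the chain did, in execution order."""

    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, params: dict, **info) -> None:
        self.stages.append({"stage": name, "params": params, **info})

    def stage_names(self) -> list[str]:
        return [s["stage"] for s in self.stages]

    def to_dict(self) -> dict:
        return {"stages": self.stages}


# ---------------------------------------------------------------------------
# Individual stages
# ---------------------------------------------------------------------------

def crop(ds: SpectralDataset, lo: float, hi: float) -> SpectralDataset:
    """Retain exactly the grid points with ``lo <= w <= hi`` (closed interval)."""
    if not lo < hi:
        raise ConfigError(f"crop interval requires lo < hi, got [{lo}, {hi}]")
    mask = (ds.wavenumbers >= lo) & (ds.wavenumbers <= hi)
    if int(mask.sum()) < 3:
        raise ValidationError(
            f"crop [{lo}, {hi}] retains {int(mask.sum())} grid points; at least 3 required"
        )
    return ds.with_intensities(ds.intensities[mask, :].copy(),
                               wavenumbers=ds.wavenumbers[mask].copy())


def interpolate_to_grid(ds: SpectralDataset, grid: np.ndarray) -> SpectralDataset:
    """Linearly interpolate every spectrum onto ``grid`` (no extrapolation)."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 3 or np.any(np.diff(grid) <= 0):
        raise ConfigError("interpolation grid must be strictly increasing with >= 3 points")
    if grid[0] < ds.wavenumbers[0] or grid[-1] > ds.wavenumbers[-1]:
        raise RangeError(
            f"grid [{grid[0]}, {grid[-1]}] extends beyond the data span "
            f"[{ds.wavenumbers[0]}, {ds.wavenumbers[-1]}]; extrapolation is not supported"
        )
    out = np.empty((grid.size, ds.n_spectra))
    for j in range(ds.n_spectra):
        out[:, j] = np.interp(grid, ds.wavenumbers, ds.intensities[:, j])
    return ds.with_intensities(out, wavenumbers=grid.copy())


def despike_median(ds: SpectralDataset, window: int = 5) -> SpectralDataset:
    """Replace each intensity by the median of its centered window.

    Removes single-channel cosmic-ray spikes. Edges use nearest-value
    padding.
    """
    window = int(window)
    if window % 2 == 0 or window < 3:
        raise ConfigError(f"median window must be an odd integer >= 3, got {window}")
    if window > ds.n_points:
        raise ConfigError(f"median window {window} exceeds spectrum length {ds.n_points}")
    out = median_filter(ds.intensities, size=(window, 1), mode="nearest")
    return ds.with_intensities(out)


def _modpoly(w_norm: np.ndarray, y: np.ndarray, degree: int,
             max_iter: int, tol: float) -> tuple[np.ndarray, bool, int]:
    """Iterative clip-to-fit polynomial baseline on one spectrum.

    Returns (baseline, converged, iterations). The fit never rises above
    the running minimum envelope, so Raman peaks are excluded from the
    background estimate while the smooth fluorescence is captured.
    """
    y_work = y.astype(float).copy()
    prev_fit = None
    fit = np.zeros_like(y_work)
    for it in range(1, max_iter + 1):
        coef = npoly.polyfit(w_norm, y_work, degree)
        fit = npoly.polyval(w_norm, coef)
        if prev_fit is not None:
            scale = max(float(np.linalg.norm(prev_fit)), 1e-300)
            if float(np.linalg.norm(fit - prev_fit)) <= tol * scale:
                return fit, True, it
        y_work = np.minimum(y_work, fit)
        prev_fit = fit
    return fit, False, max_iter


def baseline_polynomial(sp: Spectrum, degree: int = 5, max_iter: int = 100,
                        tol: float = 1e-4) -> Spectrum:
    """Subtract an iterative polynomial baseline from one spectrum.

    A plain least-squares polynomial would be pulled upward by the Raman
    peaks; the clip-to-fit iteration (fit, clip the working spectrum to the
    fit, refit) converges to a curve hugging the smooth background.
    Non-convergence emits a warning and uses the last iterate.
    """
    if degree < 0:
        raise ConfigError("degree must be >= 0")
    if len(sp) <= degree + 1:
        raise ValidationError(
            f"spectrum {sp.id!r} has {len(sp)} points; need more than degree+1={degree + 1}"
        )
    w_norm = _normalize_axis(sp.wavenumbers)
    baseline, converged, _ = _modpoly(w_norm, sp.intensities, degree, max_iter, tol)
    if not converged:
        warnings.warn(
            f"polynomial baseline did not converge in {max_iter} iterations "
            f"for spectrum {sp.id!r}; using last iterate",
            RuntimeWarning,
        )
    return Spectrum(sp.wavenumbers.copy(), sp.intensities - baseline, id=sp.id)


def baseline_polynomial_dataset(ds: SpectralDataset, degree: int = 5,
                                max_iter: int = 100, tol: float = 1e-4
                                ) -> tuple[SpectralDataset, int]:
    """Apply the polynomial baseline to every column; returns (dataset, n_not_converged)."""
    w_norm = _normalize_axis(ds.wavenumbers)
    out = np.empty_like(ds.intensities)
    n_fail = 0
    for j in range(ds.n_spectra):
        baseline, converged, _ = _modpoly(w_norm, ds.intensities[:, j], degree, max_iter, tol)
        if not converged:
            n_fail += 1
        out[:, j] = ds.intensities[:, j] - baseline
    if n_fail:
        warnings.warn(
            f"polynomial baseline did not converge for {n_fail} spectra; "
            "last iterates used",
            RuntimeWarning,
        )
    return ds.with_intensities(out), n_fail


def _normalize_axis(w: np.ndarray) -> np.ndarray:
    """Map wavenumbers affinely onto [-1, 1] to condition polynomial fits."""
    lo, hi = float(w[0]), float(w[-1])
    return 2.0 * (w - lo) / (hi - lo) - 1.0


def baseline_emsc(ds: SpectralDataset, reference="mean",
                  emsc_degree: int = 2) -> SpectralDataset:
    """Extended multiplicative signal correction.

    Each spectrum ``x`` is modeled as ``x = b * m + sum_k p_k w^k + e``
    against the reference ``m`` and polynomial terms in the normalized
    wavenumber ``w in [-1, 1]``, by least squares. The corrected spectrum
    is ``(x - sum_k p_k w^k) / b``: the additive background removed, the
    multiplicative scattering scale divided out.
    """
    if emsc_degree < 0:
        raise ConfigError("emsc_degree must be >= 0")
    if isinstance(reference, str):
        if reference != "mean":
            raise ConfigError(f"unknown EMSC reference {reference!r}")
        m = ds.intensities.mean(axis=1)
    elif isinstance(reference, Spectrum):
        if not np.array_equal(reference.wavenumbers, ds.wavenumbers):
            raise ValidationError("EMSC reference spectrum is on a different grid")
        m = reference.intensities.astype(float)
    else:
        m = np.asarray(reference, dtype=float)
        if m.shape != (ds.n_points,):
            raise ValidationError(
                f"EMSC reference length {m.size} does not match grid length {ds.n_points}"
            )
    w_norm = _normalize_axis(ds.wavenumbers)
    # design matrix: [m, 1, w, w^2, ...]
    P = np.column_stack([w_norm ** k for k in range(emsc_degree + 1)])
    A = np.column_stack([m, P])
    coef, *_ = np.linalg.lstsq(A, ds.intensities, rcond=None)  # (2+deg, N)
    out = np.empty_like(ds.intensities)
    for j in range(ds.n_spectra):
        b = float(coef[0, j])
        if b <= 0 or abs(b) < 1e-8:
            raise DegenerateFitError(
                f"EMSC multiplicative factor b={b:.3g} is degenerate for "
                f"spectrum {ds.ids[j]!r}"
            )
        additive = P @ coef[1:, j]
        out[:, j] = (ds.intensities[:, j] - additive) / b
    return ds.with_intensities(out)


def smooth_savitzky_golay(ds: SpectralDataset, window: int = 11,
                          order: int = 3) -> SpectralDataset:
    """Savitzky-Golay smoothing (local least-squares polynomial, mirror edges)."""
    window = int(window)
    if window % 2 == 0 or window < 3:
        raise ConfigError(f"sg window must be an odd integer >= 3, got {window}")
    if not 0 <= order < window:
        raise ConfigError(f"sg order ({order}) must be non-negative and < window ({window})")
    if window > ds.n_points:
        raise ConfigError(f"sg window {window} exceeds spectrum length {ds.n_points}")
    out = savgol_filter(ds.intensities, window_length=window, polyorder=order,
                        axis=0, mode="mirror")
    return ds.with_intensities(out)


def normalize_area(ds: SpectralDataset) -> SpectralDataset:
    """Divide each spectrum by the sum of its intensities (sum becomes 1).

    The grid is uniform in the intended use, so the plain sum differs from a
    trapezoid integral only by a constant factor, and keeps the unit-sum
    invariant exact.
    """
    sums = ds.intensities.sum(axis=0)
    zero = np.isclose(sums, 0.0, atol=1e-300)
    if np.any(zero):
        j = int(np.argmax(zero))
        raise NormalizationError(
            f"spectrum {ds.ids[j]!r} has zero total intensity; area normalization undefined"
        )
    return ds.with_intensities(ds.intensities / sums[np.newaxis, :])


# ---------------------------------------------------------------------------
# The full chain
# ---------------------------------------------------------------------------

def run_chain(ds: SpectralDataset, cfg: PreprocessConfig,
              emsc_reference: np.ndarray | None = None
              ) -> tuple[SpectralDataset, PreprocessReport]:
    """Apply the full preprocessing chain in its fixed order.

    Order: crop -> interpolate -> despike -> baseline -> smooth -> normalize.
    The configuration is validated before any computation. ``emsc_reference``
    overrides ``cfg.emsc_reference`` (used to apply a training-fitted EMSC
    reference to held-out data); the reference actually used is recorded in
    the report so provenance can be archived.

    Returns
    -------
    (SpectralDataset, PreprocessReport)
    """
    cfg.validate()
    report = PreprocessReport()
    out = ds

    if cfg.crop_lo is not None:
        before = out.n_points
        out = crop(out, cfg.crop_lo, cfg.crop_hi)
        report.add("crop", {"lo": cfg.crop_lo, "hi": cfg.crop_hi},
                   points_removed=before - out.n_points)

    if cfg.target_grid is not None:
        out = interpolate_to_grid(out, cfg.target_grid)
        report.add("interpolate", {"n_points": int(np.asarray(cfg.target_grid).size)})

    if cfg.despike_window is not None:
        filtered = despike_median(out, cfg.despike_window)
        altered = int(np.sum(filtered.intensities != out.intensities))
        report.add("despike_median", {"window": int(cfg.despike_window)},
                   points_altered=altered)
        out = filtered

    if cfg.baseline_method == "polynomial":
        out, n_fail = baseline_polynomial_dataset(
            out, cfg.poly_degree, cfg.poly_max_iter, cfg.poly_tol)
        report.add("baseline_polynomial",
                   {"degree": cfg.poly_degree, "max_iter": cfg.poly_max_iter,
                    "tol": cfg.poly_tol},
                   not_converged=n_fail)
    elif cfg.baseline_method == "emsc":
        ref = emsc_reference if emsc_reference is not None else cfg.emsc_reference
        if isinstance(ref, str) and ref == "mean":
            ref = out.intensities.mean(axis=1)
        out = baseline_emsc(out, reference=ref, emsc_degree=cfg.emsc_degree)
        report.add("baseline_emsc", {"degree": cfg.emsc_degree},
                   reference=np.asarray(ref, dtype=float).tolist())

    if cfg.sg_window is not None:
        out = smooth_savitzky_golay(out, cfg.sg_window, cfg.sg_order)
        report.add("smooth_savitzky_golay",
                   {"window": int(cfg.sg_window), "order": int(cfg.sg_order)})

    if cfg.normalize:
        out = normalize_area(out)
        report.add("normalize_area", {})

    return out, report
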