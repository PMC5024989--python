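"""Emission-peak estimation by quadratic least squares, with bead calibration.

The spectral detector samples the emission at 6 nm intervals; the peak is
interpolated below that resolution by ordinary least squares of a
second-order polynomial ``I(lambda) ~ a lambda^2 + b lambda + c`` over all
channels, with the peak taken analytically at the vertex ``-b / (2a)``.  A
fit is valid only when it is concave (a < 0) and the vertex lies inside the
axis span; invalid fits are excluded from every average and their fraction is
reported.

Per-session wavelength calibration uses a reference microsphere field imaged
at the start and end of the session: the additive offset is the reference
peak minus the mean of the two measured bead peaks, and is added to every
fitted tissue peak of that session.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cube_io import DEFAULT_AXIS, SpectralCube, WavelengthAxis
from .errors import CalibrationError

DEFAULT_REFERENCE_NM = 546.0  # vendor-reported microsphere emission peak


@dataclass(frozen=True)
class PeakFit:
    """Quadratic fit of one spectrum: coefficients, vertex, validity."""

    a: float
    b: float
    c: float
    peak_nm: float        # nan when the vertex is undefined (a == 0)
    valid: bool
    residual_rms: float

    @property
    def coeffs(self) -> tuple:
        return (self.a, self.b, self.c)


def _design(axis: WavelengthAxis) -> tuple[np.ndarray, float]:
    # centre the wavelength axis for conditioning; vertex is shift-equivariant
    lam0 = float(axis.wavelengths.mean())
    x = axis.wavelengths - lam0
    return np.column_stack([x**2, x, np.ones_like(x)]), lam0


def _vertex_and_validity(a: float, b: float, axis: WavelengthAxis, lam0: float):
    if a == 0.0:
        return float("nan"), False
    peak = lam0 - b / (2.0 * a)
    valid = a < 0.0 and axis.start_nm <= peak <= axis.end_nm
    return float(peak), bool(valid)


def fit_spectrum(spectrum: np.ndarray, axis: WavelengthAxis = DEFAULT_AXIS) -> PeakFit:
    """OLS quadratic over all channels; analytic vertex as the peak estimate.

    A constant or all-zero spectrum yields ``a == 0`` and an invalid fit
    rather than an exception.
    """
    y = np.asarray(spectrum, dtype=np.float64)
    if y.shape != (axis.n_channels,):
        raise ValueError(
            f"spectrum length {y.shape} does not match axis with {axis.n_channels} channels"
        )
    X, lam0 = _design(axis)
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    a, b_c, c_c = (float(v) for v in coef)
    resid = y - X @ coef
    peak, valid = _vertex_and_validity(a, b_c, axis, lam0)
    # report coefficients on the raw wavelength scale
    b = b_c - 2.0 * a * lam0
    c = a * lam0**2 - b_c * lam0 + c_c
    return PeakFit(a, b, c, peak, valid, float(np.sqrt(np.mean(resid**2))))


@dataclass
class PixelFitResult:
    """Per-pixel quadratic fits over a mask, plus the mean valid peak."""

    peak_map: np.ndarray          # (H, W) float, nan outside mask / invalid
    valid_map: np.ndarray         # (H, W) bool
    mean_peak_nm: float           # nan when no pixel fit is valid
    invalid_fraction: float
    n_valid: int


def fit_pixels(cube: SpectralCube, mask: np.ndarray) -> PixelFitResult:
    """Fit every masked pixel's spectrum independently; average valid peaks.

    The mean is over valid fits only; a mask with zero valid fits yields a
    NaN mean (an explicit missing value, never zero).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    X, lam0 = _design(cube.axis)
    Y = cube.intensities[mask].astype(np.float64).T  # (n_channels, n_pixels)
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)     # (3, n_pixels)
    a, b = coef[0], coef[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        peaks = lam0 - b / (2.0 * a)
    valid = (a < 0) & (peaks >= cube.axis.start_nm) & (peaks <= cube.axis.end_nm)
    peaks = np.where(valid, peaks, np.nan)

    h, w, _ = cube.shape
    peak_map = np.full((h, w), np.nan)
    valid_map = np.zeros((h, w), bool)
    peak_map[mask] = peaks
    valid_map[mask] = valid
    n_valid = int(valid.sum())
    mean_peak = float(np.nanmean(peaks)) if n_valid else float("nan")
    return PixelFitResult(
        peak_map=peak_map,
        valid_map=valid_map,
        mean_peak_nm=mean_peak,
        invalid_fraction=float(1.0 - n_valid / mask.sum()),
        n_valid=n_valid,
    )


def fit_mean_spectrum(cube: SpectralCube, mask: np.ndarray) -> PeakFit:
    """Average the masked spectra first, then fit once (macroscopic mode)."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("mask is empty")
    return fit_spectrum(cube.mean_spectrum(mask), cube.axis)


@dataclass(frozen=True)
class CalibrationRecord:
    """Per-session additive wavelength offset derived from reference beads."""

    session_id: str
    measured_start_nm: float
    measured_end_nm: float
    reference_nm: float = DEFAULT_REFERENCE_NM

    @property
    def offset_nm(self) -> float:
        return self.reference_nm - 0.5 * (self.measured_start_nm + self.measured_end_nm)


#: identity calibration (offset 0) for uncalibrated analyses
NO_CALIBRATION = CalibrationRecord("none", DEFAULT_REFERENCE_NM, DEFAULT_REFERENCE_NM)


def calibrate_session(
    start_cube: SpectralCube,
    end_cube: SpectralCube,
    reference_nm: float = DEFAULT_REFERENCE_NM,
    threshold: float | None = None,
    session_id: str = "",
) -> CalibrationRecord:
    """Measure the bead peak in both session-boundary fields and derive the offset.

    Bead pixels are selected by the same intensity threshold used for tissue
    (Otsu on log total intensity by default, absolute override via
    ``threshold``); each field's peak is the mean valid per-pixel fit.
    """
    from .segmentation import threshold_cube

    measured = []
    for which, cube in (("start", start_cube), ("end", end_cube)):
        thr = threshold_cube(cube, threshold=threshold)
        if thr.empty:
            raise CalibrationError(f"no above-threshold pixels in {which} microsphere field")
        fit = fit_pixels(cube, thr.mask)
        if not np.isfinite(fit.mean_peak_nm):
            raise CalibrationError(f"no valid bead fits in {which} microsphere field")
        measured.append(fit.mean_peak_nm)
    return CalibrationRecord(session_id, measured[0], measured[1], reference_nm)


def apply_calibration(peak_nm, record: CalibrationRecord):
    """Add the session offset to a fitted peak (scalar or array)."""
    return peak_nm + record.offset_nm
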