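"""Wavelength and intensity calibration.

Pixel->wavenumber mapping is fitted as a least-squares polynomial through
reference-band positions detected in a paracetamol spectrum; intensity is
corrected with an instrument-response vector derived from a calibration
lamp of known relative irradiance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .spectra import SpectraSet

__all__ = ["CalibrationModel", "fit_wavelength", "fit_response", "apply_calibration"]


@dataclass
class CalibrationModel:
    """Pixel->wavenumber polynomial plus instrument-response vector.

    ``wl_coeffs`` are ascending-order polynomial coefficients mapping pixel
    index to cm^-1; the polynomial must be strictly increasing over the
    pixel range.  ``response`` is strictly positive, unit mean.
    """

    wl_coeffs: np.ndarray
    wl_degree: int
    px_count: int
    response: np.ndarray | None = None
    reference_residuals: np.ndarray = field(default_factory=lambda: np.array([]))
    residual_tolerance: float = 2.0  # cm^-1

    def __post_init__(self) -> None:
        self.wl_coeffs = np.asarray(self.wl_coeffs, dtype=float)
        axis = self.native_axis()
        if not np.all(np.diff(axis) > 0):
            raise ValueError("calibration polynomial is not strictly increasing")
        if self.response is not None:
            self.response = np.asarray(self.response, dtype=float)
            if np.any(self.response <= 0):
                raise ValueError("instrument response must be strictly positive")
        if self.reference_residuals.size and (
            np.max(np.abs(self.reference_residuals)) > self.residual_tolerance
        ):
            raise ValueError(
                "reference band residuals exceed tolerance "
                f"({np.max(np.abs(self.reference_residuals)):.3f} > "
                f"{self.residual_tolerance} cm^-1)"
            )

    def native_axis(self) -> np.ndarray:
        px = np.arange(self.px_count, dtype=float)
        return np.polynomial.polynomial.polyval(px, self.wl_coeffs)


def _parabola_on_reciprocal(y: np.ndarray, p: int):
    """Lorentzian parameters (A, center_px, gamma_px) from a 3-point
    parabola on 1/y around the maximum at index ``p``.

    For an isolated Lorentzian, 1/y is exactly quadratic in the pixel
    coordinate, so this refinement is exact at any sampling phase.  Falls
    back to a plain parabola on y (A set to 0, excluded from tail
    modeling) when the reciprocal fit is degenerate.
    """
    if not (0 < p < y.size - 1) or np.any(y[p - 1 : p + 2] <= 0):
        return 0.0, float(p), 1.0
    i = np.arange(p - 1, p + 2, dtype=float)
    a, b, c0 = np.polyfit(i, 1.0 / y[p - 1 : p + 2], 2)
    if a <= 0:
        y0, y1, y2 = y[p - 1 : p + 2]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        return 0.0, p + float(np.clip(delta, -0.5, 0.5)), 1.0
    center = -b / (2.0 * a)
    inv_amplitude = c0 - b * b / (4.0 * a)
    if inv_amplitude <= 0:
        return 0.0, float(np.clip(center, p - 0.5, p + 0.5)), 1.0
    amplitude = 1.0 / inv_amplitude
    gamma = np.sqrt(1.0 / (a * amplitude))
    return float(amplitude), float(center), float(gamma)


def _detect_peaks(
    spectrum: np.ndarray,
    n_wanted: int,
    prominence_frac: float = 0.05,
    n_refine_iter: int = 3,
):
    """Local maxima above a relative prominence threshold, centers refined
    by 3-point parabolic interpolation on the reciprocal intensities with
    iterative subtraction of the other bands' Lorentzian tails.  Returns
    sub-pixel positions."""
    spectrum = np.asarray(spectrum, dtype=float)
    peaks, props = find_peaks(spectrum, prominence=prominence_frac * spectrum.max())
    if len(peaks) < n_wanted:
        raise ValueError(
            f"detected {len(peaks)} peaks but {n_wanted} reference bands expected"
        )
    if len(peaks) > n_wanted:
        keep = np.sort(np.argsort(props["prominences"])[-n_wanted:])
        peaks = peaks[keep]
    params = [_parabola_on_reciprocal(spectrum, p) for p in peaks]
    x = np.arange(spectrum.size, dtype=float)
    for _ in range(n_refine_iter):
        updated = []
        for k, p in enumerate(peaks):
            tails = sum(
                (A / (1.0 + ((x - c) / g) ** 2) for j, (A, c, g) in enumerate(params)
                 if j != k and A > 0),
                np.zeros_like(x),
            )
            updated.append(_parabola_on_reciprocal(spectrum - tails, p))
        params = updated
    return np.array([c for _, c, _ in params])


def fit_wavelength(
    reference: np.ndarray,
    known_centers,
    degree: int = 3,
    prominence_frac: float = 0.05,
    residual_tolerance: float = 2.0,
) -> CalibrationModel:
    """Fit the pixel->wavenumber polynomial from a pixel-domain reference
    spectrum with bands at known wavenumber positions.

    Peaks are detected in the pixel domain, matched to ``known_centers`` in
    order, and a least-squares polynomial of the requested degree is fitted.
    """
    reference = np.asarray(reference, dtype=float)
    known = np.sort(np.asarray(list(known_centers), dtype=float))
    if known.size < degree + 1:
        raise ValueError(
            f"{known.size} reference bands cannot determine a degree-{degree} "
            "polynomial"
        )
    peak_px = _detect_peaks(reference, known.size, prominence_frac)
    # ascending-order coefficients from a plain least-squares Vandermonde fit
    coeffs = np.polynomial.polynomial.polyfit(peak_px, known, degree)
    fitted = np.polynomial.polynomial.polyval(peak_px, coeffs)
    residuals = fitted - known
    return CalibrationModel(
        wl_coeffs=coeffs,
        wl_degree=degree,
        px_count=reference.size,
        reference_residuals=residuals,
        residual_tolerance=residual_tolerance,
    )


def fit_response(
    measured_lamp: np.ndarray,
    true_irradiance: np.ndarray,
    smooth_window: int = 31,
    smooth_polyorder: int = 2,
) -> np.ndarray:
    """Instrument response = smoothed(measured / true), rescaled to unit mean.

    The true irradiance must be strictly positive; the returned response is
    strictly positive.  Smoothing is a moving-window polynomial filter.
    """
    measured = np.asarray(measured_lamp, dtype=float)
    true = np.asarray(true_irradiance, dtype=float)
    if measured.shape != true.shape:
        raise ValueError("lamp spectra must share one axis")
    if np.any(true <= 0):
        raise ValueError("true irradiance must be strictly positive everywhere")
    ratio = measured / true
    if smooth_window > 2 and measured.size > smooth_window:
        ratio = savgol_filter(ratio, smooth_window, smooth_polyorder, mode="interp")
    response = ratio / ratio.mean()
    if np.any(response <= 0):
        raise ValueError("fitted response is not strictly positive")
    return response


def apply_calibration(
    raw: SpectraSet, model: CalibrationModel, target_axis: np.ndarray
) -> SpectraSet:
    """Convert a pixel-domain SpectraSet onto a common wavenumber grid.

    Intensities are divided by the instrument response on the native pixel
    grid, then linearly interpolated from the calibrated native axis onto
    ``target_axis``.  No extrapolation: the target must lie inside the
    calibrated range.
    """
    if raw.n_channels != model.px_count:
        raise ValueError(
            f"SpectraSet has {raw.n_channels} channels but model calibrates "
            f"{model.px_count} pixels"
        )
    native = model.native_axis()
    target_axis = np.asarray(target_axis, dtype=float)
    if target_axis[0] < native[0] - 1e-9 or target_axis[-1] > native[-1] + 1e-9:
        raise ValueError(
            f"target axis [{target_axis[0]:.1f}, {target_axis[-1]:.1f}] extends "
            f"beyond calibrated range [{native[0]:.1f}, {native[-1]:.1f}]"
        )
    intensities = raw.intensities
    if model.response is not None:
        intensities = intensities / model.response[None, :]
    out = np.vstack([np.interp(target_axis, native, row) for row in intensities])
    return SpectraSet(
        axis=target_axis,
        intensities=out,
        meta=raw.meta.copy(),
        provenance=raw.provenance
        + [
            {
                "op": "apply_calibration",
                "params": {
                    "wl_degree": model.wl_degree,
                    "target_range": [float(target_axis[0]), float(target_axis[-1])],
                    "n_target_channels": int(target_axis.size),
                },
            }
        ],
    )
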