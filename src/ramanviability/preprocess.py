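"""Spectral cleanup chain for single-cell Raman data.

Canonical order: cosmic-spike removal -> EMSC background correction ->
Savitzky-Golay smoothing -> area normalization over the analysis windows
-> region selection -> rejection of background-only rows.  Every step
appends to the SpectraSet provenance so a run can be replayed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.signal import savgol_filter

from .spectra import SpectraSet

__all__ = [
    "EMSCBasis",
    "RegionSpec",
    "DEFAULT_REGIONS",
    "remove_spikes",
    "emsc_correct",
    "smooth",
    "area_normalize",
    "select_regions",
    "reject_empty",
    "preprocess_pipeline",
    "replay_provenance",
    "PreprocessParams",
]

QC_NO_CELL_SIGNAL = "no_cell_signal"
QC_ZERO_INTEGRAL = "zero_integral"


# ----------------------------------------------------------------------
# region windows
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class RegionSpec:
    """Disjoint, sorted half-open wavenumber windows ``[low, high)``."""

    windows: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        wins = tuple((float(lo), float(hi)) for lo, hi in self.windows)
        if any(hi <= lo for lo, hi in wins):
            raise ValueError("each window needs low < high")
        for (lo1, hi1), (lo2, hi2) in zip(wins, wins[1:]):
            if lo2 < hi1:
                raise ValueError("windows must be disjoint and sorted")
        object.__setattr__(self, "windows", wins)

    def mask(self, axis: np.ndarray) -> np.ndarray:
        axis = np.asarray(axis, dtype=float)
        m = np.zeros(axis.shape, dtype=bool)
        for lo, hi in self.windows:
            m |= (axis >= lo) & (axis < hi)
        return m

    def to_list(self) -> list[list[float]]:
        return [[lo, hi] for lo, hi in self.windows]


#: fingerprint 615-1800 plus high-wavenumber 2790-3010; the band-poor
#: silent region in between is dropped
DEFAULT_REGIONS = RegionSpec(((615.0, 1800.0), (2790.0, 3010.0)))


# ----------------------------------------------------------------------
# cosmic spikes
# ----------------------------------------------------------------------
def remove_spikes(
    s: SpectraSet,
    z_thresh: float = 8.0,
    window: int = 7,
    isolation_ratio: float = 2.0,
) -> tuple[SpectraSet, pd.DataFrame]:
    """Replace cosmic spikes by the local running median.

    A channel is a spike when (a) its residual against the running median
    exceeds ``z_thresh`` robust standard deviations (1.4826 * MAD of that
    spectrum's residuals), and (b) the residual dominates both immediate
    neighbors by ``isolation_ratio`` — a cosmic-ray hit is narrower than
    the instrument lineshape, so an isolated one-channel excursion is a
    spike while the crest of a genuine Raman band (whose neighbors are
    comparably elevated) is not.  Returns the cleaned set and a report
    with per-spectrum correction counts and channel positions.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window >= s.n_channels:
        raise ValueError(
            f"window {window} must be smaller than channel count {s.n_channels}"
        )
    y = s.intensities
    med = median_filter(y, size=(1, window), mode="nearest")
    resid = y - med
    mad = np.median(np.abs(resid - np.median(resid, axis=1, keepdims=True)), axis=1)
    robust_sd = 1.4826 * mad
    robust_sd = np.where(robust_sd <= 0, np.finfo(float).tiny, robust_sd)
    positive = np.clip(resid, 0.0, None)
    left = np.pad(positive[:, :-1], ((0, 0), (1, 0)))
    right = np.pad(positive[:, 1:], ((0, 0), (0, 1)))
    neighbor = np.maximum(left, right)
    is_spike = (resid > z_thresh * robust_sd[:, None]) & (
        resid > isolation_ratio * neighbor
    )

    cleaned = np.where(is_spike, med, y)
    report = pd.DataFrame(
        {
            "n_corrected": is_spike.sum(axis=1),
            "channels": [np.flatnonzero(row).tolist() for row in is_spike],
        }
    )
    out = s.with_intensities(
        cleaned,
        "remove_spikes",
        {"z_thresh": z_thresh, "window": window,
         "isolation_ratio": isolation_ratio},
    )
    return out, report


# ----------------------------------------------------------------------
# EMSC
# ----------------------------------------------------------------------
class EMSCBasis:
    """Design matrix for extended multiplicative signal correction.

    Columns: pure-cell reference spectrum, named interferent spectra
    (water, fluorescence, ...), and polynomial baseline terms up to
    ``poly_order`` (default 3) on the axis rescaled to [-1, 1].  The
    matrix must have full column rank.
    """

    def __init__(
        self,
        axis: np.ndarray,
        reference: np.ndarray,
        interferents: dict[str, np.ndarray] | None = None,
        poly_order: int = 3,
    ) -> None:
        self.axis = np.asarray(axis, dtype=float)
        self.reference = np.asarray(reference, dtype=float)
        if self.reference.shape != self.axis.shape:
            raise ValueError("reference spectrum must live on the basis axis")
        self.interferents = {
            k: np.asarray(v, dtype=float) for k, v in (interferents or {}).items()
        }
        for name, vec in self.interferents.items():
            if vec.shape != self.axis.shape:
                raise ValueError(f"interferent {name!r} not on the basis axis")
        self.poly_order = int(poly_order)
        t = (self.axis - self.axis[0]) / (self.axis[-1] - self.axis[0]) * 2.0 - 1.0
        poly_cols = [t**k for k in range(self.poly_order + 1)]
        cols = [self.reference, *self.interferents.values(), *poly_cols]
        self.design = np.column_stack(cols)
        if not np.all(np.isfinite(self.design)):
            raise ValueError("basis vectors must be finite")
        if np.linalg.matrix_rank(self.design) < self.design.shape[1]:
            raise ValueError("EMSC design matrix is rank-deficient")
        self.column_names = (
            ["b_ref"]
            + [f"b_{name}" for name in self.interferents]
            + [f"c{k}" for k in range(self.poly_order + 1)]
        )

    @property
    def n_interferents(self) -> int:
        return len(self.interferents)


def emsc_correct(
    s: SpectraSet, basis: EMSCBasis, b_ref_eps: float = 1e-6
) -> tuple[SpectraSet, pd.DataFrame]:
    """Per-spectrum ordinary least squares on the EMSC design matrix.

    For each row ``y`` the model ``y = b_ref*ref + sum(b_i*interf_i) +
    sum(c_k*t^k) + e`` is solved; the corrected spectrum is
    ``(y - interferent and polynomial parts) / b_ref``.  Rows with
    ``b_ref <= b_ref_eps`` carry no cell signal: they are flagged, left as
    the raw residual (undivided), and feed :func:`reject_empty`.
    """
    if basis.axis.shape != s.axis.shape or not np.allclose(basis.axis, s.axis):
        raise ValueError("EMSC basis is not on the SpectraSet axis")
    Y = s.intensities
    coeffs, *_ = np.linalg.lstsq(basis.design, Y.T, rcond=None)
    coeffs = coeffs.T  # (n_spectra, n_cols)
    b_ref = coeffs[:, 0]
    nuisance = coeffs[:, 1:] @ basis.design[:, 1:].T
    residual = Y - nuisance
    no_signal = b_ref <= b_ref_eps
    divisor = np.where(no_signal, 1.0, b_ref)
    corrected = residual / divisor[:, None]

    table = pd.DataFrame(coeffs, columns=basis.column_names)
    table["no_cell_signal"] = no_signal
    out = s.with_intensities(
        corrected,
        "emsc_correct",
        {
            "poly_order": basis.poly_order,
            "interferents": list(basis.interferents),
            "b_ref_eps": b_ref_eps,
        },
    )
    out.meta["emsc_b_ref"] = b_ref
    out.add_qc_flag(no_signal, QC_NO_CELL_SIGNAL)
    return out, table


# ----------------------------------------------------------------------
# smoothing & normalization
# ----------------------------------------------------------------------
def smooth(s: SpectraSet, window: int = 9, polyorder: int = 3) -> SpectraSet:
    """Savitzky-Golay smoothing of every row; edges by polynomial fit on
    the truncated window.  Polynomials of degree <= polyorder pass through
    unchanged."""
    if polyorder >= window:
        raise ValueError("polyorder must be < window")
    if window >= s.n_channels:
        raise ValueError("window must be smaller than the channel count")
    smoothed = savgol_filter(s.intensities, window, polyorder, axis=1, mode="interp")
    return smooth_record(s, smoothed, window, polyorder)


def smooth_record(s, smoothed, window, polyorder):
    return s.with_intensities(
        smoothed, "smooth", {"window": window, "polyorder": polyorder}
    )


def area_normalize(
    s: SpectraSet, regions: RegionSpec = DEFAULT_REGIONS
) -> SpectraSet:
    """Divide each row by the integral of its absolute value over the
    analysis windows (trapezoidal rule), cancelling per-cell laser-gain
    differences.  Zero-integral rows are flagged, not divided."""
    mask = regions.mask(s.axis)
    if not mask.any():
        raise ValueError("normalization regions do not overlap the axis")
    areas = _windowed_abs_area(s.axis, s.intensities, regions)
    zero = areas <= 0
    divisor = np.where(zero, 1.0, areas)
    out = s.with_intensities(
        s.intensities / divisor[:, None],
        "area_normalize",
        {"windows": regions.to_list()},
    )
    out.add_qc_flag(zero, QC_ZERO_INTEGRAL)
    return out


def _windowed_abs_area(axis, intensities, regions: RegionSpec) -> np.ndarray:
    absval = np.abs(intensities)
    total = np.zeros(intensities.shape[0])
    for lo, hi in regions.windows:
        m = (axis >= lo) & (axis < hi)
        if m.sum() >= 2:
            total += np.trapezoid(absval[:, m], axis[m], axis=1)
    return total


def select_regions(s: SpectraSet, regions: RegionSpec = DEFAULT_REGIONS) -> SpectraSet:
    """Drop channels outside the analysis windows (silent region etc.)."""
    mask = regions.mask(s.axis)
    if not mask.any():
        raise ValueError(
            f"region windows {regions.to_list()} select no channels on axis "
            f"[{s.axis[0]:.0f}, {s.axis[-1]:.0f}]"
        )
    return SpectraSet(
        axis=s.axis[mask],
        intensities=s.intensities[:, mask],
        meta=s.meta.copy(),
        provenance=s.provenance
        + [{"op": "select_regions", "params": {"windows": regions.to_list()}}],
    )


# ----------------------------------------------------------------------
# empty-spectrum rejection
# ----------------------------------------------------------------------
def reject_empty(
    s: SpectraSet, rel_threshold: float = 0.05, b_ref_floor: float = 0.05
) -> tuple[SpectraSet, pd.DataFrame]:
    """Remove background-only rows.

    A row is rejected when it carries the EMSC ``no_cell_signal`` flag or
    its cell-reference coefficient falls below ``rel_threshold`` times the
    median coefficient of its well (well-anchored so dose-dependent
    intensity shifts do not inflate rejection).  ``b_ref_floor`` is an
    absolute lower bound on the coefficient — in units of the reference
    spectrum, i.e. it assumes the reference is a typical single cell — so
    that a well containing no cells at all (well median near zero) is
    still fully rejected.  Returns the filtered set and a per-well report
    of rejected fractions; an all-rejected well is allowed and reported at
    warning level.
    """
    if "emsc_b_ref" not in s.meta.columns:
        raise ValueError("reject_empty requires emsc_correct to have run")
    b_ref = s.meta["emsc_b_ref"].to_numpy(dtype=float)
    flagged = s.has_qc_flag(QC_NO_CELL_SIGNAL)
    reject = flagged.copy()
    wells = s.meta["well"].astype(str)
    for well, idx in wells.groupby(wells).groups.items():
        idx = np.asarray(idx)
        med = np.median(b_ref[idx])
        reject[idx] |= b_ref[idx] < max(rel_threshold * med, b_ref_floor)

    rows = []
    for well, idx in wells.groupby(wells).groups.items():
        idx = np.asarray(idx)
        frac = float(reject[idx].mean())
        rows.append(
            {
                "well": well,
                "n_total": int(idx.size),
                "n_rejected": int(reject[idx].sum()),
                "rejected_fraction": frac,
                "warning": "all rows rejected" if frac == 1.0 else "",
            }
        )
    report = pd.DataFrame(rows)
    out = s.subset_rows(
        ~reject,
        "reject_empty",
        {"rel_threshold": rel_threshold, "b_ref_floor": b_ref_floor},
    )
    return out, report


# ----------------------------------------------------------------------
# pipeline driver & provenance replay
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class PreprocessParams:
    """Tunable knobs of the cleanup chain with their defaults."""

    spike_z_thresh: float = 8.0
    spike_window: int = 7
    sg_window: int = 9
    sg_polyorder: int = 3
    b_ref_eps: float = 1e-6
    reject_rel_threshold: float = 0.05


def preprocess_pipeline(
    s: SpectraSet,
    basis: EMSCBasis,
    regions: RegionSpec = DEFAULT_REGIONS,
    params: PreprocessParams = PreprocessParams(),
) -> tuple[SpectraSet, dict]:
    """Run the full cleanup chain in canonical order and collect reports."""
    out, spike_report = remove_spikes(s, params.spike_z_thresh, params.spike_window)
    out, emsc_table = emsc_correct(out, basis, params.b_ref_eps)
    out = smooth(out, params.sg_window, params.sg_polyorder)
    out = area_normalize(out, regions)
    out = select_regions(out, regions)
    out, rejection_report = reject_empty(out, params.reject_rel_threshold)
    reports = {
        "spikes": spike_report,
        "emsc": emsc_table,
        "rejection": rejection_report,
    }
    return out, reports


def replay_provenance(
    raw: SpectraSet, provenance: list[dict], env: dict
) -> SpectraSet:
    """Re-execute a provenance log on raw input.

    ``env`` supplies the non-scalar objects steps need (``basis`` for
    EMSC, ``regions`` built from the recorded windows).  Entries whose op
    is not a preprocessing step (e.g. the simulate record) are skipped.
    """
    out = raw
    for entry in provenance:
        op, p = entry["op"], entry["params"]
        if op == "remove_spikes":
            out, _ = remove_spikes(
                out, p["z_thresh"], p["window"], p["isolation_ratio"]
            )
        elif op == "emsc_correct":
            out, _ = emsc_correct(out, env["basis"], p["b_ref_eps"])
        elif op == "smooth":
            out = smooth(out, p["window"], p["polyorder"])
        elif op == "area_normalize":
            out = area_normalize(out, RegionSpec(tuple(map(tuple, p["windows"]))))
        elif op == "select_regions":
            out = select_regions(out, RegionSpec(tuple(map(tuple, p["windows"]))))
        elif op == "reject_empty":
            out, _ = reject_empty(out, p["rel_threshold"], p["b_ref_floor"])
    return out
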