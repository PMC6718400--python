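"""Dose-response analysis of predicted viability percentages.

IC50 is estimated by a four-parameter log-logistic fit in which the upper
asymptote is anchored to the mean control viability (a zero dose cannot
enter a log-dose model as a fitted point) and the lower asymptote is
bounded in [0, 30] percent.  A multi-start grid over slope and IC50 makes
the nonlinear fit deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .chemometrics import ViabilityPrediction

__all__ = ["DoseResponseFit", "AssayComparison", "fit_ic50", "compare_assays"]


@dataclass
class DoseResponseFit:
    """Fitted log-logistic dose-response curve.

    ``v(d) = lower + (upper - lower) / (1 + (d / ic50)^slope)``
    """

    lower: float
    upper: float
    slope: float
    ic50: float
    rss: float
    per_point_fit: pd.DataFrame
    extrapolated: bool = False
    non_inhibitory: bool = False
    n_starts_converged: int = 0

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError("lower asymptote exceeds upper asymptote")
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")

    def predict(self, doses) -> np.ndarray:
        d = np.asarray(doses, dtype=float)
        out = np.full_like(d, self.upper)
        pos = d > 0
        out[pos] = self.lower + (self.upper - self.lower) / (
            1.0 + (d[pos] / self.ic50) ** self.slope
        )
        return out


@dataclass
class AssayComparison:
    """Row-wise deviation of Raman-predicted viability from the reference
    assay, condition by condition."""

    rows: pd.DataFrame
    max_abs_deviation: float = field(init=False)

    def __post_init__(self) -> None:
        self.max_abs_deviation = float(self.rows["deviation"].abs().max())


def _loglogistic(d, lower, upper, slope, ic50):
    return lower + (upper - lower) / (1.0 + (d / ic50) ** slope)


def fit_ic50(
    doses,
    viability_percent,
    lower_bounds: tuple[float, float] = (0.0, 30.0),
    slope_grid=(0.5, 1.0, 1.5, 2.0, 3.0),
    n_ic50_starts: int = 12,
) -> DoseResponseFit:
    """Fit the anchored log-logistic model to (dose, percent-viable) pairs.

    Zero-dose (control) points set the upper asymptote: their mean is
    fixed as ``upper`` and they do not enter the residuals.  ``lower`` and
    ``slope`` are fitted within bounds; the best of a deterministic
    multi-start grid (by residual sum of squares) is returned.  Percent
    scale is arbitrary: 0-1 inputs fit identically up to asymptote units.
    """
    d = np.asarray(list(doses), dtype=float)
    v = np.asarray(list(viability_percent), dtype=float)
    if d.shape != v.shape:
        raise ValueError("doses and viability arrays must align")
    if not (np.all(np.isfinite(d)) and np.all(np.isfinite(v))):
        raise ValueError("non-finite dose or viability input")
    if np.any(d < 0):
        raise ValueError("doses must be >= 0")
    scale = 100.0 if v.max() > 1.5 else 1.0
    if np.any(v < 0) or np.any(v > scale):
        raise ValueError("viability values outside the percent range")

    is_ctrl = d == 0
    if not is_ctrl.any():
        raise ValueError("need at least one zero-dose (control) point")
    if np.unique(d[~is_ctrl]).size < 3:
        raise ValueError("need >= 4 dose levels including the control")
    upper = float(v[is_ctrl].mean())
    d_fit, v_fit = d[~is_ctrl], v[~is_ctrl]

    lo = (lower_bounds[0] / 100.0 * scale, 0.1, 1e-4)
    # the lower asymptote can never exceed the anchored upper asymptote
    hi = (min(lower_bounds[1] / 100.0 * scale, upper), 10.0, 1e3)
    ic50_starts = np.geomspace(d_fit.min() / 5.0, d_fit.max() * 5.0, n_ic50_starts)

    best = None
    n_ok = 0
    for s0 in slope_grid:
        for i0 in ic50_starts:
            x0 = np.clip(
                [min(v_fit.min(), upper) * 0.5, s0, i0], lo, hi
            )
            try:
                res = least_squares(
                    lambda p: _loglogistic(d_fit, p[0], upper, p[1], p[2]) - v_fit,
                    x0,
                    bounds=(lo, hi),
                )
            except Exception:
                continue
            if not res.success:
                continue
            n_ok += 1
            if best is None or res.cost < best.cost - 1e-12:
                best = res
    if best is None:
        raise RuntimeError(
            "no multi-start converged; slope grid "
            f"{tuple(slope_grid)}, ic50 starts "
            f"[{ic50_starts[0]:.3g}, {ic50_starts[-1]:.3g}]"
        )
    lower, slope, ic50 = best.x
    fitted = _loglogistic(d_fit, lower, upper, slope, ic50)
    per_point = pd.DataFrame(
        {"dose": d_fit, "observed": v_fit, "fitted": fitted,
         "residual": v_fit - fitted}
    )
    extrapolated = not (d_fit[d_fit > 0].min() / 10.0 <= ic50 <= d_fit.max() * 10.0)
    # viability rising with dose means the curve is not inhibitory
    non_inhibitory = np.polyfit(np.log(d_fit), v_fit, 1)[0] > 0
    if non_inhibitory:
        warnings.warn(
            "viability increases with dose: fit is not inhibitory and the "
            "IC50 is not meaningful",
            stacklevel=2,
        )
    return DoseResponseFit(
        lower=float(lower),
        upper=upper,
        slope=float(slope),
        ic50=float(ic50),
        rss=float(2.0 * best.cost),
        per_point_fit=per_point,
        extrapolated=extrapolated,
        non_inhibitory=bool(non_inhibitory),
        n_starts_converged=n_ok,
    )


def compare_assays(
    pred: ViabilityPrediction | pd.DataFrame, reference_table: pd.DataFrame
) -> AssayComparison:
    """Join Raman-predicted percentages with the reference assay table on
    (condition_label, batch) and tabulate deviations.

    ``reference_table`` needs columns condition_label, batch,
    reference_percent.  Unmatched conditions are an error naming them.
    """
    raman = pred.per_condition if isinstance(pred, ViabilityPrediction) else pred
    required = {"condition_label", "batch", "percent_viable"}
    if not required <= set(raman.columns):
        raise ValueError(f"prediction table needs columns {sorted(required)}")
    raman = raman[sorted(required | ({"dose"} & set(raman.columns)))]
    merged = raman.merge(
        reference_table[["condition_label", "batch", "reference_percent"]],
        on=["condition_label", "batch"],
        how="outer",
        indicator=True,
    )
    unmatched = merged.loc[merged["_merge"] != "both"]
    if len(unmatched):
        pairs = sorted(
            zip(unmatched["condition_label"], unmatched["batch"].astype(str))
        )
        raise ValueError(f"unmatched condition/batch pairs: {pairs}")
    rows = merged.drop(columns="_merge").rename(
        columns={"percent_viable": "raman_percent"}
    )
    rows["deviation"] = rows["raman_percent"] - rows["reference_percent"]
    return AssayComparison(rows=rows)
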