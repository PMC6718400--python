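"""Synthetic single-cell Raman data with the statistical structure the
analysis pipeline assumes.

The generator renders macromolecular component spectra (protein, lipid,
nucleic acid, drug) as sums of Lorentzian/Gaussian bands at literature
positions, adds a water background and a dose-scaled fluorescence
continuum, and draws cell populations as mixtures of a viable and a
non-viable composition.  Per-spectrum multiplicative gain, additive
detector noise, sparse cosmic spikes and background-only "empty" rows
emulate the main nuisance processes of a real high-content Raman screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import SpectraSet

__all__ = [
    "BandSpec",
    "ComponentSpectrum",
    "PopulationSpec",
    "make_axis",
    "default_component_library",
    "simulate_population",
    "simulate_dose_ladder",
    "simulate_paracetamol",
    "simulate_lamp_pair",
    "render_to_pixels",
    "logistic_viable_fractions",
    "DEFAULT_PX_COUNT",
    "DEFAULT_WL_COEFFS",
    "PARACETAMOL_BANDS",
]

# Default detector geometry: 1340-pixel CCD line mapped near-linearly onto
# ~300-3115 cm^-1, covering fingerprint (615-1800) and high-wavenumber
# (2790-3010) regions with the silent region in between.
DEFAULT_PX_COUNT = 1340
DEFAULT_WL_COEFFS = (300.0, 2.1)

#: well-documented paracetamol Raman shifts (cm^-1) used for wavelength
#: calibration; an isolated, strong subset of the published band table
PARACETAMOL_BANDS = (
    651.6,
    797.2,
    857.9,
    1105.5,
    1168.5,
    1236.8,
    1323.9,
    1561.5,
    1648.4,
    2931.1,
)


# ----------------------------------------------------------------------
# domain types
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class BandSpec:
    """One vibrational band: center (cm^-1), FWHM width, relative amplitude."""

    center: float
    width: float = 14.0
    amplitude: float = 1.0
    shape: str = "lorentzian"
    assignment: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"band width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise ValueError(f"band amplitude must be >= 0, got {self.amplitude}")
        if self.shape not in ("lorentzian", "gaussian"):
            raise ValueError(f"unknown band shape {self.shape!r}")

    def evaluate(self, axis: np.ndarray) -> np.ndarray:
        x = np.asarray(axis, dtype=float)
        if self.shape == "lorentzian":
            gamma = self.width / 2.0
            return self.amplitude / (1.0 + ((x - self.center) / gamma) ** 2)
        sigma = self.width / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return self.amplitude * np.exp(-0.5 * ((x - self.center) / sigma) ** 2)


@dataclass(frozen=True)
class ComponentSpectrum:
    """A named pure-component spectrum: a band list plus an optional broad
    smooth profile (used for water and fluorescence continua).

    Evaluated spectra are non-negative and normalized to unit area so that
    mixture weights read as composition fractions.
    """

    name: str
    bands: tuple[BandSpec, ...] = ()
    broad_profile: tuple[tuple[float, float, float], ...] = ()
    #: each broad term is (center, fwhm, amplitude) of a broad Gaussian
    ramp: tuple[float, float] = (0.0, 0.0)  # (offset, slope per cm^-1)

    def evaluate(self, axis: np.ndarray, normalize: bool = True) -> np.ndarray:
        x = np.asarray(axis, dtype=float)
        y = np.zeros_like(x)
        for band in self.bands:
            y += band.evaluate(x)
        for center, fwhm, amp in self.broad_profile:
            y += BandSpec(center, fwhm, amp, "gaussian").evaluate(x)
        offset, slope = self.ramp
        if offset or slope:
            y += offset + slope * (x - x[0])
        y = np.clip(y, 0.0, None)
        if normalize:
            area = np.trapezoid(y, x)
            if area <= 0:
                raise ValueError(f"component {self.name!r} has zero area on this axis")
            y = y / area
        return y


def _weights_valid(weights: dict[str, float]) -> None:
    if any(w < 0 for w in weights.values()):
        raise ValueError("composition weights must be >= 0")
    total = sum(weights.values())
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"composition weights must sum to 1, got {total}")


@dataclass
class PopulationSpec:
    """Everything needed to simulate one well: condition, dose, population
    size, viable fraction, compositions of the two subpopulations and the
    nuisance-process parameters."""

    condition_label: str
    dose: float
    n_cells: int
    viable_fraction: float
    composition_viable: dict[str, float]
    composition_nonviable: dict[str, float]
    fluorescence_scale: float = 0.0
    water_amplitude: float = 0.5
    composition_jitter_sd: float = 0.05
    noise_sd: float = 1.5e-4
    gain_cv: float = 0.05
    spike_rate: float = 0.05
    empty_rate: float = 0.1
    batch: str = "batch-1"
    well: str = "well-1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.viable_fraction <= 1.0:
            raise ValueError("viable_fraction must lie in [0, 1]")
        if self.dose < 0:
            raise ValueError("dose must be >= 0")
        _weights_valid(self.composition_viable)
        _weights_valid(self.composition_nonviable)


# ----------------------------------------------------------------------
# axis
# ----------------------------------------------------------------------
def make_axis(px_count: int, coeffs=DEFAULT_WL_COEFFS) -> np.ndarray:
    """Evaluate a pixel->wavenumber polynomial on ``0..px_count-1``.

    The polynomial (coefficients in ascending order) must be strictly
    increasing over the pixel range; a folding map is rejected.
    """
    if px_count < 2:
        raise ValueError("px_count must be >= 2")
    px = np.arange(px_count, dtype=float)
    axis = np.polynomial.polynomial.polyval(px, np.asarray(coeffs, dtype=float))
    if not np.all(np.diff(axis) > 0):
        raise ValueError("pixel->wavenumber polynomial is not strictly increasing")
    return axis


# ----------------------------------------------------------------------
# component library
# ----------------------------------------------------------------------
def default_component_library(axis: np.ndarray) -> dict[str, np.ndarray]:
    """Unit-area pure-component spectra on ``axis``.

    Band positions follow the standard cell-spectrum assignments:
    nucleic acids at 783/813/830/1096, proteins at 760/830/1004/1263/1660
    (plus the 2930 CH3 stretch), lipids at 1096/1263/1303/1441/1660/1740/
    2851, doxorubicin at 1086/1215/1247.  Water and fluorescence are broad
    smooth continua.
    """
    components = [
        ComponentSpectrum(
            "protein",
            bands=(
                BandSpec(760, 13, 0.5, assignment="tryptophan"),
                BandSpec(830, 13, 0.4, assignment="tyrosine ring breathing"),
                BandSpec(1004, 13, 1.0, assignment="phenylalanine ring breathing"),
                BandSpec(1263, 18, 0.5, assignment="amide III"),
                BandSpec(1340, 20, 0.4, assignment="CH deformation"),
                BandSpec(1660, 20, 0.9, assignment="amide I"),
                BandSpec(2930, 28, 1.1, assignment="CH3 stretch"),
            ),
        ),
        ComponentSpectrum(
            "lipid",
            bands=(
                BandSpec(1096, 14, 0.35, assignment="chain C-C stretch"),
                BandSpec(1263, 16, 0.4, assignment="=C-H in-plane cis"),
                BandSpec(1303, 14, 0.8, assignment="CH2 twist"),
                BandSpec(1441, 16, 1.0, assignment="CH2 scissor"),
                BandSpec(1660, 18, 0.5, assignment="C=C cis stretch"),
                BandSpec(1740, 14, 0.45, assignment="ester C=O stretch"),
                BandSpec(2851, 22, 1.2, assignment="CH2 symmetric stretch"),
            ),
        ),
        ComponentSpectrum(
            "nucleic_acid",
            bands=(
                BandSpec(783, 13, 1.0, assignment="U/C/T ring breathing"),
                BandSpec(813, 13, 0.6, assignment="RNA O-P-O stretch"),
                BandSpec(830, 13, 0.5, assignment="DNA B-form O-P-O"),
                BandSpec(1096, 14, 0.8, assignment="DNA PO2 symmetric stretch"),
                BandSpec(1485, 16, 0.5, assignment="G/A ring"),
                BandSpec(1575, 16, 0.5, assignment="G/A ring"),
            ),
        ),
        ComponentSpectrum(
            "dox",
            bands=(
                BandSpec(1086, 14, 0.7, assignment="C-O of DOX"),
                BandSpec(1215, 14, 0.9, assignment="C-O-H of DOX"),
                BandSpec(1247, 14, 1.0, assignment="C-H of DOX"),
            ),
        ),
        # broad OH-bend continuum around 1640 plus the low-wavenumber wing
        # of the OH stretch entering the high-wavenumber window
        ComponentSpectrum(
            "water",
            broad_profile=((1640.0, 300.0, 1.0), (3080.0, 320.0, 1.4)),
        ),
        # dose-scaled drug fluorescence: gentle ramp plus a broad hump in
        # the fingerprint region
        ComponentSpectrum(
            "fluorescence",
            broad_profile=((1350.0, 1200.0, 1.0),),
            ramp=(0.3, 1.5e-4),
        ),
    ]
    return {c.name: c.evaluate(axis) for c in components}


# ----------------------------------------------------------------------
# population simulation
# ----------------------------------------------------------------------
def simulate_population(
    spec: PopulationSpec,
    components: dict[str, np.ndarray],
    axis: np.ndarray,
) -> tuple[SpectraSet, pd.DataFrame]:
    """Draw one well of single-cell spectra.

    Each non-empty row is
    ``gain * (mixture + fluorescence_scale*fluor + water_amplitude*water)
    + noise + spikes``; empty rows carry background only.  Cell-to-cell
    biological variability is modeled as Gaussian jitter on the
    composition weights (renormalized to the simplex), which is what
    concentrates spectral variance in the leading principal components
    the way real single-cell data do.  Returns the SpectraSet and a
    ground-truth table (label, gain, spike channels) aligned to its rows.
    Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    axis = np.asarray(axis, dtype=float)
    n = spec.n_cells

    comp_names = sorted(set(spec.composition_viable) | set(spec.composition_nonviable))
    missing = set(comp_names) - set(components)
    if missing:
        raise KeyError(f"unknown component name(s): {sorted(missing)}")
    comp_matrix = np.vstack([components[name] for name in comp_names])
    w_viable = np.array([spec.composition_viable.get(k, 0.0) for k in comp_names])
    w_nonviable = np.array(
        [spec.composition_nonviable.get(k, 0.0) for k in comp_names]
    )
    background = (
        spec.fluorescence_scale * components["fluorescence"]
        + spec.water_amplitude * components["water"]
    )

    is_empty = rng.random(n) < spec.empty_rate
    is_viable = rng.random(n) < spec.viable_fraction
    labels = np.where(is_empty, "empty", np.where(is_viable, "viable", "non_viable"))

    weights = np.where(is_viable[:, None], w_viable[None, :], w_nonviable[None, :])
    if spec.composition_jitter_sd > 0:
        weights = weights + rng.normal(
            0.0, spec.composition_jitter_sd, size=weights.shape
        )
        weights = np.clip(weights, 0.0, None)
        weights = weights / weights.sum(axis=1, keepdims=True)
    signal = np.where(is_empty[:, None], 0.0, weights @ comp_matrix)
    gains = (
        rng.normal(1.0, spec.gain_cv, size=n) if spec.gain_cv > 0 else np.ones(n)
    )
    gains = np.clip(gains, 0.1, None)
    intensities = gains[:, None] * (signal + background[None, :])
    if spec.noise_sd > 0:
        intensities = intensities + rng.normal(0.0, spec.noise_sd, size=intensities.shape)

    # cosmic spikes: Poisson count per spectrum, uniform channel, amplitude
    # 5-50x the local signal level
    spike_channels: list[list[int]] = []
    n_spikes = rng.poisson(spec.spike_rate, size=n) if spec.spike_rate > 0 else np.zeros(n, int)
    for i in range(n):
        chans = sorted(rng.integers(0, axis.size, size=n_spikes[i]).tolist())
        for ch in chans:
            local = max(abs(intensities[i, ch]), 10 * spec.noise_sd, 1e-6)
            intensities[i, ch] += rng.uniform(5.0, 50.0) * local
        spike_channels.append(chans)

    meta = pd.DataFrame(
        {
            "condition_label": spec.condition_label,
            "dose": spec.dose,
            "batch": spec.batch,
            "well": spec.well,
            "qc_flags": "",
            "ground_truth_label": labels,
        }
    )
    truth = pd.DataFrame(
        {
            "label": labels,
            "gain": gains,
            "n_spikes": n_spikes,
            "spike_channels": spike_channels,
        }
    )
    sset = SpectraSet(
        axis=axis,
        intensities=intensities,
        meta=meta,
        provenance=[
            {
                "op": "simulate",
                "params": {
                    "condition_label": spec.condition_label,
                    "dose": spec.dose,
                    "n_cells": n,
                    "seed": spec.seed,
                },
            }
        ],
    )
    return sset, truth


# ----------------------------------------------------------------------
# dose-ladder helper
# ----------------------------------------------------------------------
def default_compositions(dose: float) -> tuple[dict[str, float], dict[str, float]]:
    """Composition maps for viable and non-viable cells at a given dose.

    Viable cells under dose mildly gain lipid and lose nucleic acid;
    non-viable cells sit at a distinct protein/nucleic-acid balance and
    shift further along that direction with dose.  Drug weight grows with
    dose in both.  All maps renormalize to sum to 1.
    """
    d = min(dose, 1.0)
    viable = {
        "protein": 0.50,
        "lipid": 0.25 + 0.03 * d,
        "nucleic_acid": 0.25 - 0.03 * d,
        "dox": 0.0,
    }
    nonviable = {
        "protein": 0.34 - 0.02 * d,
        "lipid": 0.20,
        "nucleic_acid": 0.38 + 0.02 * d,
        "dox": 0.08,
    }

    def _norm(w: dict[str, float]) -> dict[str, float]:
        total = sum(w.values())
        return {k: v / total for k, v in w.items()}

    return _norm(viable), _norm(nonviable)


def logistic_viable_fractions(
    doses, ic50: float = 0.2, slope: float = 1.0, upper: float = 0.99, lower: float = 0.1
) -> np.ndarray:
    """Log-logistic dose->viable-fraction curve used to parameterize ladders."""
    doses = np.asarray(doses, dtype=float)
    frac = np.full_like(doses, upper)
    pos = doses > 0
    frac[pos] = lower + (upper - lower) / (1.0 + (doses[pos] / ic50) ** slope)
    return frac


def simulate_dose_ladder(
    doses,
    viable_fractions,
    n_cells_per_condition: int,
    axis: np.ndarray | None = None,
    components: dict[str, np.ndarray] | None = None,
    seed: int = 0,
    batch: str = "batch-1",
    fluorescence_per_um: float = 1.0,
    **spec_overrides,
) -> tuple[SpectraSet, pd.DataFrame, list[PopulationSpec]]:
    """Simulate a full dose ladder (one well per dose) and concatenate.

    Fluorescence amplitude scales linearly with dose.  Returns the merged
    SpectraSet, merged ground-truth table and the per-well specs used.
    """
    if axis is None:
        axis = make_axis(DEFAULT_PX_COUNT, DEFAULT_WL_COEFFS)
    if components is None:
        components = default_component_library(axis)
    doses = list(doses)
    viable_fractions = list(viable_fractions)
    if len(doses) != len(viable_fractions):
        raise ValueError("doses and viable_fractions must have equal length")

    sets, truths, specs = [], [], []
    for i, (dose, vf) in enumerate(zip(doses, viable_fractions)):
        comp_v, comp_nv = default_compositions(dose)
        label = "Control" if dose == 0 else f"{dose:g} uM"
        spec = PopulationSpec(
            condition_label=label,
            dose=dose,
            n_cells=n_cells_per_condition,
            viable_fraction=vf,
            composition_viable=comp_v,
            composition_nonviable=comp_nv,
            fluorescence_scale=fluorescence_per_um * dose,
            batch=batch,
            well=f"well-{i + 1}",
            seed=seed * 1009 + i,
            **spec_overrides,
        )
        sset, truth = simulate_population(spec, components, axis)
        sets.append(sset)
        truths.append(truth)
        specs.append(spec)

    merged = SpectraSet(
        axis=axis,
        intensities=np.vstack([s.intensities for s in sets]),
        meta=pd.concat([s.meta for s in sets], ignore_index=True),
        provenance=[
            {
                "op": "simulate",
                "params": {
                    "doses": [float(d) for d in doses],
                    "n_cells_per_condition": n_cells_per_condition,
                    "seed": seed,
                },
            }
        ],
    )
    return merged, pd.concat(truths, ignore_index=True), specs


# ----------------------------------------------------------------------
# calibration references
# ----------------------------------------------------------------------
def simulate_paracetamol(
    axis: np.ndarray, noise_sd: float = 0.0, seed: int = 0
) -> tuple[np.ndarray, list[float]]:
    """Reference spectrum with isolated bands at documented paracetamol
    positions; returns (spectrum, band centers actually hosted by the axis).

    Rejects axes too short to host at least 6 resolvable bands.
    """
    axis = np.asarray(axis, dtype=float)
    margin = 25.0
    centers = [
        c for c in PARACETAMOL_BANDS if axis[0] + margin <= c <= axis[-1] - margin
    ]
    if len(centers) < 6:
        raise ValueError(
            f"axis [{axis[0]:.0f}, {axis[-1]:.0f}] cm^-1 hosts only "
            f"{len(centers)} reference bands; need >= 6"
        )
    y = np.zeros_like(axis)
    for c in centers:
        y += BandSpec(c, 10.0, 1.0).evaluate(axis)
    if noise_sd > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_sd, size=y.shape)
    return y, centers


def simulate_lamp_pair(
    axis: np.ndarray, response: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """(measured lamp spectrum, true relative irradiance) pair.

    The true irradiance is a smooth broad positive curve; the measured
    spectrum is that curve times the instrument response (default: a
    smooth ramp 0.5 -> 1.5).  The response must be strictly positive.
    """
    axis = np.asarray(axis, dtype=float)
    t = (axis - axis[0]) / (axis[-1] - axis[0])
    true_irradiance = 1.0 + 0.6 * np.exp(-0.5 * ((t - 0.45) / 0.35) ** 2)
    if response is None:
        response = 0.5 + 1.0 * t
    response = np.asarray(response, dtype=float)
    if response.shape != axis.shape:
        raise ValueError("response must match the axis length")
    if np.any(response <= 0):
        raise ValueError("instrument response must be strictly positive")
    measured = true_irradiance * response
    return measured, true_irradiance


def render_to_pixels(
    wn_axis: np.ndarray,
    intensities: np.ndarray,
    coeffs,
    px_count: int,
    response: np.ndarray | None = None,
) -> np.ndarray:
    """Forward instrument model: sample wavenumber-domain spectra at the
    pixel grid's wavenumber positions and multiply by the response.

    The detector samples a physically continuous spectrum, so the
    wavenumber-domain rows are interpolated with a cubic spline rather
    than piecewise-linearly.  Used to produce raw detector frames for
    calibration round-trips.
    """
    from scipy.interpolate import CubicSpline

    native = make_axis(px_count, coeffs)
    if native[0] < wn_axis[0] - 1e-9 or native[-1] > wn_axis[-1] + 1e-9:
        raise ValueError("pixel axis maps outside the simulated wavenumber range")
    intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
    out = np.vstack(
        [CubicSpline(wn_axis, row)(native) for row in intensities]
    )
    if response is not None:
        response = np.asarray(response, dtype=float)
        if np.any(response <= 0):
            raise ValueError("instrument response must be strictly positive")
        out = out * response[None, :]
    return out
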