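import numpy as np
import pytest

from ramanviability import preprocess as pp
from ramanviability import synthdata as sd


@pytest.fixture(scope="session")
def axis():
    return sd.make_axis(sd.DEFAULT_PX_COUNT, sd.DEFAULT_WL_COEFFS)


@pytest.fixture(scope="session")
def library(axis):
    return sd.default_component_library(axis)


@pytest.fixture(scope="session")
def basis(axis, library):
    comp_v, _ = sd.default_compositions(0.0)
    reference = sum(w * library[name] for name, w in comp_v.items())
    return pp.EMSCBasis(
        axis,
        reference,
        {"water": library["water"], "fluorescence": library["fluorescence"]},
        poly_order=3,
    )


def clean_spec(**overrides):
    """PopulationSpec with all nuisance processes switched off unless
    overridden — the deterministic limit used by exact tests."""
    comp_v, comp_nv = sd.default_compositions(overrides.get("dose", 0.0))
    defaults = dict(
        condition_label="Control",
        dose=0.0,
        n_cells=8,
        viable_fraction=1.0,
        composition_viable=comp_v,
        composition_nonviable=comp_nv,
        fluorescence_scale=0.0,
        composition_jitter_sd=0.0,
        noise_sd=0.0,
        gain_cv=0.0,
        spike_rate=0.0,
        empty_rate=0.0,
        seed=0,
    )
    defaults.update(overrides)
    return sd.PopulationSpec(**defaults)


@pytest.fixture(scope="session")
def two_class_set(axis, library):
    """Moderate two-condition set (control + high dose) with default
    nuisance levels, plus its ground truth."""
    s, truth, _ = sd.simulate_dose_ladder(
        [0.0, 1.0], [0.99, 0.13], 300, axis=axis, components=library, seed=11
    )
    return s, truth
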