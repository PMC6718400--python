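"""Readers/writers and the end-to-end pipeline driver.

Spectra travel as TSV matrices (header row = axis values, one row per
cell) with a JSON metadata sidecar (one record per row).  A run is fully
described by a :class:`RunConfig`; ``run_pipeline`` executes simulate or
load -> preprocess -> PCA-SVM -> viability -> IC50 and returns a result
bundle, optionally writing JSON artifacts stamped with the config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from . import chemometrics, preprocess, synthdata, viability
from .datasets import dox_thp1_viability_table
from .preprocess import EMSCBasis, PreprocessParams, RegionSpec
from .spectra import SpectraSet

__all__ = ["read_spectra", "write_spectra", "RunConfig", "PipelineResult",
           "run_pipeline"]

log = logging.getLogger("ramanviability")


# ----------------------------------------------------------------------
# spectra I/O
# ----------------------------------------------------------------------
def write_spectra(s: SpectraSet, path, sidecar_path) -> None:
    """TSV matrix (header = axis) plus JSON sidecar (meta + provenance)."""
    frame = pd.DataFrame(s.intensities, columns=[repr(float(v)) for v in s.axis])
    frame.to_csv(path, sep="\t", index=False)
    sidecar = {
        "meta": json.loads(s.meta.to_json(orient="records")),
        "provenance": s.provenance,
    }
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))


def read_spectra(path, sidecar_path) -> SpectraSet:
    """Read a TSV spectra matrix and its JSON sidecar into a SpectraSet.

    Validates numeric cells (reported with row/column position), strictly
    increasing axis, and meta/matrix row-count agreement.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    try:
        axis = np.array([float(c) for c in raw.columns])
    except ValueError as exc:
        raise ValueError(f"non-numeric axis value in header: {exc}") from None
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        try:
            values[:, j] = raw[col].astype(float)
        except ValueError:
            for i, cell in enumerate(raw[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell at row {i}, column {j} ({cell!r})"
                    ) from None
            raise
    sidecar = json.loads(Path(sidecar_path).read_text())
    meta = pd.DataFrame(sidecar["meta"])
    if len(meta) != values.shape[0]:
        raise ValueError(
            f"sidecar has {len(meta)} records but matrix has "
            f"{values.shape[0]} rows"
        )
    return SpectraSet(
        axis=axis,
        intensities=values,
        meta=meta,
        provenance=list(sidecar.get("provenance", [])),
    )


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------
class SimulateConfig(BaseModel):
    """Dose ladder to synthesize when no input spectra are given."""

    model_config = ConfigDict(extra="forbid")

    doses: list[float] = [0.0, 0.05, 0.1, 0.5, 1.0]
    viable_fractions: list[float] = [0.99, 0.78, 0.69, 0.36, 0.13]
    n_cells_per_condition: int = 400
    batch: str = "batch-2"
    composition_jitter_sd: float = 0.05
    noise_sd: float = 1.5e-4
    gain_cv: float = 0.05
    spike_rate: float = 0.05
    empty_rate: float = 0.1


class StageParams(BaseModel):
    """Every preprocessing/chemometrics default, overridable per run."""

    model_config = ConfigDict(extra="forbid")

    spike_z_thresh: float = 8.0
    spike_window: int = 7
    sg_window: int = 9
    sg_polyorder: int = 3
    emsc_poly_order: int = 3
    b_ref_eps: float = 1e-6
    reject_rel_threshold: float = 0.05
    n_components: int = 2
    svm_C: float = 1.0
    svm_alpha_init: float = 0.5
    cv_folds: int = 10


class TrainingSelector(BaseModel):
    """Which conditions supply the labeled training split: one control
    and the highest-dose condition of one batch."""

    model_config = ConfigDict(extra="forbid")

    control_label: str = "Control"
    treated_label: str = "1 uM"
    batch: str = "batch-2"


class RunConfig(BaseModel):
    """Complete, serializable description of a pipeline run.

    Unknown keys are rejected so a config file cannot silently misspell a
    parameter.  A run is reproducible from (RunConfig, inputs) alone.
    """

    model_config = ConfigDict(extra="forbid")

    spectra_path: str | None = None
    sidecar_path: str | None = None
    basis_reference_path: str | None = None
    reference_table_path: str | None = None
    output_dir: str | None = None
    simulate: SimulateConfig | None = SimulateConfig()
    params: StageParams = StageParams()
    training: TrainingSelector = TrainingSelector()
    region_windows: list[list[float]] = [[615.0, 1800.0], [2790.0, 3010.0]]
    seed: int = 0

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """Everything one run produces."""

    spectra: SpectraSet
    pca: chemometrics.PCAModel
    svm: chemometrics.SVMModel
    prediction: chemometrics.ViabilityPrediction
    dose_response: viability.DoseResponseFit | None
    comparison: viability.AssayComparison | None
    reports: dict[str, Any]
    config_hash: str


# ----------------------------------------------------------------------
# pipeline
# ----------------------------------------------------------------------
def _obtain_input(config: RunConfig):
    if config.spectra_path is not None:
        if config.sidecar_path is None:
            raise ValueError("spectra_path requires sidecar_path")
        s = read_spectra(config.spectra_path, config.sidecar_path)
        return s, None
    if config.simulate is None:
        raise ValueError("either spectra_path or a simulate block is required")
    sim = config.simulate
    s, truth, _ = synthdata.simulate_dose_ladder(
        sim.doses,
        sim.viable_fractions,
        sim.n_cells_per_condition,
        seed=config.seed,
        batch=sim.batch,
        composition_jitter_sd=sim.composition_jitter_sd,
        noise_sd=sim.noise_sd,
        gain_cv=sim.gain_cv,
        spike_rate=sim.spike_rate,
        empty_rate=sim.empty_rate,
    )
    return s, truth


def _build_basis(config: RunConfig, s: SpectraSet) -> EMSCBasis:
    library = synthdata.default_component_library(s.axis)
    if config.basis_reference_path is not None:
        ref = np.loadtxt(config.basis_reference_path)
        if ref.shape != s.axis.shape:
            raise ValueError("basis reference spectrum is not on the data axis")
    else:
        comp_v, _ = synthdata.default_compositions(0.0)
        missing = set(comp_v) - set(library)
        if missing:
            raise ValueError(f"EMSC basis missing component(s): {sorted(missing)}")
        ref = sum(w * library[name] for name, w in comp_v.items())
    interferents = {"water": library["water"], "fluorescence": library["fluorescence"]}
    return EMSCBasis(
        s.axis, ref, interferents, poly_order=config.params.emsc_poly_order
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis chain described by ``config``.

    Stages: obtain input (load or simulate) -> preprocess -> PCA-SVM
    training on the configured conditions -> per-condition viability
    prediction -> IC50 fit -> optional comparison with a reference assay
    table.  Artifacts are written to ``output_dir`` when set, each file
    stamped with the config hash.
    """
    chash = config.config_hash()
    s, truth = _obtain_input(config)
    log.info("input: %d spectra, %d channels [%s]", s.n_spectra, s.n_channels, chash)

    basis = _build_basis(config, s)
    regions = RegionSpec(tuple(map(tuple, config.region_windows)))
    p = config.params
    pp = PreprocessParams(
        spike_z_thresh=p.spike_z_thresh,
        spike_window=p.spike_window,
        sg_window=p.sg_window,
        sg_polyorder=p.sg_polyorder,
        b_ref_eps=p.b_ref_eps,
        reject_rel_threshold=p.reject_rel_threshold,
    )
    clean, reports = preprocess.preprocess_pipeline(s, basis, regions, pp)
    for _, row in reports["rejection"].iterrows():
        if row["warning"]:
            log.warning("well %s: %s", row["well"], row["warning"])
    log.info(
        "preprocess: %d acquired, %d retained", s.n_spectra, clean.n_spectra
    )

    tmask, tlabels = chemometrics.training_split(
        clean, config.training.control_label, config.training.treated_label,
        config.training.batch,
    )
    train_set = clean.subset_rows(tmask, "training_split", {})
    pca, _ = chemometrics.fit_pca(
        SpectraSet(clean.axis, train_set.intensities, train_set.meta,
                   provenance=clean.provenance),
        n_components=p.n_components,
    )
    train_scores = chemometrics.pca_transform(pca, train_set.intensities)
    svm = chemometrics.train_svm(
        train_scores, tlabels, C=p.svm_C, alpha_init=p.svm_alpha_init
    )
    svm.cv_cost = chemometrics.crossval_cost(
        train_scores, tlabels, C=p.svm_C, folds=p.cv_folds, seed=config.seed
    )
    prediction = chemometrics.predict_viability(clean, pca, svm)

    per_cond = prediction.per_condition
    dose_response = None
    if np.unique(per_cond.loc[per_cond["dose"] > 0, "dose"]).size >= 3:
        doses, values = [], []
        for batch, grp in per_cond.groupby("batch"):
            ctrl = grp.loc[grp["dose"] == 0, "percent_viable"]
            if len(ctrl):
                doses.append(0.0)
                values.append(float(ctrl.mean()))
            treated = grp.loc[grp["dose"] > 0]
            doses.extend(treated["dose"].tolist())
            values.extend(treated["percent_viable"].tolist())
        dose_response = viability.fit_ic50(doses, values)

    comparison = None
    if config.reference_table_path is not None:
        ref = pd.read_csv(config.reference_table_path, sep="\t")
        comparison = viability.compare_assays(prediction, ref)
    elif truth is not None:
        # ground-truth viable fraction among classified (non-empty) cells
        frame = s.meta.copy()
        frame["label"] = truth["label"].to_numpy()
        rows = []
        for (cond, batch), grp in frame.groupby(["condition_label", "batch"],
                                                sort=False):
            cells = grp.loc[grp["label"] != "empty"]
            rows.append(
                {
                    "condition_label": cond,
                    "batch": batch,
                    "reference_percent": 100.0 * (cells["label"] == "viable").mean(),
                }
            )
        comparison = viability.compare_assays(prediction, pd.DataFrame(rows))

    result = PipelineResult(
        spectra=clean,
        pca=pca,
        svm=svm,
        prediction=prediction,
        dose_response=dose_response,
        comparison=comparison,
        reports=reports,
        config_hash=chash,
    )
    if config.output_dir is not None:
        _write_artifacts(result, config)
    return result


def _write_artifacts(result: PipelineResult, config: RunConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": result.config_hash}
    payload = {
        **stamp,
        "config": config.model_dump(),
        "pca": {
            "explained_variance_ratio":
                result.pca.explained_variance_ratio.tolist(),
            "n_components_kept": result.pca.n_components_kept,
        },
        "svm": {
            "weights": result.svm.weights.tolist(),
            "bias": result.svm.bias,
            "cv_cost": result.svm.cv_cost,
        },
        "per_condition": json.loads(
            result.prediction.per_condition.to_json(orient="records")
        ),
        "dose_response": None
        if result.dose_response is None
        else {
            "ic50": result.dose_response.ic50,
            "slope": result.dose_response.slope,
            "lower": result.dose_response.lower,
            "upper": result.dose_response.upper,
            "rss": result.dose_response.rss,
        },
        "comparison": None
        if result.comparison is None
        else json.loads(result.comparison.rows.to_json(orient="records")),
        "rejection": json.loads(
            result.reports["rejection"].to_json(orient="records")
        ),
        "provenance": result.spectra.provenance,
    }
    (out / "results.json").write_text(json.dumps(payload, indent=1))


def reference_table_for_simulation() -> pd.DataFrame:
    """The published assay table reshaped for compare_assays (per batch)."""
    table = dox_thp1_viability_table()
    return table[["condition_label", "batch", "reference_percent"]]
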