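"""PCA-SVM classification of viable vs non-viable cells.

Spectra are mean-centered and decomposed by SVD; a linear soft-margin SVM
is trained on the first two principal-component scores, its error
estimated by stratified 10-fold cross-validation, and the model applied
per condition/batch to estimate the viable percentage of each mixed
population.  Score-space geometry can be mapped back to spectra:
reconstructions from two components, and the family of spectra along a
line parallel to PC1 that crosses the decision boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .spectra import SpectraSet

__all__ = [
    "PCAModel",
    "SVMModel",
    "ViabilityPrediction",
    "BoundarySpectra",
    "fit_pca",
    "pca_transform",
    "train_svm",
    "crossval_cost",
    "predict_viability",
    "reconstruct_spectra",
    "boundary_spectra",
    "training_split",
]

VIABLE, NON_VIABLE = "viable", "non_viable"

#: preprocessing ops whose parameters must match between train and predict
_PIPELINE_OPS = (
    "remove_spikes",
    "emsc_correct",
    "smooth",
    "area_normalize",
    "select_regions",
    "reject_empty",
)


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------
@dataclass
class PCAModel:
    """Mean spectrum, orthonormal loadings (components x channels),
    explained-variance ratios and the preprocessing provenance of the
    training data (compared before prediction)."""

    mean_spectrum: np.ndarray
    loadings: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    n_components_kept: int
    train_provenance: list[dict[str, Any]] = field(default_factory=list)

    def __post_init__(self) -> None:
        gram = self.loadings @ self.loadings.T
        if not np.allclose(gram, np.eye(self.loadings.shape[0]), atol=1e-10):
            raise ValueError("loadings are not orthonormal")
        if np.any(np.diff(self.explained_variance_ratio) > 1e-12):
            raise ValueError("explained variance ratios must be non-increasing")


def _fix_loading_signs(loadings: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: the element of largest absolute
    value in each loading is positive."""
    signs = np.sign(loadings[np.arange(loadings.shape[0]),
                             np.argmax(np.abs(loadings), axis=1)])
    signs[signs == 0] = 1.0
    return loadings * signs[:, None]


def fit_pca(s: SpectraSet, n_components: int = 2) -> tuple[PCAModel, np.ndarray]:
    """Mean-centered SVD of the intensity matrix.

    Returns the model (keeping ``n_components``) and the score matrix of
    the training rows.  Loading signs follow the largest-element-positive
    convention so scores are reproducible across runs and platforms.
    """
    X = s.intensities
    n, p = X.shape
    if n < n_components + 1:
        raise ValueError("need at least n_components + 1 spectra")
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(rows-1, channels)="
            f"{min(n - 1, p)}"
        )
    mean = X.mean(axis=0)
    centered = X - mean
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    variances = svals**2 / (n - 1)
    total = variances.sum()
    ratios = variances / total if total > 0 else np.zeros_like(variances)
    loadings = _fix_loading_signs(vt[:n_components])
    model = PCAModel(
        mean_spectrum=mean,
        loadings=loadings,
        explained_variance=variances[:n_components],
        explained_variance_ratio=ratios[:n_components],
        n_components_kept=n_components,
        train_provenance=[e for e in s.provenance if e["op"] in _PIPELINE_OPS],
    )
    scores = centered @ loadings.T
    return model, scores


def pca_transform(pca: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project spectra onto the kept loadings using the training mean."""
    return (np.atleast_2d(X) - pca.mean_spectrum) @ pca.loadings.T


# ----------------------------------------------------------------------
# SVM
# ----------------------------------------------------------------------
@dataclass
class SVMModel:
    """Linear soft-margin SVM in principal-component score space.

    Decision function f(z) = weights . z + bias; f > 0 predicts viable.
    ``alpha_init`` records the dual-variable initialization convention of
    the original analysis environment; it is metadata, not behavior —
    any convergent solver yields the same hyperplane.
    """

    weights: np.ndarray
    bias: float
    regularization: float = 1.0
    alpha_init: float = 0.5
    classes: tuple[str, str] = (VIABLE, NON_VIABLE)
    cv_cost: float | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.linalg.norm(self.weights) == 0:
            raise ValueError("trained SVM has zero weight vector")
        if self.cv_cost is not None and not 0.0 <= self.cv_cost <= 1.0:
            raise ValueError("cv_cost must lie in [0, 1]")

    def decision_function(self, scores: np.ndarray) -> np.ndarray:
        return np.atleast_2d(scores) @ self.weights + self.bias

    def predict(self, scores: np.ndarray) -> np.ndarray:
        return np.where(self.decision_function(scores) > 0, VIABLE, NON_VIABLE)


def _encode(labels) -> np.ndarray:
    labels = np.asarray(labels)
    y = np.where(labels == VIABLE, 1, -1)
    bad = ~np.isin(labels, [VIABLE, NON_VIABLE])
    if bad.any():
        raise ValueError(f"unknown class labels: {sorted(set(labels[bad]))}")
    return y


def train_svm(
    train_scores: np.ndarray,
    train_labels,
    C: float = 1.0,
    alpha_init: float = 0.5,
    standardize: bool = True,
) -> SVMModel:
    """Train the linear soft-margin SVM on score-space points.

    Both classes must be present.  The sign convention (f > 0 => viable)
    is enforced regardless of label ordering.

    With ``standardize`` (default) each score column is divided by its
    training standard deviation before the QP is solved, so the box
    constraint C acts on a dimensionless margin regardless of the raw
    score magnitude; the fitted hyperplane is mapped back to raw-score
    units, so the returned model is a plain linear function of the scores
    either way.  ``standardize=False`` solves the QP on the scores as
    given (useful when comparing against an external dual solution).
    """
    scores = np.atleast_2d(np.asarray(train_scores, dtype=float))
    y = _encode(train_labels)
    if len(set(y)) < 2:
        raise ValueError("training data contains a single class")
    if standardize:
        scale = scores.std(axis=0)
        scale[scale == 0] = 1.0
    else:
        scale = np.ones(scores.shape[1])
    clf = SVC(kernel="linear", C=C, tol=1e-8)
    clf.fit(scores / scale, y)
    w = clf.coef_[0] / scale
    b = float(clf.intercept_[0])
    # sklearn orients the decision function toward classes_[1]; flip when
    # that class is -1 (non_viable) so f > 0 always means viable
    if clf.classes_[1] == -1:
        w, b = -w, -b
    return SVMModel(weights=w, bias=b, regularization=C, alpha_init=alpha_init)


def crossval_cost(
    train_scores: np.ndarray,
    train_labels,
    C: float = 1.0,
    folds: int = 10,
    seed: int = 0,
    standardize: bool = True,
) -> float:
    """Stratified k-fold cross-validated misclassification rate (pooled
    over folds), the "model cost" of the classifier."""
    scores = np.atleast_2d(np.asarray(train_scores, dtype=float))
    labels = np.asarray(train_labels)
    y = _encode(labels)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    counts = np.bincount((y + 1) // 2, minlength=2)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} members; cannot stratify "
            f"into {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errors = 0
    for train_idx, test_idx in skf.split(scores, y):
        model = train_svm(
            scores[train_idx], labels[train_idx], C=C, standardize=standardize
        )
        errors += int((model.predict(scores[test_idx]) != labels[test_idx]).sum())
    return errors / y.size


# ----------------------------------------------------------------------
# viability prediction
# ----------------------------------------------------------------------
@dataclass
class ViabilityPrediction:
    """Per-condition viable percentages plus the per-cell labels aligned
    to the SpectraSet rows they were computed from."""

    per_condition: pd.DataFrame
    per_cell: np.ndarray
    decision_values: np.ndarray


def _check_provenance(pca: PCAModel, s: SpectraSet) -> None:
    test = [e for e in s.provenance if e["op"] in _PIPELINE_OPS]
    train = pca.train_provenance
    for i, (a, b) in enumerate(zip(train, test)):
        if a["op"] != b["op"] or a["params"] != b["params"]:
            raise ValueError(
                f"preprocessing mismatch at step {i}: training ran "
                f"{a['op']}({a['params']}) but prediction input ran "
                f"{b['op']}({b['params']})"
            )
    if len(train) != len(test):
        longer = train if len(train) > len(test) else test
        raise ValueError(
            "preprocessing mismatch: step "
            f"{longer[min(len(train), len(test))]['op']!r} present on one "
            "side only"
        )


def predict_viability(
    s: SpectraSet, pca: PCAModel, svm: SVMModel
) -> ViabilityPrediction:
    """Classify every (non-rejected) row and aggregate percent viable per
    condition and batch.

    The input must have been preprocessed with the same chain as the
    training data; a divergent step is reported by name.
    """
    _check_provenance(pca, s)
    scores = pca_transform(pca, s.intensities)
    decisions = svm.decision_function(scores)
    labels = np.where(decisions > 0, VIABLE, NON_VIABLE)
    frame = s.meta[["condition_label", "dose", "batch"]].copy()
    frame["predicted"] = labels
    rows = []
    for (cond, dose, batch), grp in frame.groupby(
        ["condition_label", "dose", "batch"], sort=False
    ):
        n = len(grp)
        n_viable = int((grp["predicted"] == VIABLE).sum())
        rows.append(
            {
                "condition_label": cond,
                "dose": dose,
                "batch": batch,
                "n_cells": n,
                "n_viable_predicted": n_viable,
                "percent_viable": 100.0 * n_viable / n,
            }
        )
    return ViabilityPrediction(
        per_condition=pd.DataFrame(rows), per_cell=labels, decision_values=decisions
    )


def training_split(
    s: SpectraSet, control_label: str, treated_label: str, batch: str
) -> tuple[np.ndarray, np.ndarray]:
    """Condition-level training labels: rows of the control condition of
    one batch are labeled viable, rows of the high-dose condition
    non-viable (accepting the impurity of either population).  Returns
    (row mask, labels for the masked rows)."""
    meta = s.meta
    in_batch = meta["batch"].astype(str) == str(batch)
    is_ctrl = in_batch & (meta["condition_label"] == control_label)
    is_trt = in_batch & (meta["condition_label"] == treated_label)
    if not is_ctrl.any() or not is_trt.any():
        raise ValueError(
            f"training conditions {control_label!r}/{treated_label!r} not found "
            f"in batch {batch!r}"
        )
    mask = (is_ctrl | is_trt).to_numpy()
    labels = np.where(is_ctrl.to_numpy()[mask], VIABLE, NON_VIABLE)
    return mask, labels


# ----------------------------------------------------------------------
# reconstruction & boundary spectra
# ----------------------------------------------------------------------
def reconstruct_spectra(
    scores: np.ndarray, pca: PCAModel, add_mean: bool = False
) -> np.ndarray:
    """Map score-space points back to spectra: scores x loadings, with the
    dataset mean added only when requested."""
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[1] != pca.n_components_kept:
        raise ValueError(
            f"scores have {scores.shape[1]} columns; model keeps "
            f"{pca.n_components_kept} components"
        )
    out = scores @ pca.loadings
    if add_mean:
        out = out + pca.mean_spectrum
    return out


@dataclass
class BoundarySpectra:
    """Spectra reconstructed along a PC1-parallel line through score
    space, plus the analytically solved decision-boundary crossing."""

    line_scores: np.ndarray
    spectra: np.ndarray
    crossing_scores: np.ndarray
    threshold_spectrum: np.ndarray
    threshold_decision_value: float


def boundary_spectra(
    pca: PCAModel,
    svm: SVMModel,
    pc2_value: float,
    pc1_range: tuple[float, float],
    n_points: int = 9,
    add_mean: bool = False,
) -> BoundarySpectra:
    """Reconstruct spectra along the line PC2 = const, PC1 in range, and
    solve the boundary crossing w1*pc1 + w2*pc2 + b = 0 analytically.

    Errors if the line never crosses the decision boundary (w1 = 0 or the
    crossing lies outside the range).
    """
    if pca.n_components_kept != 2 or svm.weights.size != 2:
        raise ValueError("boundary spectra require a 2-component score space")
    w1, w2 = svm.weights
    if w1 == 0:
        raise ValueError("line parallel to the decision boundary: no crossing")
    pc1_cross = -(svm.bias + w2 * pc2_value) / w1
    lo, hi = pc1_range
    if not lo <= pc1_cross <= hi:
        raise ValueError(
            f"decision boundary crossing at PC1={pc1_cross:.4g} lies outside "
            f"the requested range [{lo}, {hi}]"
        )
    pc1 = np.linspace(lo, hi, n_points)
    line = np.column_stack([pc1, np.full(n_points, pc2_value)])
    crossing = np.array([pc1_cross, pc2_value])
    spectra = reconstruct_spectra(line, pca, add_mean)
    threshold = reconstruct_spectra(crossing[None, :], pca, add_mean)[0]
    return BoundarySpectra(
        line_scores=line,
        spectra=spectra,
        crossing_scores=crossing,
        threshold_spectrum=threshold,
        threshold_decision_value=float(svm.decision_function(crossing[None, :])[0]),
    )
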