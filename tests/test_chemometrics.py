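"""PCA-SVM contracts: decomposition oracles, SVM dual oracle,
cross-validation, viability aggregation, reconstruction and the
decision-boundary spectra."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from ramanviability import chemometrics as cm
from ramanviability import preprocess as pp
from ramanviability import synthdata as sd
from ramanviability.spectra import SpectraSet

from .conftest import clean_spec


def _random_set(n, p, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    axis = np.arange(p, dtype=float)
    return SpectraSet(axis, X, pd.DataFrame({"condition_label": ["x"] * n}))


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------
class TestPCA:
    def test_rank_one_data_explains_everything_with_first_component(self):
        rng = np.random.default_rng(1)
        direction = rng.normal(size=40)
        scores = rng.normal(size=(25, 1))
        X = scores @ direction[None, :]
        s = SpectraSet(np.arange(40.0), X,
                       pd.DataFrame({"condition_label": ["x"] * 25}))
        model, _ = cm.fit_pca(s, 1)
        assert model.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-10)

    def test_matches_covariance_eigendecomposition_oracle(self):
        """Scores and variances agree with an independent eigendecomposition
        of the sample covariance matrix (20 x 50 random data)."""
        s = _random_set(20, 50, seed=7)
        model, scores = cm.fit_pca(s, 5)
        X = s.intensities
        C = np.cov(X, rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        assert np.allclose(model.explained_variance, evals[:5], atol=1e-8)
        assert model.explained_variance_ratio == pytest.approx(
            evals[:5] / evals.sum(), abs=1e-8
        )
        centered = X - X.mean(axis=0)
        for k in range(5):
            oracle = centered @ evecs[:, k]
            # eigenvector sign is arbitrary; compare up to our convention
            sign = np.sign(evecs[np.argmax(np.abs(evecs[:, k])), k])
            assert np.allclose(scores[:, k], sign * oracle, atol=1e-8)

    def test_loadings_orthonormal_and_variances_ordered(self, two_class_set):
        s, _ = two_class_set
        basisless = pp.area_normalize(s)
        model, _ = cm.fit_pca(basisless, 4)
        gram = model.loadings @ model.loadings.T
        assert np.allclose(gram, np.eye(4), atol=1e-10)
        assert np.all(np.diff(model.explained_variance_ratio) <= 1e-12)

    def test_sign_convention_largest_element_positive(self):
        model, _ = cm.fit_pca(_random_set(30, 20, seed=3), 4)
        for row in model.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_component_count_validated(self):
        s = _random_set(5, 10)
        with pytest.raises(ValueError, match="n_components"):
            cm.fit_pca(s, 6)


# ----------------------------------------------------------------------
# SVM
# ----------------------------------------------------------------------
def _svm_dual_oracle(X, y, C=1.0):
    """Independent soft-margin linear SVM: solve the dual QP
    max sum(a) - 0.5 a'Q a, 0 <= a <= C, sum(a y) = 0 with SLSQP,
    then recover (w, b) from the KKT conditions."""
    n = len(y)
    Q = (y[:, None] * X) @ (y[:, None] * X).T

    def neg_dual(a):
        return -(a.sum() - 0.5 * a @ Q @ a)

    def neg_dual_grad(a):
        return -(np.ones(n) - Q @ a)

    cons = {"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y.astype(float)}
    res = minimize(
        neg_dual, np.full(n, C / 2), jac=neg_dual_grad,
        bounds=[(0.0, C)] * n, constraints=[cons], method="SLSQP",
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    a = res.x
    w = (a * y) @ X
    on_margin = (a > 1e-6 * C) & (a < C * (1 - 1e-6))
    if on_margin.any():
        b = np.mean(y[on_margin] - X[on_margin] @ w)
    else:
        # all multipliers at the bounds: the bias is only
        # interval-determined by the KKT conditions; take the midpoint
        f = X @ w
        lo, hi = -np.inf, np.inf
        for i in range(n):
            if y[i] > 0:
                lo, hi = (max(lo, 1 - f[i]), hi) if a[i] < 1e-6 * C else (
                    lo, min(hi, 1 - f[i]))
            else:
                lo, hi = (lo, min(hi, -1 - f[i])) if a[i] < 1e-6 * C else (
                    max(lo, -1 - f[i]), hi)
        b = (lo + hi) / 2
    return w, b


class TestSVM:
    def test_separable_clouds_zero_training_error(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(20, 2)) * 0.3 + [3.0, 0.0]
        b = rng.normal(size=(20, 2)) * 0.3 + [-3.0, 0.0]
        X = np.vstack([a, b])
        labels = np.array(["viable"] * 20 + ["non_viable"] * 20)
        model = cm.train_svm(X, labels)
        assert (model.predict(X) == labels).all()
        # boundary lies between the clouds
        crossing_x = -model.bias / model.weights[0]
        assert -2.0 < crossing_x < 2.0

    @pytest.mark.parametrize("seed,n", [(0, 24), (1, 40), (2, 30)])
    def test_decision_values_match_dual_qp_oracle(self, seed, n):
        """Plain (unstandardized) training agrees with an independent
        quadratic-program solution of the SVM dual to 1e-4."""
        rng = np.random.default_rng(seed)
        half = n // 2
        X = np.vstack([
            rng.normal(size=(half, 2)) + [1.2, 0.0],
            rng.normal(size=(n - half, 2)) - [1.2, 0.0],
        ])
        labels = np.array(["viable"] * half + ["non_viable"] * (n - half))
        y = np.where(labels == "viable", 1.0, -1.0)
        model = cm.train_svm(X, labels, C=1.0, standardize=False)
        w_oracle, b_oracle = _svm_dual_oracle(X, y, C=1.0)
        ours = model.decision_function(X)
        oracle = X @ w_oracle + b_oracle
        assert np.max(np.abs(ours - oracle)) < 1e-4

    def test_standardized_training_matches_qp_on_standardized_features(self):
        """The default standardizing path equals the QP oracle applied to
        SD-scaled features, mapped back to raw units."""
        rng = np.random.default_rng(9)
        X = np.vstack([
            rng.normal(size=(15, 2)) * [1e-3, 1e-2] + [2e-3, 0.0],
            rng.normal(size=(15, 2)) * [1e-3, 1e-2] - [2e-3, 0.0],
        ])
        labels = np.array(["viable"] * 15 + ["non_viable"] * 15)
        y = np.where(labels == "viable", 1.0, -1.0)
        scale = X.std(axis=0)
        model = cm.train_svm(X, labels, C=1.0, standardize=True)
        w_std, b_std = _svm_dual_oracle(X / scale, y, C=1.0)
        oracle = (X / scale) @ w_std + b_std
        assert np.max(np.abs(model.decision_function(X) - oracle)) < 1e-4

    def test_label_flip_negates_hyperplane(self):
        rng = np.random.default_rng(2)
        X = np.vstack([rng.normal(size=(12, 2)) + 1.5,
                       rng.normal(size=(12, 2)) - 1.5])
        labels = np.array(["viable"] * 12 + ["non_viable"] * 12)
        flipped = np.where(labels == "viable", "non_viable", "viable")
        m1 = cm.train_svm(X, labels)
        m2 = cm.train_svm(X, flipped)
        assert np.allclose(m1.weights, -m2.weights, atol=1e-8)
        assert m1.bias == pytest.approx(-m2.bias, abs=1e-8)

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(ValueError, match="single class"):
            cm.train_svm(X, ["viable"] * 10)


class TestCrossval:
    def test_separable_data_zero_cost_any_fold_count(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(size=(30, 2)) * 0.2 + [2, 0],
                       rng.normal(size=(30, 2)) * 0.2 - [2, 0]])
        labels = np.array(["viable"] * 30 + ["non_viable"] * 30)
        assert cm.crossval_cost(X, labels, folds=2, seed=0) == 0.0
        assert cm.crossval_cost(X, labels, folds=10, seed=0) == 0.0

    def test_cost_tracks_bayes_error_of_overlapping_gaussians(self):
        """Two spherical Gaussians with ||mu1-mu2|| = 2 * 1.645 * sigma have
        Bayes error Phi(-1.645) ~= 5%; the CV cost of the linear SVM lands
        within 2 points of that at n=2000."""
        from scipy.stats import norm

        delta = 2 * 1.645  # in units of sigma
        bayes = norm.cdf(-delta / 2)
        rng = np.random.default_rng(17)
        n = 1000
        X = np.vstack([
            rng.normal(size=(n, 2)) + [delta / 2, 0.0],
            rng.normal(size=(n, 2)) - [delta / 2, 0.0],
        ])
        labels = np.array(["viable"] * n + ["non_viable"] * n)
        cost = cm.crossval_cost(X, labels, folds=10, seed=1)
        assert abs(cost - bayes) < 0.02

    def test_fold_feasibility_validated(self):
        X = np.random.default_rng(0).normal(size=(12, 2))
        labels = np.array(["viable"] * 9 + ["non_viable"] * 3)
        with pytest.raises(ValueError, match="stratify"):
            cm.crossval_cost(X, labels, folds=5)


# ----------------------------------------------------------------------
# viability prediction
# ----------------------------------------------------------------------
def _trained_on(two_class_set, basis):
    s, truth = two_class_set
    clean, _ = pp.preprocess_pipeline(s, basis)
    mask, labels = cm.training_split(clean, "Control", "1 uM", "batch-1")
    train = SpectraSet(clean.axis, clean.intensities[mask],
                       clean.meta.loc[mask], provenance=list(clean.provenance))
    pca, _ = cm.fit_pca(train, 2)
    scores = cm.pca_transform(pca, train.intensities)
    svm = cm.train_svm(scores, labels)
    return clean, train, labels, pca, svm


class TestPredictViability:
    def test_self_consistency_with_training_labels(self, two_class_set, basis):
        clean, train, labels, pca, svm = _trained_on(two_class_set, basis)
        pred = cm.predict_viability(clean, pca, svm)
        cost = cm.crossval_cost(
            cm.pca_transform(pca, train.intensities), labels, seed=0
        )
        # percent viable on the training conditions within the CV cost of
        # the condition-label percentage
        table = pred.per_condition.set_index("condition_label")
        label_pct = 100.0 * (labels == "viable").mean()
        got_ctrl = table.loc["Control", "percent_viable"]
        got_trt = table.loc["1 uM", "percent_viable"]
        pooled = (got_ctrl + got_trt) / 2
        assert abs(pooled - label_pct) <= 100.0 * cost + 1.0

    def test_in_sample_predictions_equal_train_time_predictions(
        self, two_class_set, basis
    ):
        clean, train, labels, pca, svm = _trained_on(two_class_set, basis)
        pred = cm.predict_viability(clean, pca, svm)
        scores = cm.pca_transform(pca, clean.intensities)
        assert np.array_equal(pred.per_cell, svm.predict(scores))

    def test_all_viable_well_predicted_above_95(self, axis, library, basis):
        s, _ = sd.simulate_dose_ladder(
            [0.0, 1.0], [0.99, 0.13], 250, axis=axis, components=library, seed=5
        )[:2]
        clean, _ = pp.preprocess_pipeline(s, basis)
        mask, labels = cm.training_split(clean, "Control", "1 uM", "batch-1")
        train = SpectraSet(clean.axis, clean.intensities[mask],
                           clean.meta.loc[mask], provenance=list(clean.provenance))
        pca, _ = cm.fit_pca(train, 2)
        svm = cm.train_svm(cm.pca_transform(pca, train.intensities), labels)
        pure, _, _ = sd.simulate_dose_ladder(
            [0.0], [1.0], 300, axis=axis, components=library, seed=6
        )
        pure_clean, _ = pp.preprocess_pipeline(pure, basis)
        pred = cm.predict_viability(pure_clean, pca, svm)
        assert pred.per_condition.loc[0, "percent_viable"] >= 95.0

    def test_provenance_mismatch_names_divergent_step(self, two_class_set, basis):
        clean, _, _, pca, svm = _trained_on(two_class_set, basis)
        other = pp.RegionSpec(((700.0, 1700.0),))
        s, _ = two_class_set
        different, _ = pp.preprocess_pipeline(s, basis, regions=other)
        with pytest.raises(ValueError, match="area_normalize|select_regions"):
            cm.predict_viability(different, pca, svm)


# ----------------------------------------------------------------------
# reconstruction
# ----------------------------------------------------------------------
class TestReconstruction:
    def test_zero_scores_with_mean_give_mean_spectrum(self):
        model, _ = cm.fit_pca(_random_set(15, 30, seed=5), 2)
        out = cm.reconstruct_spectra(np.zeros((1, 2)), model, add_mean=True)
        assert np.allclose(out[0], model.mean_spectrum, atol=1e-12)

    def test_full_rank_reconstruction_is_identity(self):
        s = _random_set(12, 8, seed=6)
        model, scores = cm.fit_pca(s, 8)
        out = cm.reconstruct_spectra(scores, model, add_mean=True)
        assert np.allclose(out, s.intensities, atol=1e-10)

    def test_two_component_error_equals_discarded_variance(self):
        """Parseval: squared reconstruction error = (n-1) * sum of the
        variances of the discarded components (via an SVD oracle)."""
        s = _random_set(25, 40, seed=8)
        n = s.n_spectra
        X = s.intensities
        centered = X - X.mean(axis=0)
        svals = np.linalg.svd(centered, compute_uv=False)
        discarded = (svals[2:] ** 2).sum()

        model, scores = cm.fit_pca(s, 2)
        recon = cm.reconstruct_spectra(scores, model, add_mean=True)
        err = np.sum((recon - X) ** 2)
        assert err == pytest.approx(discarded, rel=1e-8)

    def test_dimension_mismatch_rejected(self):
        model, _ = cm.fit_pca(_random_set(15, 30), 2)
        with pytest.raises(ValueError, match="columns"):
            cm.reconstruct_spectra(np.zeros((1, 3)), model)


# ----------------------------------------------------------------------
# boundary spectra
# ----------------------------------------------------------------------
class TestBoundarySpectra:
    def _model(self, weights, bias):
        pca, _ = cm.fit_pca(_random_set(20, 30, seed=10), 2)
        svm = cm.SVMModel(weights=np.asarray(weights, float), bias=bias)
        return pca, svm

    def test_axis_aligned_crossing_is_closed_form(self):
        pca, svm = self._model([1.0, 0.0], 0.0)
        out = cm.boundary_spectra(pca, svm, pc2_value=0.7, pc1_range=(-1, 1),
                                  n_points=5)
        assert out.crossing_scores[0] == pytest.approx(0.0, abs=1e-12)
        assert out.threshold_decision_value == pytest.approx(0.0, abs=1e-10)

    def test_general_crossing_decision_value_zero(self):
        pca, svm = self._model([0.8, -0.3], 0.15)
        out = cm.boundary_spectra(pca, svm, pc2_value=0.4, pc1_range=(-5, 5))
        assert out.threshold_decision_value == pytest.approx(0.0, abs=1e-10)
        # reconstructed threshold spectrum projects back onto the boundary
        back = cm.pca_transform(pca, out.threshold_spectrum[None, :]
                                + pca.mean_spectrum)
        assert svm.decision_function(back)[0] == pytest.approx(0.0, abs=1e-8)

    def test_parallel_line_rejected(self):
        pca, svm = self._model([0.0, 1.0], 0.3)
        with pytest.raises(ValueError, match="parallel"):
            cm.boundary_spectra(pca, svm, pc2_value=0.0, pc1_range=(-1, 1))

    def test_line_sides_follow_class_mean_difference(self, two_class_set, basis):
        """Moving along the line from the non-viable to the viable side
        changes the reconstruction in the same direction as the
        (viable - non-viable) class-mean difference at discriminative
        channels."""
        clean, train, labels, pca, svm = _trained_on(two_class_set, basis)
        scores = cm.pca_transform(pca, train.intensities)
        mid_pc2 = scores[:, 1].mean()
        lo, hi = scores[:, 0].min(), scores[:, 0].max()
        out = cm.boundary_spectra(pca, svm, pc2_value=mid_pc2,
                                  pc1_range=(lo, hi), n_points=7)
        end_diff = out.spectra[-1] - out.spectra[0]
        if svm.decision_function(out.line_scores[-1:])[0] < 0:
            end_diff = -end_diff  # orient toward the viable side
        class_diff = (
            train.intensities[labels == "viable"].mean(axis=0)
            - train.intensities[labels == "non_viable"].mean(axis=0)
        )
        strong = np.abs(class_diff) > np.percentile(np.abs(class_diff), 90)
        agreement = np.sign(end_diff[strong]) == np.sign(class_diff[strong])
        assert agreement.mean() > 0.9
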