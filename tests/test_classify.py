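import numpy as np
import pandas as pd
import pytest

from chondrospec import (
    ConfusionMatrix,
    loocv,
    mahal_classify,
    mahal_fit,
    pca_fit,
    pca_transform,
    report,
    segmented_cv,
    truncate_percent,
)
from chondrospec.classify import ClassifyError, mahal_distances
from chondrospec.spectra import SpectrumSet, WavenumberGrid


def make_set(matrix, grades):
    grid = WavenumberGrid(600.0 + np.arange(matrix.shape[1]))
    manifest = pd.DataFrame(
        {
            "cell_id": [f"c{i}" for i in range(len(grades))],
            "specimen_id": "s",
            "grade": grades,
            "kind": "cell",
        }
    )
    return SpectrumSet(grid, matrix, manifest)


class TestPCA:
    def test_rank_one_data_explains_everything_on_pc1(self, rng):
        direction = rng.normal(size=40)
        X = np.outer(rng.normal(size=12), direction)
        model = pca_fit(X, n_components=3)
        np.testing.assert_allclose(
            model.explained_variance_fraction, [1.0, 0.0, 0.0], atol=1e-9
        )

    def test_duplication_invariance(self, rng):
        X = rng.normal(size=(15, 30))
        a = pca_fit(X, 3)
        b = pca_fit(np.vstack([X, X]), 3)
        np.testing.assert_allclose(a.loadings, b.loadings, atol=1e-8)
        np.testing.assert_allclose(
            a.explained_variance_fraction, b.explained_variance_fraction, atol=1e-9
        )

    def test_loadings_orthonormal(self, rng):
        X = rng.normal(size=(20, 50))
        model = pca_fit(X, 4)
        gram = model.loadings @ model.loadings.T
        np.testing.assert_allclose(gram, np.eye(4), atol=1e-9)

    def test_matches_covariance_eigendecomposition_oracle(self, rng):
        """Independent oracle: eigh of the scatter matrix XᶜᵀXᶜ."""
        X = rng.normal(size=(20, 50))
        model = pca_fit(X, 3)
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        evals, evecs = evals[::-1], evecs[:, ::-1]
        np.testing.assert_allclose(
            model.explained_variance_fraction, evals[:3] / evals.sum(), rtol=1e-9
        )
        for k in range(3):
            dot = abs(model.loadings[k] @ evecs[:, k])
            assert dot == pytest.approx(1.0, abs=1e-8)

    def test_matches_sklearn_cross_check(self, rng):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        X = rng.normal(size=(25, 60))
        model = pca_fit(X, 3)
        ref = sklearn_pca(n_components=3, svd_solver="full").fit(X)
        np.testing.assert_allclose(
            model.explained_variance_fraction, ref.explained_variance_ratio_, rtol=1e-9
        )
        for k in range(3):
            assert abs(model.loadings[k] @ ref.components_[k]) == pytest.approx(
                1.0, abs=1e-9
            )

    def test_sign_convention_largest_element_positive(self, rng):
        X = rng.normal(size=(20, 50))
        model = pca_fit(X, 3)
        for row in model.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ClassifyError):
            pca_fit(rng.normal(size=(3, 10)), 3)


class TestPCATransform:
    def test_mean_spectrum_maps_to_origin(self, rng):
        X = rng.normal(size=(10, 20))
        model = pca_fit(X, 2)
        np.testing.assert_allclose(
            pca_transform(model, model.mean_spectrum), 0.0, atol=1e-10
        )

    def test_loading_displacement_gives_unit_score(self, rng):
        X = rng.normal(size=(10, 20))
        model = pca_fit(X, 3)
        x = model.mean_spectrum + 2.0 * model.loadings[0]
        np.testing.assert_allclose(pca_transform(model, x), [2.0, 0.0, 0.0], atol=1e-9)

    def test_reconstruction_residual_orthogonal_to_loadings(self, rng):
        X = rng.normal(size=(10, 20))
        model = pca_fit(X, 3)
        x = rng.normal(size=20)
        score = pca_transform(model, x)
        recon = model.mean_spectrum + score @ model.loadings
        residual = x - recon
        np.testing.assert_allclose(model.loadings @ residual, 0.0, atol=1e-9)

    def test_grid_mismatch_rejected(self, rng):
        model = pca_fit(rng.normal(size=(10, 20)), 2)
        with pytest.raises(ClassifyError):
            pca_transform(model, np.zeros(21))


class TestMahalanobis:
    def test_centroids_recovered_from_separated_gaussians(self, rng):
        mus = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        scores = np.vstack([rng.normal(mu, 1.0, size=(200, 2)) for mu in mus])
        grades = np.repeat(["I", "II", "III"], 200)
        model = mahal_fit(scores, grades)
        np.testing.assert_allclose(model.centroids, mus, atol=0.25)

    def test_identity_covariance_reduces_to_euclidean(self, rng):
        """Unit-variance isotropic classes: Mahalanobis = Euclidean."""
        mus = np.array([[0.0, 0.0], [8.0, 0.0], [0.0, 8.0]])
        scores = np.vstack([rng.normal(mu, 1.0, size=(500, 2)) for mu in mus])
        grades = np.repeat(["I", "II", "III"], 500)
        model = mahal_fit(scores, grades, policy="pooled")
        pts = rng.normal(2.0, 3.0, size=(50, 2))
        d2 = mahal_distances(model, pts)
        eucl = ((pts[:, None, :] - model.centroids[None]) ** 2).sum(axis=2)
        # covariance ≈ I so distances agree within estimation error
        np.testing.assert_allclose(d2, eucl, rtol=0.15)

    def test_degenerate_class_still_yields_finite_distances(self):
        scores = np.array(
            [[0.0, 0.0]] * 6 + [[5.0, 1.0], [5.5, 0.5], [6.0, 1.5], [5.2, 0.8],
                                [5.8, 1.2], [5.1, 1.1]]
        )
        grades = np.array(["I"] * 6 + ["II"] * 6)
        model = mahal_fit(scores, grades, classes=("I", "II"))
        d2 = mahal_distances(model, np.array([[1.0, 1.0]]))
        assert np.all(np.isfinite(d2))

    def test_centroid_classifies_to_own_class(self, rng):
        scores = rng.normal(size=(60, 3)) + np.repeat(
            np.array([[0, 0, 0], [6, 0, 0], [0, 6, 0]]), 20, axis=0
        )
        grades = np.repeat(["I", "II", "III"], 20)
        model = mahal_fit(scores, grades)
        pred = mahal_classify(model, model.centroids)
        assert pred.tolist() == ["I", "II", "III"]

    def test_tie_breaks_toward_lower_grade(self):
        from chondrospec.classify import MahalanobisModel

        # exact tie by construction: identity covariances, symmetric
        # centroids, query at the midpoint
        model = MahalanobisModel(
            classes=("I", "II"),
            centroids=np.array([[0.0, 0.0], [2.0, 0.0]]),
            covariances=np.stack([np.eye(2), np.eye(2)]),
            covariance_policy="per_class",
        )
        assert mahal_classify(model, np.array([1.0, 0.0]))[0] == "I"

    def test_matches_brute_force_distance_loop(self, rng):
        """1000 random points vs an explicit per-point, per-class loop
        with np.linalg.inv."""
        mus = rng.normal(scale=4.0, size=(3, 3))
        scores = np.vstack([rng.normal(mu, 1.3, size=(80, 3)) for mu in mus])
        grades = np.repeat(["I", "II", "III"], 80)
        model = mahal_fit(scores, grades)
        pts = rng.normal(scale=5.0, size=(1000, 3))
        pred = mahal_classify(model, pts)
        inv = [np.linalg.inv(model.covariances[c]) for c in range(3)]
        for i in range(1000):
            d2 = [
                float((pts[i] - model.centroids[c]) @ inv[c] @ (pts[i] - model.centroids[c]))
                for c in range(3)
            ]
            assert pred[i] == model.classes[int(np.argmin(d2))]

    def test_absent_class_rejected(self, rng):
        scores = rng.normal(size=(10, 2))
        grades = np.array(["I"] * 10)
        with pytest.raises(ClassifyError, match="absent"):
            mahal_fit(scores, grades)


class TestCrossValidation:
    def _tiny_set(self, rng, spread=0.3):
        centers = {"I": [0, 0, 0, 0], "II": [6, 0, 0, 0], "III": [0, 6, 0, 0]}
        rows, grades = [], []
        for g, mu in centers.items():
            for _ in range(2):
                rows.append(np.asarray(mu, dtype=float) + rng.normal(0, spread, 4))
                grades.append(g)
        return make_set(np.vstack(rows), grades)

    def test_separable_classes_give_diagonal_matrix(self, rng):
        X = np.vstack(
            [np.add(rng.normal(0, 0.05, size=(8, 6)), mu)
             for mu in (np.r_[0, 0, 0, 0, 0, 0], np.r_[9, 0, 0, 0, 0, 0],
                        np.r_[0, 9, 0, 0, 0, 0])]
        )
        sset = make_set(X, ["I"] * 8 + ["II"] * 8 + ["III"] * 8)
        cm = loocv(sset, n_components=2)
        np.testing.assert_array_equal(cm.counts, np.diag([8, 8, 8]))

    def test_loocv_matches_hand_enumerated_folds(self, rng):
        """Six spectra, two per class: explicit enumeration of all six
        hold-one-out folds using the public fit/transform pieces."""
        sset = self._tiny_set(rng)
        cm = loocv(sset, n_components=2)

        classes = ("I", "II", "III")
        grades = sset.grades.to_numpy()
        counts = np.zeros((3, 3), dtype=int)
        for i in range(6):
            mask = np.ones(6, dtype=bool)
            mask[i] = False
            pca = pca_fit(sset.matrix[mask], 2)
            model = mahal_fit(
                pca_transform(pca, sset.matrix[mask]), grades[mask],
                "per_class", classes,
            )
            pred = mahal_classify(model, pca_transform(pca, sset.matrix[i]))[0]
            counts[classes.index(grades[i]), classes.index(pred)] += 1
        np.testing.assert_array_equal(cm.counts, counts)

    def test_segment_size_one_equals_loocv(self, rng):
        X = rng.normal(size=(12, 8)) + np.repeat(
            np.array([[0] * 8, [4] * 8, [8] * 8]), 4, axis=0
        )
        sset = make_set(X, ["I"] * 4 + ["II"] * 4 + ["III"] * 4)
        np.testing.assert_array_equal(
            segmented_cv(sset, segment_size=1, n_components=2).counts,
            loocv(sset, n_components=2).counts,
        )

    def test_fold_arithmetic(self, rng):
        # interleaved grades so every 10-spectrum fold keeps both classes
        # represented in its training split
        offsets = np.tile(np.repeat([[0.0] * 10, [10.0] * 10], 1, axis=0), (10, 1))
        X = rng.normal(size=(20, 10)) + offsets
        sset = make_set(X, ["I", "II"] * 10)
        cm = segmented_cv(sset, segment_size=10, n_components=2)
        assert cm.total == 20  # 2 folds × 10 spectra, all classified once

    def test_row_sums_equal_class_counts(self, rng):
        sset = self._tiny_set(rng)
        cm = loocv(sset, n_components=2)
        np.testing.assert_array_equal(cm.row_sums(), [2, 2, 2])

    def test_oversized_segment_rejected(self, rng):
        sset = self._tiny_set(rng)
        with pytest.raises(ClassifyError):
            segmented_cv(sset, segment_size=6)


class TestReport:
    def test_perfect_classifier_all_rates_100(self):
        cm = ConfusionMatrix(("I", "II", "III"), np.diag([150, 150, 150]))
        rep = report(cm)
        assert rep.overall_percent == 100.0
        for f in ("recall", "precision", "specificity", "npv"):
            assert rep.percent(f) == [100.0, 100.0, 100.0]

    def test_never_predicted_class_has_nan_precision(self):
        cm = ConfusionMatrix(("I", "II"), np.array([[5, 0], [5, 0]]))
        rep = report(cm)
        assert np.isnan(rep.precision[1])
        assert rep.overall_efficiency == 0.5

    def test_truncation_not_rounding(self):
        # 92.29…% truncates to 92.2, would round to 92.3
        assert truncate_percent(0.92299) == 92.2
        assert truncate_percent(415 / 450) == 92.2
        assert truncate_percent(1.0) == 100.0

    def test_empty_actual_class_rejected(self):
        cm = ConfusionMatrix(("I", "II"), np.array([[3, 1], [0, 0]]))
        with pytest.raises(ClassifyError):
            report(cm)
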