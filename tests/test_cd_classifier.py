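"""Covariant discriminant: fitting, Mahalanobis scores, prediction, I/O."""

import numpy as np
import pytest

import nucphyschem as npc
from nucphyschem.cd_classifier import (
    discriminant,
    fit,
    load_model,
    mahalanobis_sq,
    predict,
    predict_batch,
    save_model,
)
from nucphyschem.encoding import FeatureMatrix


def _matrix(Xp, Xn):
    Xp, Xn = np.asarray(Xp, float), np.asarray(Xn, float)
    return FeatureMatrix(
        X=np.vstack([Xp, Xn]),
        y=np.r_[np.ones(len(Xp), bool), np.zeros(len(Xn), bool)],
    )


class TestFit:
    def test_mean_is_midpoint_and_cov_unbiased(self):
        m = _matrix([[0, 0], [2, 2]], [[5, 5], [7, 7]])
        model = fit(m)
        np.testing.assert_allclose(model.positive.mean, [1, 1])
        # hand sum: (0-1)^2 + (2-1)^2 = 2, divided by N-1 = 1
        assert model.positive.covariance[0, 0] == pytest.approx(
            2.0 + model.positive.ridge_used
        )

    def test_duplicate_feature_columns_trigger_recorded_ridge(self, rng):
        base = rng.normal(size=(20, 2))
        X = np.hstack([base, base[:, :1]])  # third column duplicates the first
        m = FeatureMatrix(X=np.vstack([X, X + 5]),
                          y=np.r_[np.ones(20, bool), np.zeros(20, bool)])
        model = fit(m)
        assert model.positive.ridge_used > 0
        # regularized covariance is positive definite
        assert np.linalg.eigvalsh(model.positive.covariance).min() > 0

    def test_precision_times_covariance_is_identity(self, rng):
        m = _matrix(rng.normal(size=(50, 4)), rng.normal(size=(50, 4)) + 1)
        model = fit(m)
        np.testing.assert_allclose(
            model.positive.precision @ model.positive.covariance,
            np.eye(4), atol=1e-8,
        )

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            fit(_matrix([[1, 2]], [[0, 0], [1, 1]]))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            fit(_matrix([[1, np.nan], [2, 3]], [[0, 0], [1, 1]]))

    def test_feature_subset_projection(self, rng):
        m = _matrix(rng.normal(size=(30, 6)), rng.normal(size=(30, 6)))
        model = fit(m, feature_index=[1, 3, 5])
        assert model.dim == 3
        np.testing.assert_allclose(model.positive.mean,
                                   m.X[m.y][:, [1, 3, 5]].mean(axis=0))


class TestMahalanobis:
    def test_zero_at_own_mean(self, rng):
        m = _matrix(rng.normal(size=(30, 3)), rng.normal(size=(30, 3)))
        model = fit(m)
        assert mahalanobis_sq(model.positive.mean, model.positive) == pytest.approx(0.0)

    def test_identity_covariance_reduces_to_squared_euclid(self):
        cm = fit(_matrix(np.eye(4)[:, :2] * 0, np.ones((2, 2)))).positive
        # build an explicit identity-covariance class model instead
        cm.mean[:] = 0
        cm.precision[:] = np.eye(2)
        cm.covariance[:] = np.eye(2)
        assert mahalanobis_sq(np.array([3.0, 4.0]), cm) == pytest.approx(25.0)

    def test_matches_brute_force_triple_product(self, rng):
        m = _matrix(rng.normal(size=(40, 3)), rng.normal(size=(40, 3)))
        cm = fit(m).positive
        x = rng.normal(size=3)
        d = x - cm.mean
        brute = sum(d[i] * cm.precision[i, j] * d[j]
                    for i in range(3) for j in range(3))
        ours = mahalanobis_sq(x, cm)
        assert ours == pytest.approx(brute, rel=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        cm = fit(_matrix(rng.normal(size=(10, 3)), rng.normal(size=(10, 3)))).positive
        with pytest.raises(ValueError, match="dimension"):
            mahalanobis_sq(np.zeros(4), cm)

    def test_nonnegative_everywhere(self, rng):
        m = _matrix(rng.normal(size=(25, 5)), rng.normal(size=(25, 5)))
        cm = fit(m).positive
        for _ in range(50):
            assert mahalanobis_sq(rng.normal(size=5), cm) >= 0


class TestDiscriminant:
    def _identity_model(self, mean, scale=1.0):
        d = len(mean)
        cm = fit(_matrix(np.random.default_rng(0).normal(size=(10, d)),
                         np.random.default_rng(1).normal(size=(10, d)))).positive
        cm.mean[:] = mean
        cm.covariance[:] = scale * np.eye(d)
        cm.precision[:] = np.eye(d) / scale
        object.__setattr__(cm, "log_det", float(d * np.log(scale)))
        return cm

    def test_identity_covariance_is_euclid_plus_zero(self):
        cm = self._identity_model([0.0, 0.0])
        assert discriminant(np.array([3.0, 4.0]), cm) == pytest.approx(25.0)

    def test_scaled_identity_at_mean_is_logdet(self):
        cm = self._identity_model([1.0, -1.0], scale=2.0)
        assert discriminant(np.array([1.0, -1.0]), cm) == pytest.approx(2 * np.log(2))

    def test_logdet_grows_with_covariance_scale(self):
        a = self._identity_model([0.0, 0.0], scale=1.0)
        b = self._identity_model([0.0, 0.0], scale=3.0)
        x = np.zeros(2)
        assert discriminant(x, b) > discriminant(x, a)


class TestPredict:
    def _toy_model(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.normal(size=(200, 2)) * 0.1 + [1, 0],
                    rng.normal(size=(200, 2)) * 0.1 + [-1, 0])
        return fit(m)

    def test_nearer_mean_wins_with_similar_covariances(self):
        model = self._toy_model()
        assert predict(np.array([0.9, 0.0]), model).label == "nucleosome"
        assert predict(np.array([-0.9, 0.0]), model).label == "linker"

    def test_margin_sign_matches_label(self):
        model = self._toy_model()
        p = predict(np.array([0.9, 0.0]), model)
        assert p.margin > 0
        n = predict(np.array([-0.9, 0.0]), model)
        assert n.margin < 0

    def test_exact_tie_goes_to_nucleosome(self):
        model = self._toy_model()
        # force symmetric classes so the midpoint is an exact tie
        model.negative.mean[:] = -model.positive.mean
        model.negative.covariance[:] = model.positive.covariance
        model.negative.precision[:] = model.positive.precision
        object.__setattr__(model.negative, "log_det", model.positive.log_det)
        p = predict(np.zeros(2), model)
        assert p.margin == pytest.approx(0.0)
        assert p.label == "nucleosome"

    def test_batch_agrees_with_scalar_path(self, rng):
        model = self._toy_model()
        X = rng.normal(size=(20, 2))
        labels, margins = predict_batch(X, model)
        for i in range(20):
            p = predict(X[i], model)
            assert (p.label == "nucleosome") == labels[i]
            assert p.margin == pytest.approx(margins[i], rel=1e-9)

    def test_invariant_under_common_invertible_linear_map(self, rng):
        Xp = rng.normal(size=(60, 3)) + [1, 0, 0]
        Xn = rng.normal(size=(60, 3)) - [1, 0, 0]
        T = rng.normal(size=(3, 3)) + 3 * np.eye(3)  # well-conditioned map
        test = rng.normal(size=(40, 3))
        base, _ = predict_batch(test, fit(_matrix(Xp, Xn)))
        mapped, _ = predict_batch(test @ T, fit(_matrix(Xp @ T, Xn @ T)))
        assert np.mean(base == mapped) >= 0.95  # loose: finite-precision effects


class TestOracleEquivalence:
    def test_matches_equal_prior_qda_on_gaussian_draws(self, rng):
        from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis

        Xp = rng.normal(size=(500, 5)) @ np.diag([1, 2, 1, 0.5, 1]) + 1
        Xn = rng.normal(size=(500, 5)) - 0.5
        m = _matrix(Xp, Xn)
        model = fit(m)
        assert model.positive.ridge_used == 0.0
        ours, _ = predict_batch(m.X, model)
        q = QuadraticDiscriminantAnalysis(priors=[0.5, 0.5]).fit(m.X, m.y.astype(int))
        np.testing.assert_array_equal(ours, q.predict(m.X).astype(bool))


class TestParameterRecovery:
    def test_error_shrinks_with_sample_size(self):
        mu = np.array([0.5, -0.3, 1.0])
        cov = np.array([[1.0, 0.3, 0.0], [0.3, 1.0, 0.2], [0.0, 0.2, 0.5]])
        errs = []
        for n, seed in ((100, 1), (10_000, 2)):
            rng = np.random.default_rng(seed)
            Xp = rng.multivariate_normal(mu, cov, size=n)
            Xn = rng.multivariate_normal(-mu, cov, size=n)
            model = fit(_matrix(Xp, Xn))
            errs.append(
                np.linalg.norm(model.positive.mean - mu)
                + np.linalg.norm(model.positive.covariance - cov)
            )
        assert errs[1] < errs[0] / 3


class TestSerialization:
    def test_round_trip_exact(self, tmp_path, trained_model, separable_seq_matrix):
        path = tmp_path / "model.npz"
        save_model(trained_model, path, table_checksum="abc123")
        back = load_model(path)
        np.testing.assert_array_equal(back.feature_index, trained_model.feature_index)
        for attr in ("mean", "covariance", "precision"):
            np.testing.assert_array_equal(
                getattr(back.positive, attr), getattr(trained_model.positive, attr)
            )
        assert back.positive.log_det == trained_model.positive.log_det
        assert back.negative.ridge_used == trained_model.negative.ridge_used
        # identical predictions after round trip
        X = separable_seq_matrix.X[:, trained_model.feature_index]
        a, am = predict_batch(X, trained_model)
        b, bm = predict_batch(X, back)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(am, bm)

    def test_unrecognized_format_rejected(self, tmp_path):
        path = tmp_path / "junk.npz"
        np.savez(path, meta=np.array('{"format": "other"}'))
        with pytest.raises(ValueError, match="format"):
            load_model(path)
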