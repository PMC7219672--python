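import numpy as np
import pytest

from fracfall.classify import (
    FD_SENTINEL,
    FeatureVector,
    LDAModel,
    assemble_features,
    cross_validate,
    discriminant,
    evaluate,
    predict,
    train_lda,
)
from fracfall.dwt import multilevel_dwt
from fracfall.fractal import wavelet_fractal_dimensions
from fracfall.pipeline import features_for_window
from fracfall.preprocess import make_windowed_signal


def blobs(n=200, sep=3.0, dim=2, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(size=(n, dim)) - sep / 2
    X1 = rng.normal(size=(n, dim)) + sep / 2
    return np.vstack([X0, X1]), np.r_[np.zeros(n, int), np.ones(n, int)]


class TestAssembleFeatures:
    def test_vector_has_fixed_order_and_dimension(self, rng):
        w = rng.normal(loc=1.0, size=128)
        win = make_windowed_signal(w)
        dec = multilevel_dwt(win.a)
        frac = wavelet_fractal_dimensions(dec, win.var_a)
        fv = assemble_features(win, dec, frac)
        arr = fv.to_array()
        assert arr.shape == (14,)
        np.testing.assert_array_equal(arr[:8], dec.approximations[-1])
        assert arr[8] == win.mu_a_prime
        assert arr[9] == win.var_a_prime
        np.testing.assert_array_equal(arr[10:], frac.fd)

    def test_constant_window_gets_sentinels(self):
        # the DWT runs on the zero-meaned window, so A4 vanishes and the
        # window's level is carried by the mean feature alone
        fv = features_for_window(np.full(128, 2.0))
        np.testing.assert_allclose(fv.a4, 0.0, atol=1e-12)
        assert fv.mu == pytest.approx(2.0)
        assert (fv.fd == FD_SENTINEL).all()
        assert fv.fd_undefined.all()

    def test_sd_toggle(self, rng):
        w = rng.normal(loc=1.0, size=128)
        fv_var = features_for_window(w)
        fv_sd = features_for_window(w, use_sd=True)
        assert fv_sd.var == pytest.approx(np.sqrt(fv_var.var))

    def test_wrong_window_length_rejected(self, rng):
        win = make_windowed_signal(rng.normal(size=128))
        dec = multilevel_dwt(rng.normal(size=64), levels=4)
        frac = wavelet_fractal_dimensions(dec, 1.0)
        with pytest.raises(ValueError, match="4-level decomposition"):
            assemble_features(win, dec, frac)


class TestLDA:
    def test_separable_blobs_trained_accurately(self):
        X, y = blobs(sep=6.0)
        model = train_lda(X, y)
        acc = np.mean(predict(model, X) == y)
        assert acc >= 0.99

    def test_identical_distributions_near_chance(self):
        accs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(400, 4))
            y = np.r_[np.zeros(200, int), np.ones(200, int)]
            model = train_lda(X, y)
            accs.append(np.mean(predict(model, X) == y))
        assert np.mean(accs) == pytest.approx(0.5, abs=0.1)

    def test_weights_match_closed_form_direction(self):
        """On a diagonal-covariance problem w ∝ Σ⁻¹Δμ analytically."""
        rng = np.random.default_rng(3)
        scales = np.array([1.0, 2.0, 0.5, 4.0])
        delta = np.array([1.0, -0.5, 2.0, 0.25])
        X0 = rng.normal(size=(4000, 4)) * scales
        X1 = rng.normal(size=(4000, 4)) * scales + delta
        model = train_lda(np.vstack([X0, X1]), np.r_[np.zeros(4000), np.ones(4000)])
        analytic = delta / scales**2
        cos = model.weights @ analytic / (
            np.linalg.norm(model.weights) * np.linalg.norm(analytic)
        )
        assert cos >= 0.99

    def test_matches_sklearn_oracle(self):
        sk = pytest.importorskip("sklearn.discriminant_analysis")
        X, y = blobs(sep=2.0, dim=5, seed=7)
        model = train_lda(X, y)
        ref = sk.LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        np.testing.assert_array_equal(predict(model, X), ref.predict(X))

    def test_boundary_is_inclusive_fall(self):
        X, y = blobs(sep=4.0)
        model = train_lda(X, y)
        # construct a point exactly on the boundary: w·x + b = 0
        x0 = -model.bias * model.weights / (model.weights @ model.weights)
        assert discriminant(model, x0) == pytest.approx(0.0, abs=1e-9)
        assert predict(model, x0[None, :])[0] == 1

    def test_affine_rescaling_invariance(self):
        """Predictions are unchanged by a common affine feature rescaling
        applied at both train and predict time."""
        X, y = blobs(sep=2.0, dim=5, seed=11)
        scale, shift = 3.7, -2.0
        m1 = train_lda(X, y)
        m2 = train_lda(X * scale + shift, y)
        np.testing.assert_array_equal(
            predict(m1, X), predict(m2, X * scale + shift)
        )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_lda(np.zeros((10, 3)), np.zeros(10, int))

    def test_dimension_mismatch_rejected(self):
        X, y = blobs()
        model = train_lda(X, y)
        with pytest.raises(ValueError, match="dimension"):
            discriminant(model, np.zeros(5))

    def test_json_round_trip(self, tmp_path):
        X, y = blobs(dim=14)
        model = train_lda(X, y)
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = LDAModel.from_json(path)
        np.testing.assert_allclose(loaded.weights, model.weights)
        assert loaded.bias == pytest.approx(model.bias)
        np.testing.assert_array_equal(predict(loaded, X), predict(model, X))


class TestEvaluate:
    def test_all_correct(self):
        m = evaluate([1, 0, 1], [1, 0, 1])
        assert m.accuracy == 1.0 and m.tp == 2 and m.tn == 1

    def test_hand_confusion_arithmetic(self):
        truth = [1] * 10 + [0] * 10
        preds = [1] * 9 + [0] + [1] * 2 + [0] * 8
        m = evaluate(preds, truth)
        assert (m.tp, m.fn, m.tn, m.fp) == (9, 1, 8, 2)
        assert m.sensitivity == pytest.approx(0.9)
        assert m.specificity == pytest.approx(0.8)
        assert m.accuracy == pytest.approx(0.85)
        assert m.precision == pytest.approx(9 / 11)

    def test_no_positives_sensitivity_missing(self):
        m = evaluate([0, 0], [0, 0])
        assert m.sensitivity is None
        assert m.accuracy == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            evaluate([1], [1, 0])


class TestCrossValidation:
    def test_stratified_folds_cover_data_once(self):
        from fracfall.classify import stratified_kfold_indices

        y = np.r_[np.zeros(37, int), np.ones(63, int)]
        folds = stratified_kfold_indices(y, k=5, seed=1)
        seen = np.concatenate([test for _, test in folds])
        assert sorted(seen) == list(range(100))
        for train, test in folds:
            assert set(train) | set(test) == set(range(100))
            assert not set(train) & set(test)
            # stratification keeps both classes in every fold
            assert 0 < y[test].mean() < 1

    def test_cross_validate_on_separable_data(self):
        X, y = blobs(sep=6.0)
        cv = cross_validate(X, y, k=5, seed=0)
        assert cv["mean_accuracy"] >= 0.98
        assert len(cv["fold_accuracies"]) == 5
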