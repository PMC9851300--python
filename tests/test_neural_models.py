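"""Network training contracts: preprocessing, determinism, persistence
and prediction conventions.  Tiny configurations keep these fast; the
full-scale learnability checks live in the acceptance suite."""

import numpy as np
import pytest

from ltrnet.kmer_conv import N_KMERS
from ltrnet.neural_models import (
    ClassifierConfig,
    DEFAULT_LINEAGES,
    DetectorConfig,
    FeaturePreprocessor,
    FilterConfig,
    ModelBundle,
    detect_windows,
    fit_preprocessor,
    predict_element,
    train_classifier,
    train_detector,
    train_filter,
)

TINY_DET = DetectorConfig(
    window_size=300, conv_filters=(4, 4, 4), kernel=5, pool=3,
    dense=(16, 8), epochs=3, batch_size=8,
)
TINY_FNN = FilterConfig(hidden=(16, 16, 16), epochs=10, batch_size=16)


def _toy_windows(n=24, rng=None):
    rng = rng or np.random.default_rng(0)
    X = np.zeros((n, 5, 300), dtype=np.float32)
    rows = rng.integers(0, 4, size=(n, 300))
    X[np.arange(n)[:, None].repeat(300, 1), rows, np.arange(300)[None, :].repeat(n, 0)] = 1
    y = rng.integers(0, 2, size=n)
    y[:2] = [0, 1]  # guarantee both classes
    return X, y


class TestPreprocessor:
    def test_transform_is_centred_and_scaled(self):
        rng = np.random.default_rng(1)
        X = rng.random((50, 40))
        pre = FeaturePreprocessor(n_components=5).fit(X)
        Z = pre.transform(X)
        assert np.allclose(Z.mean(axis=0), 0, atol=1e-6)
        assert np.allclose(Z.std(axis=0), 1, atol=1e-6)

    def test_too_many_components_rejected(self):
        with pytest.raises(ValueError, match="n_components"):
            FeaturePreprocessor(n_components=60).fit(np.zeros((10, 40)))

    def test_unfitted_transform_rejected(self):
        with pytest.raises(RuntimeError):
            FeaturePreprocessor().transform(np.zeros((2, 40)))

    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        X = rng.random((30, 20))
        pre = fit_preprocessor(X, n_components=4)
        pre.save(tmp_path / "pre.npz")
        loaded = FeaturePreprocessor.load(tmp_path / "pre.npz")
        assert np.array_equal(pre.transform(X), loaded.transform(X))


class TestTrainingContracts:
    def test_single_class_detector_rejected(self):
        X, _ = _toy_windows()
        with pytest.raises(ValueError, match="degenerate"):
            train_detector(X, np.zeros(len(X)), TINY_DET, seed=0)

    def test_single_class_filter_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            train_filter(np.random.default_rng(0).random((20, 8)),
                         np.zeros(20), TINY_FNN, seed=0)

    def test_unknown_lineage_label_named_in_error(self):
        X = np.random.default_rng(0).random((13, 8))
        labels = list(DEFAULT_LINEAGES[:12]) + ["RLX_Mystery"]
        with pytest.raises(ValueError, match="RLX_Mystery"):
            train_classifier(X, labels, ClassifierConfig(hidden=(8,), epochs=1), seed=0)

    def test_wrong_label_list_size_rejected(self):
        X = np.random.default_rng(0).random((4, 8))
        with pytest.raises(ValueError, match="13"):
            train_classifier(X, ["a"] * 4, lineages=["a", "b"], seed=0)

    def test_detector_training_is_seed_deterministic(self):
        X, y = _toy_windows()
        m1, h1 = train_detector(X, y, TINY_DET, seed=9)
        m2, h2 = train_detector(X, y, TINY_DET, seed=9)
        assert h1["loss"] == h2["loss"]
        assert np.array_equal(m1.predict_proba(X), m2.predict_proba(X))

    def test_fnn_training_is_seed_deterministic(self):
        rng = np.random.default_rng(3)
        X = rng.random((40, 12)).astype(np.float32)
        y = (X[:, 0] > 0.5).astype(int)
        m1, _ = train_filter(X, y, TINY_FNN, seed=4)
        m2, _ = train_filter(X, y, TINY_FNN, seed=4)
        assert np.array_equal(m1.predict_proba(X), m2.predict_proba(X))

    def test_random_labels_give_chance_accuracy(self):
        """With the window/label pairing destroyed there is no signal, so
        held-out accuracy sits at chance."""
        from ltrnet.synthetic_data import gen_training_windows
        from ltrnet.genome_io import encode_sequence

        seqs, labels, _ = gen_training_windows(50, 50, window_size=4000, seed=21)
        X = np.stack([encode_sequence(s) for s in seqs])
        shuffled = np.random.default_rng(21).permutation(labels)
        cfg = DetectorConfig(window_size=4000, epochs=10)
        _, hist = train_detector(X, shuffled, cfg, seed=21)
        assert 0.3 <= hist["val_accuracy"] <= 0.7

    def test_detect_windows_threshold(self):
        X, y = _toy_windows()
        model, _ = train_detector(X, y, TINY_DET, seed=0)
        scored = detect_windows(model, list(X), threshold=0.5)
        for _, p, keep in scored:
            assert 0.0 <= p <= 1.0
            assert keep == (p >= 0.5)
        assert not any(k for _, _, k in detect_windows(model, list(X), threshold=1.1))

    def test_all_n_window_scores_cleanly(self):
        X, y = _toy_windows()
        model, _ = train_detector(X, y, TINY_DET, seed=0)
        alln = np.zeros((1, 5, 300), dtype=np.float32)
        alln[:, 4, :] = 1.0
        (_, p, _), = detect_windows(model, [alln[0]])
        assert 0.0 <= p <= 1.0


def _tiny_bundle(seed=0):
    rng = np.random.default_rng(seed)
    X = rng.random((60, N_KMERS))
    pre = fit_preprocessor(X, n_components=6, seed=seed)
    Z = pre.transform(X)
    yf = (Z[:, 0] > 0).astype(int)
    filt, _ = train_filter(Z, yf, TINY_FNN, seed=seed)
    yc = [DEFAULT_LINEAGES[i % 13] for i in range(60)]
    cfg = ClassifierConfig(hidden=(16, 16, 16), epochs=5, batch_size=16)
    clf, _ = train_classifier(Z, yc, cfg, seed=seed)
    X_det, y_det = _toy_windows(rng=rng)
    det, _ = train_detector(X_det, y_det, TINY_DET, seed=seed)
    return ModelBundle(detector=det, preprocessor=pre, filter=filt, classifier=clf,
                       window_size=300), X


class TestBundleAndPrediction:
    def test_probabilities_are_valid(self):
        bundle, X = _tiny_bundle()
        intact, lineage, lin_p = predict_element(bundle, X[0])
        assert 0.0 <= intact <= 1.0 and 0.0 <= lin_p <= 1.0
        assert lineage in DEFAULT_LINEAGES
        probs = bundle.classifier.predict_proba(
            bundle.preprocessor.transform(X[:5]).astype(np.float32))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_intact_prob_is_class_zero(self):
        bundle, X = _tiny_bundle()
        feats = bundle.preprocessor.transform(X[:1]).astype(np.float32)
        p = bundle.filter.predict_proba(feats)[0]
        intact, _, _ = predict_element(bundle, X[0])
        assert intact == pytest.approx(float(p[0]))

    def test_wrong_dimensionality_rejected(self):
        bundle, _ = _tiny_bundle()
        with pytest.raises(ValueError, match="5460"):
            predict_element(bundle, np.zeros(100))

    def test_save_load_reproduces_predictions(self, tmp_path):
        bundle, X = _tiny_bundle(seed=5)
        bundle.save(tmp_path / "bundle")
        loaded = ModelBundle.load(tmp_path / "bundle")
        assert loaded.lineages == bundle.lineages
        for x in X[:8]:
            assert predict_element(bundle, x) == predict_element(loaded, x)
        wins = np.zeros((2, 5, 300), dtype=np.float32)
        wins[:, 0, :] = 1.0
        assert np.array_equal(
            bundle.detector.predict_proba(wins), loaded.detector.predict_proba(wins)
        )

    def test_missing_bundle_dir_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            ModelBundle.load(tmp_path / "nope")
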