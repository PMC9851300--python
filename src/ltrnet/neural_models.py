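"""The three predictive networks and their shared feature preprocessing.

* **Detector** — a CNN over 5x(window) one-hot matrices that decides which
  genome sections contain an LTR-retrotransposon: three convolutional
  layers each followed by max pooling, then dense layers of 1000 and 500
  units, all ReLU, trained with SGD on binary cross-entropy (100 epochs,
  batch 64 by default).
* **Intactness filter** — an FNN on k-mer features deciding intact (class
  0) vs non-intact (class 1): three hidden layers of 200 units with batch
  normalisation (momentum 0.99), dropout 0.5, l1 kernel penalty 1e-4 and
  l2 bias penalty 0.01, softmax output, Adam on categorical cross-entropy
  (200 epochs, batch 128 by default).
* **Lineage classifier** — same architecture with 13 softmax outputs, one
  per lineage.

Features for the filter and classifier are 5460-dimensional k-mer counts
reduced by PCA and standardised (:class:`FeaturePreprocessor`).

Every training entry point takes an explicit seed and performs its own
stratified 80/20 train/validation split; held-out accuracy is reported in
the returned history under ``"val_accuracy"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA
from sklearn.preprocessing import StandardScaler

from . import _nn
from .genome_io import WINDOW_SIZE, OneHotWindow
from .kmer_conv import N_KMERS, KmerVector

#: Default 13-lineage label space (Copia "RLC_*" and Gypsy "RLG_*"
#: plant lineages); the bundle may carry any user-supplied list of 13.
DEFAULT_LINEAGES = [
    "RLC_Ale", "RLC_Angela", "RLC_Bianca", "RLC_Ikeros", "RLC_Ivana",
    "RLC_SIRE", "RLC_TAR", "RLC_Tork",
    "RLG_Athila", "RLG_CRM", "RLG_Galadriel", "RLG_Reina", "RLG_Retand",
]

BUNDLE_FORMAT_VERSION = 1


# ------------------------------------------------------------- configs


@dataclass
class DetectorConfig:
    """Window-level CNN detector hyper-parameters.

    Conv filter counts / kernel / pool widths are configurable (a standard
    (32, 64, 128) pyramid with width-10 kernels and pools by default, which
    keeps 50 kb inputs tractable on CPU); the remaining values are the
    published training recipe.
    """

    window_size: int = WINDOW_SIZE
    conv_filters: tuple[int, ...] = (32, 64, 128)
    kernel: int = 10
    #: one max-pool width per conv layer (an int is broadcast); width 0
    #: pools each channel over its whole feature map, which makes the
    #: downstream dense layers position-invariant
    pool: int | tuple[int, ...] = 10
    dense: tuple[int, ...] = (1000, 500)
    lr: float = 0.005
    momentum: float = 0.9
    epochs: int = 100
    batch_size: int = 64


@dataclass
class FilterConfig:
    """Intactness-filter FNN hyper-parameters (label 0 = intact)."""

    hidden: tuple[int, ...] = (200, 200, 200)
    dropout: float = 0.5
    bn_momentum: float = 0.99
    l1_kernel: float = 1e-4
    l2_bias: float = 0.01
    lr: float = 0.001
    epochs: int = 200
    batch_size: int = 128
    n_classes: int = 2


@dataclass
class ClassifierConfig(FilterConfig):
    """Lineage-classifier FNN: same recipe with 13 softmax outputs."""

    n_classes: int = 13


# -------------------------------------------------- feature preprocessing


class FeaturePreprocessor:
    """PCA projection followed by standard scaling of k-mer count vectors.

    ``n_components`` may be an int (randomised SVD) or a float in (0, 1)
    (variance fraction, full SVD).  After fitting, ``transform`` is a pure
    array computation so a loaded preprocessor needs no fitted sklearn
    state.
    """

    def __init__(self, n_components: int | float = 64):
        self.n_components = n_components
        self.fitted = False
        self.pca_mean_: np.ndarray | None = None
        self.components_: np.ndarray | None = None
        self.scale_mean_: np.ndarray | None = None
        self.scale_std_: np.ndarray | None = None

    def fit(self, X: np.ndarray, seed: int = 0) -> "FeaturePreprocessor":
        X = np.asarray(X, dtype=np.float64)
        n, d = X.shape
        if isinstance(self.n_components, int):
            if self.n_components > min(n, d):
                raise ValueError(
                    f"n_components={self.n_components} exceeds min(n_samples={n}, n_features={d})"
                )
            pca = PCA(n_components=self.n_components, svd_solver="randomized", random_state=seed)
        else:
            pca = PCA(n_components=self.n_components, svd_solver="full")
        pca.fit(X)
        self.pca_mean_ = np.ascontiguousarray(pca.mean_)
        self.components_ = np.ascontiguousarray(pca.components_)
        # fit the scaler on the same array computation transform() uses, so
        # the training set is standardised exactly and a saved/loaded
        # preprocessor is bit-identical to the fitted one
        Z = (X - self.pca_mean_) @ self.components_.T
        scaler = StandardScaler().fit(Z)
        self.scale_mean_ = scaler.mean_
        self.scale_std_ = scaler.scale_
        self.fitted = True
        return self

    def transform(self, X) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("preprocessor is not fitted")
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 1:
            X = X[None, :]
        Z = (X - self.pca_mean_) @ self.components_.T
        return (Z - self.scale_mean_) / self.scale_std_

    def save(self, path) -> None:
        np.savez(
            path,
            pca_mean=self.pca_mean_, components=self.components_,
            scale_mean=self.scale_mean_, scale_std=self.scale_std_,
        )

    @classmethod
    def load(cls, path) -> "FeaturePreprocessor":
        with np.load(path) as d:
            p = cls(n_components=int(d["components"].shape[0]))
            p.pca_mean_ = d["pca_mean"]
            p.components_ = d["components"]
            p.scale_mean_ = d["scale_mean"]
            p.scale_std_ = d["scale_std"]
            p.fitted = True
        return p


def fit_preprocessor(
    vectors, n_components: int | float = 64, seed: int = 0
) -> FeaturePreprocessor:
    """Fit the k-mer feature preprocessor on training count vectors."""
    X = _vectors_to_array(vectors)
    return FeaturePreprocessor(n_components=n_components).fit(X, seed=seed)


def _vectors_to_array(vectors) -> np.ndarray:
    if isinstance(vectors, np.ndarray):
        return vectors.astype(np.float64)
    rows = [v.counts if isinstance(v, KmerVector) else np.asarray(v) for v in vectors]
    return np.asarray(rows, dtype=np.float64)


# ---------------------------------------------------------- construction


def build_detector(cfg: DetectorConfig, seed: int = 0) -> _nn.Model:
    layers: list[_nn.Layer] = []
    pools = cfg.pool if isinstance(cfg.pool, tuple) else (cfg.pool,) * len(cfg.conv_filters)
    c_in, length = 5, cfg.window_size
    for c_out, p in zip(cfg.conv_filters, pools):
        conv_len = length - cfg.kernel + 1
        width = conv_len if p == 0 else p  # 0 = global pooling
        layers += [_nn.Conv1D(c_in, c_out, cfg.kernel), _nn.ReLU(), _nn.MaxPool1D(width)]
        length = conv_len // width
        c_in = c_out
    layers.append(_nn.Flatten())
    n_in = c_in * length
    for units in cfg.dense:
        layers += [_nn.Dense(n_in, units), _nn.ReLU()]
        n_in = units
    layers.append(_nn.Dense(n_in, 1))
    return _nn.Model(layers, loss="bce", seed=seed)


def build_fnn(cfg: FilterConfig, input_dim: int, seed: int = 0) -> _nn.Model:
    layers: list[_nn.Layer] = []
    n_in = input_dim
    for units in cfg.hidden:
        layers += [
            _nn.Dense(n_in, units, l1=cfg.l1_kernel, l2_bias=cfg.l2_bias),
            _nn.BatchNorm(units, momentum=cfg.bn_momentum),
            _nn.ReLU(),
            _nn.Dropout(cfg.dropout),
        ]
        n_in = units
    layers.append(_nn.Dense(n_in, cfg.n_classes))
    return _nn.Model(layers, loss="softmax_ce", seed=seed)


# -------------------------------------------------------------- training


def _stratified_split(y: np.ndarray, frac: float, rng: np.random.Generator):
    train_idx, val_idx = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = idx[rng.permutation(len(idx))]
        n_val = max(1, int(round(len(idx) * (1 - frac))))
        val_idx.extend(idx[:n_val])
        train_idx.extend(idx[n_val:])
    return np.sort(np.asarray(train_idx)), np.sort(np.asarray(val_idx))


def _windows_to_array(windows) -> np.ndarray:
    if isinstance(windows, np.ndarray):
        return windows.astype(np.float32)
    mats = [w.matrix if isinstance(w, OneHotWindow) else np.asarray(w) for w in windows]
    return np.stack(mats).astype(np.float32)


def train_detector(
    windows, labels, cfg: DetectorConfig | None = None, seed: int = 0
) -> tuple[_nn.Model, dict]:
    """Train the window CNN on binary labels (1 = contains an element)."""
    cfg = cfg or DetectorConfig()
    X = _windows_to_array(windows)
    y = np.asarray(labels, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate training set: only one class present")
    rng = np.random.default_rng(seed)
    tr, va = _stratified_split(y, 0.8, rng)
    model = build_detector(cfg, seed=seed)
    opt = _nn.SGD(lr=cfg.lr, momentum=cfg.momentum)
    history = model.fit(X[tr], y[tr], epochs=cfg.epochs, batch_size=cfg.batch_size, optimizer=opt)
    p = model.predict_proba(X[va], batch_size=8)
    history["val_accuracy"] = float(np.mean((p >= 0.5).astype(int) == y[va]))
    return model, history


def detect_windows(
    model: _nn.Model, windows, threshold: float = 0.5, batch_size: int = 8
) -> list[tuple[OneHotWindow, float, bool]]:
    """Score windows and flag those reaching the detection threshold."""
    if not windows:
        return []
    X = _windows_to_array(windows)
    probs = model.predict_proba(X, batch_size=batch_size)
    return [(w, float(p), bool(p >= threshold)) for w, p in zip(windows, probs)]


def _train_fnn(features, y, cfg: FilterConfig, seed: int) -> tuple[_nn.Model, dict]:
    X = _vectors_to_array(features).astype(np.float32)
    rng = np.random.default_rng(seed)
    tr, va = _stratified_split(y, 0.8, rng)
    model = build_fnn(cfg, input_dim=X.shape[1], seed=seed)
    opt = _nn.Adam(lr=cfg.lr)
    history = model.fit(X[tr], y[tr], epochs=cfg.epochs, batch_size=cfg.batch_size, optimizer=opt)
    p = model.predict_proba(X[va], batch_size=256)
    history["val_accuracy"] = float(np.mean(p.argmax(axis=1) == y[va]))
    return model, history


def train_filter(
    features, labels, cfg: FilterConfig | None = None, seed: int = 0
) -> tuple[_nn.Model, dict]:
    """Train the intactness filter (label 0 = intact, 1 = non-intact)."""
    cfg = cfg or FilterConfig()
    y = np.asarray(labels, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate training set: only one class present")
    return _train_fnn(features, y, cfg, seed)


def train_classifier(
    features,
    labels,
    cfg: ClassifierConfig | None = None,
    seed: int = 0,
    lineages: list[str] | None = None,
) -> tuple[_nn.Model, dict]:
    """Train the lineage classifier; ``labels`` are lineage names.

    Supports retraining on user data: any label list of the configured
    cardinality may be supplied.
    """
    cfg = cfg or ClassifierConfig()
    lineages = lineages if lineages is not None else list(DEFAULT_LINEAGES)
    if len(lineages) != cfg.n_classes:
        raise ValueError(f"label list has {len(lineages)} entries, expected {cfg.n_classes}")
    lut = {name: i for i, name in enumerate(lineages)}
    y = np.empty(len(labels), dtype=np.int64)
    for i, lab in enumerate(labels):
        if lab not in lut:
            raise ValueError(f"unknown lineage label {lab!r}")
        y[i] = lut[lab]
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate training set: only one class present")
    return _train_fnn(features, y, cfg, seed)


# ---------------------------------------------------------------- bundle


@dataclass
class ModelBundle:
    """Trained detector + preprocessor + filter + classifier, persistable.

    Saved as a directory of npz weight files plus a JSON metadata file;
    loading reproduces bit-identical predictions.
    """

    detector: _nn.Model
    preprocessor: FeaturePreprocessor
    filter: _nn.Model
    classifier: _nn.Model
    lineages: list[str] = field(default_factory=lambda: list(DEFAULT_LINEAGES))
    window_size: int = WINDOW_SIZE
    metadata: dict = field(default_factory=dict)

    def save(self, bundle_dir) -> None:
        d = Path(bundle_dir)
        d.mkdir(parents=True, exist_ok=True)
        self.detector.save(d / "detector.npz")
        self.filter.save(d / "filter.npz")
        self.classifier.save(d / "classifier.npz")
        self.preprocessor.save(d / "preprocessor.npz")
        meta = {
            "format_version": BUNDLE_FORMAT_VERSION,
            "lineages": self.lineages,
            "window_size": self.window_size,
            "metadata": self.metadata,
        }
        (d / "bundle.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, bundle_dir) -> "ModelBundle":
        d = Path(bundle_dir)
        meta_path = d / "bundle.json"
        if not meta_path.exists():
            raise FileNotFoundError(f"no model bundle at {d}")
        meta = json.loads(meta_path.read_text())
        return cls(
            detector=_nn.Model.load(d / "detector.npz"),
            preprocessor=FeaturePreprocessor.load(d / "preprocessor.npz"),
            filter=_nn.Model.load(d / "filter.npz"),
            classifier=_nn.Model.load(d / "classifier.npz"),
            lineages=meta["lineages"],
            window_size=meta["window_size"],
            metadata=meta.get("metadata", {}),
        )


def predict_element(bundle: ModelBundle, kmer_vector) -> tuple[float, str, float]:
    """Score one element: (intact probability, lineage, lineage probability).

    Intactness is the probability of class 0 (intact); the lineage is the
    argmax class of the classifier, exact ties resolved to the lowest class
    index.
    """
    counts = kmer_vector.counts if isinstance(kmer_vector, KmerVector) else np.asarray(kmer_vector)
    if counts.shape[-1] != N_KMERS:
        raise ValueError(f"expected {N_KMERS}-dimensional k-mer vector, got {counts.shape[-1]}")
    feats = bundle.preprocessor.transform(counts).astype(np.float32)
    p_filter = bundle.filter.predict_proba(feats)[0]
    p_class = bundle.classifier.predict_proba(feats)[0]
    li = int(np.argmax(p_class))  # argmax returns the first (lowest) index on ties
    return float(p_filter[0]), bundle.lineages[li], float(p_class[li])
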