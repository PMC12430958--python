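"""Trainable graders and recognizers for captured motions.

Two families are supported, mirroring how motion-assessment pipelines
are usually built:

* sample-based — each motion becomes a 306-dimensional time-domain
  feature vector, normalized to [0, 1] and PCA-reduced (scaler and PCA
  fitted on training data only), then classified with a conventional
  model (k-NN, RBF-kernel SVM, Gaussian naive Bayes, multinomial
  logistic regression, Gini decision tree);
* sequence-based — motions are treated as quaternion time series:
  ``dtw_knn`` is 1-nearest-neighbour under the band-constrained DTW
  motion distance; ``dtw_svm``/``dtw_nb``/``dtw_logreg``/``dtw_dtree``
  embed each motion as its vector of DTW distances to the training
  motions; ``hmm`` fits one left-to-right Gaussian HMM per class on
  keyframe quaternion vectors and classifies by maximum likelihood.

The same machinery serves grading (ordinal Fail/Pass/Good accuracy
labels) and recognition (motion classes 1-8).  Additional methods (e.g.
neural networks) can be plugged in with :func:`register_method`.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import joblib
import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .bvh import MotionSequence
from .dtw import motion_distance
from .features import apply_pca, apply_scaler, extract_time_features, fit_pca, fit_scaler
from .keyframes import extract_keyframes

__all__ = [
    "AccuracyGrade",
    "MotionClassifier",
    "cross_validate",
    "register_method",
    "SAMPLE_METHODS",
    "SEQUENCE_METHODS",
]


class AccuracyGrade(enum.IntEnum):
    """Ordinal motion-accuracy grade, Fail < Pass < Good."""

    FAIL = 0
    PASS = 1
    GOOD = 2

    @classmethod
    def from_name(cls, name: str) -> "AccuracyGrade":
        return cls[name.upper()]


SAMPLE_METHODS = ("knn", "svm", "nb", "logreg", "dtree")
SEQUENCE_METHODS = ("dtw_knn", "dtw_svm", "dtw_nb", "dtw_logreg", "dtw_dtree", "hmm")

#: Plugin registry: name -> factory(hyperparams, seed) returning an object
#: with sklearn-style fit(X, y) / predict(X).  This is the extension point
#: for neural methods, which are intentionally not built in.
_PLUGINS: dict[str, Callable] = {}


def register_method(name: str, factory: Callable) -> None:
    """Register an external classifier factory under ``name``."""
    _PLUGINS[name] = factory


def _make_estimator(method: str, hyper: dict, seed: int, n_features: int | None = None):
    if method == "knn":
        return KNeighborsClassifier(
            n_neighbors=hyper.get("k", 3), metric="euclidean", weights="distance"
        )
    if method == "svm":
        # one-vs-one multiclass, gamma = 1 / n_features
        return SVC(kernel="rbf", C=hyper.get("C", 1.0), gamma=hyper.get("gamma", "auto"))
    if method == "nb":
        return GaussianNB()
    if method == "logreg":
        # multinomial with the default L2 penalty
        return LogisticRegression(max_iter=hyper.get("max_iter", 1000))
    if method == "dtree":
        return DecisionTreeClassifier(criterion="gini", random_state=seed)
    if method in _PLUGINS:
        return _PLUGINS[method](hyper, seed)
    raise ValueError(f"unknown classification method {method!r}")


def _as_feature_matrix(inputs) -> np.ndarray:
    if isinstance(inputs, np.ndarray):
        return np.atleast_2d(inputs)
    if len(inputs) and isinstance(inputs[0], MotionSequence):
        return np.vstack([extract_time_features(m).values for m in inputs])
    return np.atleast_2d(np.asarray(inputs, dtype=float))


class MotionClassifier:
    """A grader or recognizer with a leakage-free preprocessing pipeline.

    Parameters
    ----------
    method : str
        One of :data:`SAMPLE_METHODS`, :data:`SEQUENCE_METHODS`, or a
        registered plugin name.
    pca_variance : float
        Cumulative explained-variance target for the PCA step of
        sample-based methods.
    band_fraction : float
        Sakoe-Chiba band for DTW-based methods.
    keyframe_ratio : float
        Compression ratio used to shorten sequences for the HMM.
    hmm_states : int
        Number of left-to-right states per class HMM.
    """

    def __init__(
        self,
        method: str = "knn",
        pca_variance: float = 0.95,
        band_fraction: float = 0.10,
        keyframe_ratio: float = 0.15,
        hmm_states: int = 5,
        hyperparams: dict | None = None,
        seed: int = 0,
    ):
        self.method = method
        self.pca_variance = pca_variance
        self.band_fraction = band_fraction
        self.keyframe_ratio = keyframe_ratio
        self.hmm_states = hmm_states
        self.hyperparams = hyperparams or {}
        self.seed = seed
        self._fitted = False

    # -- fitting ---------------------------------------------------------

    def fit(self, inputs, labels) -> "MotionClassifier":
        """Fit on feature rows (ndarray) or a list of MotionSequence.

        Sample-based methods fit the min-max scaler and PCA on the
        training rows only, then the estimator in PCA space.
        """
        labels = np.asarray(labels)
        if len(labels) != len(inputs):
            raise ValueError("inputs and labels must align")
        if len(np.unique(labels)) < 2:
            raise ValueError("training requires at least 2 distinct classes")
        self.classes_ = np.unique(labels)

        if self.method in SAMPLE_METHODS or (
            self.method in _PLUGINS and not isinstance(inputs[0], MotionSequence)
        ):
            X = _as_feature_matrix(inputs)
            self._scaler = fit_scaler(X)
            Xs = self._scaler.transform(X)
            self._pca = fit_pca(Xs, self.pca_variance)
            Z = self._pca.transform(Xs)
            self._est = _make_estimator(self.method, self.hyperparams, self.seed)
            self._est.fit(Z, labels)
            self._n_features_in = X.shape[1]
        elif self.method == "dtw_knn":
            self._train_motions = list(inputs)
            self._train_labels = labels
        elif self.method in ("dtw_svm", "dtw_nb", "dtw_logreg", "dtw_dtree"):
            self._train_motions = list(inputs)
            D = self._dtw_embed(inputs)
            self._scaler = fit_scaler(D)
            base = self.method.split("_", 1)[1]
            self._est = _make_estimator(base, self.hyperparams, self.seed)
            self._est.fit(self._scaler.transform(D), labels)
        elif self.method == "hmm":
            self._fit_hmm(inputs, labels)
        else:
            raise ValueError(f"unknown classification method {self.method!r}")
        self._fitted = True
        return self

    def _dtw_embed(self, motions) -> np.ndarray:
        """Each motion -> vector of DTW distances to the training motions."""
        D = np.empty((len(motions), len(self._train_motions)))
        for i, m in enumerate(motions):
            for j, t in enumerate(self._train_motions):
                D[i, j] = motion_distance(
                    m, t, band_fraction=self.band_fraction, keep_paths=False
                ).total_distance
        return D

    def _hmm_sequence(self, m: MotionSequence) -> np.ndarray:
        ks = extract_keyframes(m, ratio=self.keyframe_ratio, seed=self.seed)
        return m.quat_frames[ks.indices].reshape(len(ks.indices), -1)

    def _fit_hmm(self, motions, labels):
        from hmmlearn.hmm import GaussianHMM

        self._hmms = {}
        for cls in self.classes_:
            seqs = [self._hmm_sequence(m) for m, y in zip(motions, labels) if y == cls]
            X = np.vstack(seqs)
            lengths = [len(s) for s in seqs]
            n = min(self.hmm_states, min(lengths))
            model = GaussianHMM(
                n_components=n,
                covariance_type="diag",
                n_iter=30,
                random_state=self.seed,
                init_params="mc",
                params="stmc",
                min_covar=1e-3,
            )
            # left-to-right topology: start in state 0, move only forward;
            # zero entries stay zero under EM updates
            start = np.zeros(n)
            start[0] = 1.0
            trans = np.zeros((n, n))
            for i in range(n):
                trans[i, i] = 0.5
                if i + 1 < n:
                    trans[i, i + 1] = 0.5
                else:
                    trans[i, i] = 1.0
            model.startprob_ = start
            model.transmat_ = trans
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X, lengths)
            self._hmms[cls] = model

    # -- prediction ------------------------------------------------------

    def predict(self, inputs) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("classifier must be fitted before predicting")
        if len(inputs) == 0:
            return np.array([], dtype=self.classes_.dtype)

        if self.method in SAMPLE_METHODS or (
            self.method in _PLUGINS and hasattr(self, "_pca")
        ):
            X = _as_feature_matrix(inputs)
            if X.shape[1] != self._n_features_in:
                raise ValueError(
                    f"expected {self._n_features_in} features, got {X.shape[1]}"
                )
            Z = self._pca.transform(self._scaler.transform(X))
            return self._est.predict(Z)
        if self.method == "dtw_knn":
            out = []
            for m in inputs:
                d = [
                    motion_distance(m, t, self.band_fraction, keep_paths=False).total_distance
                    for t in self._train_motions
                ]
                out.append(self._train_labels[int(np.argmin(d))])
            return np.asarray(out)
        if self.method in ("dtw_svm", "dtw_nb", "dtw_logreg", "dtw_dtree"):
            D = self._dtw_embed(inputs)
            return self._est.predict(self._scaler.transform(D))
        if self.method == "hmm":
            out = []
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                for m in inputs:
                    seq = self._hmm_sequence(m)
                    scores = {c: h.score(seq) for c, h in self._hmms.items()}
                    out.append(max(scores, key=scores.get))
            return np.asarray(out)
        raise ValueError(f"unknown classification method {self.method!r}")

    # -- persistence -----------------------------------------------------

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "MotionClassifier":
        model = joblib.load(path)
        if not isinstance(model, MotionClassifier):
            raise TypeError(f"{path} does not contain a MotionClassifier")
        return model


def cross_validate(
    inputs,
    labels,
    method: str = "knn",
    folds: int = 10,
    seed: int = 0,
    **kwargs,
) -> tuple[np.ndarray, float]:
    """Stratified k-fold accuracy with the full pipeline refit per fold.

    The scaler and PCA of sample-based methods are refit on each training
    fold, so held-out rows never influence preprocessing.  Returns the
    per-fold accuracies and their mean.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < folds:
        raise ValueError(f"need at least {folds} samples for {folds}-fold CV, got {n}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    X_is_array = isinstance(inputs, np.ndarray)
    accs = []
    for train_idx, test_idx in skf.split(np.zeros(n), labels):
        if X_is_array:
            X_tr, X_te = inputs[train_idx], inputs[test_idx]
        else:
            X_tr = [inputs[i] for i in train_idx]
            X_te = [inputs[i] for i in test_idx]
        clf = MotionClassifier(method=method, seed=seed, **kwargs)
        clf.fit(X_tr, labels[train_idx])
        pred = clf.predict(X_te)
        accs.append(float(np.mean(pred == labels[test_idx])))
    accs = np.asarray(accs)
    return accs, float(accs.mean())
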