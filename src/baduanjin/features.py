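"""Time-domain feature extraction, min-max normalization and PCA.

Each motion is summarised by six statistics (mean, variance, standard
deviation, skewness, kurtosis, quartile deviation) of every joint-channel
series, giving 17 joints x 3 Euler channels x 6 statistics = 306 features
per motion for the default profile.  Features are normalized to [0, 1]
against the training set and reduced with PCA before classification.

Moment conventions (the population/biased forms): variance divides by F,
skewness is the third standardized moment, kurtosis the excess fourth
standardized moment; quartiles use linear interpolation.  A constant
series has undefined standardized moments and is assigned 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.decomposition import PCA as _SKPCA
from sklearn.preprocessing import MinMaxScaler as _SKMinMax

from .bvh import MotionSequence

__all__ = [
    "STAT_NAMES",
    "FeatureVector",
    "FeatureScaler",
    "PCAModel",
    "extract_time_features",
    "fit_scaler",
    "apply_scaler",
    "fit_pca",
    "apply_pca",
]

STAT_NAMES = ("mean", "variance", "std", "skewness", "kurtosis", "quartile_deviation")


@dataclass
class FeatureVector:
    """Named time-domain feature values for one motion."""

    values: np.ndarray
    names: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.names),):
            raise ValueError("values and names disagree in length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    def __len__(self) -> int:
        return len(self.values)


def _series_stats(x: np.ndarray) -> np.ndarray:
    if np.ptp(x) == 0.0:
        # constant series: dispersion is 0 and standardized moments are
        # undefined; both are assigned 0
        return np.array([float(x[0]), 0.0, 0.0, 0.0, 0.0, 0.0])
    var = float(np.var(x))  # population form
    skew = float(sps.skew(x, bias=True))
    kurt = float(sps.kurtosis(x, fisher=True, bias=True))
    if not np.isfinite(skew):  # numerically constant series
        skew = 0.0
    if not np.isfinite(kurt):
        kurt = 0.0
    q1, q3 = np.percentile(x, [25, 75])  # linear-interpolation quantiles
    return np.array([float(np.mean(x)), var, np.sqrt(var), skew, kurt, (q3 - q1) / 2.0])


def extract_time_features(m: MotionSequence) -> FeatureVector:
    """306-dimensional time-domain feature vector (17-joint profile).

    Statistics are computed on the raw Euler channels and therefore do
    not depend on ``frame_time``.  Requires at least 2 frames.
    """
    if m.euler_frames is None:
        raise ValueError("feature extraction requires euler_frames")
    if m.n_frames < 2:
        raise ValueError("feature extraction requires at least 2 frames")
    F, J, C = m.euler_frames.shape
    values = np.empty(J * C * len(STAT_NAMES))
    names: list[str] = []
    k = 0
    for j in range(J):
        for c in range(C):
            values[k : k + 6] = _series_stats(m.euler_frames[:, j, c])
            names.extend(f"joint{j}.ch{c}.{s}" for s in STAT_NAMES)
            k += 6
    return FeatureVector(values, names)


# ---------------------------------------------------------------------------
# normalization


@dataclass
class FeatureScaler:
    """Per-feature min-max normalization fitted on a training matrix.

    Transforms map training values into [0, 1]; out-of-range test values
    are clipped, and a constant training feature maps to 0.
    """

    data_min: np.ndarray
    data_max: np.ndarray
    _sk: _SKMinMax

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return self._sk.transform(x)


def fit_scaler(train: np.ndarray) -> FeatureScaler:
    train = np.atleast_2d(np.asarray(train, dtype=float))
    if train.size == 0:
        raise ValueError("cannot fit a scaler on an empty training matrix")
    sk = _SKMinMax(clip=True).fit(train)
    return FeatureScaler(sk.data_min_, sk.data_max_, sk)


def apply_scaler(s: FeatureScaler, x: np.ndarray) -> np.ndarray:
    out = s.transform(x)
    return out[0] if np.asarray(x).ndim == 1 else out


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAModel:
    """Fitted PCA: orthonormal components, training means, variance ratios."""

    components: np.ndarray  # (k, p)
    mean: np.ndarray  # (p,)
    explained_variance_ratio: np.ndarray  # (k,), non-increasing
    _sk: _SKPCA

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return self._sk.transform(x)

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        return self._sk.inverse_transform(np.atleast_2d(np.asarray(z, dtype=float)))


def fit_pca(train: np.ndarray, variance_target: float = 0.95) -> PCAModel:
    """Keep the smallest number of components whose cumulative explained
    variance reaches ``variance_target`` (1.0 keeps every component)."""
    if not 0.0 < variance_target <= 1.0:
        raise ValueError(f"variance_target must be in (0, 1], got {variance_target}")
    train = np.atleast_2d(np.asarray(train, dtype=float))
    if train.shape[0] < 2:
        raise ValueError("PCA requires at least 2 training rows")
    n_components = variance_target if variance_target < 1.0 else None
    sk = _SKPCA(n_components=n_components, svd_solver="full").fit(train)
    return PCAModel(sk.components_, sk.mean_, sk.explained_variance_ratio_, sk)


def apply_pca(p: PCAModel, x: np.ndarray) -> np.ndarray:
    out = p.transform(x)
    return out[0] if np.asarray(x).ndim == 1 else out
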