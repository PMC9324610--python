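"""Per-channel statistical and heuristic features for inertial segments.

Eleven features are computed independently for every channel of a segment,
in this fixed order:

    mean, median, absolute energy, standard deviation, variance, minimum,
    maximum, skewness, kurtosis, mean spectral energy, mean crossings

yielding an ``11 * C`` feature vector (66 features for a 6-channel IMU
segment). Conventions:

* absolute energy is the sum of squared samples;
* skewness and kurtosis use the biased moment estimators, kurtosis is
  *excess* kurtosis (normal -> 0), and both are defined as 0 on a
  zero-variance channel;
* mean spectral energy is the mean one-sided periodogram power
  (``|DFT|^2 / W``) excluding the zero-frequency bin, so it complements
  rather than duplicates the mean;
* mean crossings counts strict sign changes of the mean-subtracted signal,
  skipping samples exactly equal to the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

FEATURE_NAMES: tuple[str, ...] = (
    "mean",
    "median",
    "absolute_energy",
    "std",
    "variance",
    "minimum",
    "maximum",
    "skewness",
    "kurtosis",
    "mean_spectral_energy",
    "mean_crossings",
)

N_FEATURES_PER_CHANNEL = len(FEATURE_NAMES)


def feature_names(n_channels: int) -> list[str]:
    """Column names for an ``11 * n_channels`` feature vector."""
    return [f"ch{c}_{name}" for c in range(n_channels) for name in FEATURE_NAMES]


def _mean_spectral_energy(x: np.ndarray) -> float:
    w = x.shape[0]
    power = np.abs(np.fft.rfft(x)) ** 2 / w
    if power.shape[0] <= 1:
        return 0.0
    return float(power[1:].mean())


def _mean_crossings(x: np.ndarray) -> int:
    centered = x - x.mean()
    signs = np.sign(centered)
    signs = signs[signs != 0]  # samples exactly at the mean are skipped
    if signs.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(signs)))


def _channel_features(x: np.ndarray) -> np.ndarray:
    var = float(np.var(x))
    if var > 0:
        skew = float(stats.skew(x, bias=True))
        kurt = float(stats.kurtosis(x, bias=True, fisher=True))
    else:
        skew = 0.0
        kurt = 0.0
    return np.array(
        [
            float(np.mean(x)),
            float(np.median(x)),
            float(np.sum(x**2)),
            float(np.std(x)),
            var,
            float(np.min(x)),
            float(np.max(x)),
            skew,
            kurt,
            _mean_spectral_energy(x),
            float(_mean_crossings(x)),
        ]
    )


def compute_features(segment) -> np.ndarray:
    """Feature vector (length ``11 * C``) for one segment.

    Accepts a :class:`~perhar.preprocessing.Segment` or a bare ``(C, W)``
    array. Requires at least two samples per channel.
    """
    window = getattr(segment, "window", segment)
    window = np.asarray(window, dtype=float)
    if window.ndim != 2:
        raise ValueError("expected a (C, W) window")
    if window.shape[1] < 2:
        raise ValueError("feature computation requires at least 2 samples")
    return np.concatenate([_channel_features(window[c]) for c in range(window.shape[0])])


def compute_feature_matrix(segments) -> np.ndarray:
    """Stacked feature vectors for a segment set, shape (n, 11*C)."""
    return np.stack([compute_features(s) for s in segments])


@dataclass
class FeatureScaler:
    """Per-feature standardization (zero mean, unit standard deviation).

    Fitted once on training features and reused verbatim on test data.
    Constant features get scale clamped to 1, mapping them to zero.
    """

    location: np.ndarray
    scale: np.ndarray

    def transform(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        return (features - self.location) / self.scale


def fit_scaler(training_features: np.ndarray) -> FeatureScaler:
    """Estimate per-feature location (mean) and scale (population std)."""
    x = np.asarray(training_features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("scaler fitting requires at least 2 training rows")
    location = x.mean(axis=0)
    scale = x.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return FeatureScaler(location=location, scale=scale)


def apply_scaler(scaler: FeatureScaler, features: np.ndarray) -> np.ndarray:
    return scaler.transform(features)
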