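"""Per-event feature engineering for detected CAP phases.

Three feature families per event segment:

* time-domain moments (mean, variance, skewness, kurtosis),
* band powers from a discrete wavelet transform (db4), mapped onto the four
  clinical EEG bands — delta 0.5-4 Hz, theta 4-8 Hz, alpha 8-13 Hz,
  beta 13-30 Hz — plus their fractions,
* envelope morphology (peak duration, peak amplitude, transition slope).

A random-forest importance filter followed by PCA reduces the feature matrix
to a handful of components (F1..Fk) retaining at least 96% of the variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy import signal, stats
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.preprocessing import StandardScaler

#: analysis wavelet — a longer orthogonal filter keeps adjacent ~2 Hz packet
#: subbands selective enough that clinical-band fractions are trustworthy
WAVELET = "db16"

BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

FEATURE_NAMES = [
    "mean",
    "variance",
    "skewness",
    "kurtosis",
    "power_delta",
    "power_theta",
    "power_alpha",
    "power_beta",
    "frac_delta",
    "frac_theta",
    "frac_alpha",
    "frac_beta",
    "peak_duration_s",
    "peak_amplitude_uv",
    "transition_slope_uv_per_s",
]


@dataclass
class EventFeatures:
    time_domain: dict[str, float]
    band_power: dict[str, float]
    band_fractions: dict[str, float]
    morphology: dict[str, float]

    def as_vector(self) -> np.ndarray:
        vals = {
            **self.time_domain,
            **{f"power_{b}": v for b, v in self.band_power.items()},
            **{f"frac_{b}": v for b, v in self.band_fractions.items()},
            **self.morphology,
        }
        return np.array([vals[name] for name in FEATURE_NAMES])


@dataclass
class ReducedFeatures:
    """PCA scores F1..Fk over RF-selected, standardized features."""

    components: np.ndarray  # n_events x k scores
    loadings: np.ndarray  # k x n_selected_features
    explained_variance_fraction: float
    selected_features: list[str]

    @property
    def component_names(self) -> list[str]:
        return [f"F{i + 1}" for i in range(self.components.shape[1])]


def band_powers_dwt(segment: np.ndarray, fs: float) -> tuple[dict[str, float], dict[str, float]]:
    """Band powers and fractions from a db4 wavelet-packet decomposition.

    A full packet tree (depth chosen so subbands are at most ~2 Hz wide, in
    frequency order) gives uniform subbands whose Parseval coefficient energy
    is the band-power estimate; each subband's energy is distributed over the
    four clinical bands in proportion to frequency-interval overlap.  The
    uniform packet tiling avoids the octave mismatch of a plain multilevel
    decomposition, whose dyadic detail bands straddle the alpha/beta split.
    Fractions are normalized over the four bands.
    """
    if fs < 64:
        raise ValueError("fs must be >= 64 Hz so the beta band is resolvable")
    segment = np.asarray(segment, dtype=float)
    desired = int(np.ceil(np.log2(fs / 2.0 / 2.0)))  # subband width <= 2 Hz
    max_level = pywt.dwt_max_level(len(segment), pywt.Wavelet(WAVELET))
    level = max(1, min(desired, max_level))
    if max_level < 1:
        raise ValueError("segment too short for wavelet decomposition")
    wp = pywt.WaveletPacket(segment, WAVELET, mode="periodization", maxlevel=level)
    nodes = wp.get_level(level, order="freq")
    width = fs / 2 / len(nodes)
    powers = {b: 0.0 for b in BANDS}
    for i, node in enumerate(nodes):
        sub_power = float(np.sum(np.asarray(node.data) ** 2))
        # clip at the 0.5 Hz highpass edge: energy below it is filtered out
        # upstream, so the lowest subband's effective width starts there
        lo, hi = max(i * width, 0.5), (i + 1) * width
        if hi <= lo:
            continue
        for band, (blo, bhi) in BANDS.items():
            overlap = max(0.0, min(hi, bhi) - max(lo, blo))
            if overlap > 0:
                powers[band] += sub_power * overlap / (hi - lo)
    total = sum(powers.values())
    if total <= 0:
        fractions = {b: 0.25 for b in BANDS}
    else:
        fractions = {b: p / total for b, p in powers.items()}
    return powers, fractions


def extract_event_features(segment: np.ndarray, fs: float) -> EventFeatures:
    """All engineered features for one event segment (>= 2 s of signal).

    Moments use the raw samples; morphology uses the analytic envelope:
    peak amplitude is the envelope maximum, peak duration the time spent above
    half peak, and the transition slope the envelope rise from onset to peak
    divided by the time to peak.
    """
    segment = np.asarray(segment, dtype=float)
    if len(segment) < 2 * fs:
        raise ValueError("segment shorter than 2 s")
    var = float(np.var(segment))
    if var == 0:
        skew = kurt = 0.0
    else:
        skew = float(stats.skew(segment))
        kurt = float(stats.kurtosis(segment))
    time_domain = {
        "mean": float(np.mean(segment)),
        "variance": var,
        "skewness": skew,
        "kurtosis": kurt,
    }
    powers, fractions = band_powers_dwt(segment, fs)
    env = np.abs(signal.hilbert(segment))
    peak_idx = int(np.argmax(env))
    peak = float(env[peak_idx])
    above = env >= peak / 2
    morphology = {
        "peak_duration_s": float(np.sum(above)) / fs,
        "peak_amplitude_uv": peak,
        "transition_slope_uv_per_s": (
            (peak - float(env[0])) / (peak_idx / fs) if peak_idx > 0 else 0.0
        ),
    }
    return EventFeatures(time_domain, powers, fractions, morphology)


def rf_pca_reduce(
    features: np.ndarray,
    labels: np.ndarray,
    retain: float = 0.96,
    seed: int = 0,
    feature_names: list[str] | None = None,
    top_k: int | None = None,
) -> ReducedFeatures:
    """Random-forest importance selection followed by PCA to F1..Fk.

    Features with importance >= the mean importance are retained (or the top
    ``top_k`` when given), standardized, and projected onto the smallest
    number of principal components whose cumulative explained variance
    reaches ``retain``.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] < 10:
        raise ValueError("need a 2-D feature matrix with >= 10 events")
    if len(np.unique(y)) < 2:
        raise ValueError("need >= 2 classes for importance ranking")
    names = feature_names or [f"x{i}" for i in range(X.shape[1])]

    forest = RandomForestClassifier(n_estimators=200, random_state=seed, n_jobs=1)
    forest.fit(X, y)
    importances = forest.feature_importances_
    if top_k is not None:
        keep = np.argsort(importances)[::-1][:top_k]
        keep = np.sort(keep)
    else:
        keep = np.flatnonzero(importances >= importances.mean())
    Xs = StandardScaler().fit_transform(X[:, keep])

    pca = PCA(random_state=seed)
    pca.fit(Xs)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, retain - 1e-12) + 1)
    k = min(k, len(cum))
    scores = pca.transform(Xs)[:, :k]
    return ReducedFeatures(
        components=scores,
        loadings=pca.components_[:k],
        explained_variance_fraction=float(cum[k - 1]),
        selected_features=[names[i] for i in keep],
    )
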