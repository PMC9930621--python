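"""Summary acoustic descriptors and voice/nonvoice sound classification.

The extractor reduces each token to a fixed 88-slot feature vector built
from frame-wise contours (F0, HNR, jitter/shimmer proxies, spectral flux,
spectral moments, band energies, cepstra and envelope statistics), each
summarized by simple statistics.  The slot layout is documented in
:data:`FEATURE_NAMES`; descriptors that are undefined for a token (e.g.
jitter with fewer than two voiced frames) are imputed as 0.

Classification uses a support vector machine with a third-order polynomial
kernel by default, either stratified-fold cross-validated within one sound
set or trained on one set and tested on another (cross-classification).
"""

from __future__ import annotations

import numpy as np
from scipy.fft import dct
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import dsp
from .core import ClassificationResult, SoundToken

_SUMMARY2 = ("mean", "sd")


def _family(prefix: str, names, stats=_SUMMARY2):
    return [f"{prefix}_{n}_{s}" for n in names for s in stats]


#: Canonical ordering of the 88 feature slots.
FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"f0_{s}" for s in
     ("mean", "sd", "median", "min", "max", "range", "slope")]
    + ["voiced_fraction"]
    + [f"hnr_{s}" for s in ("mean", "sd", "min", "max")]
    + [f"jitter_{s}" for s in _SUMMARY2]
    + [f"shimmer_{s}" for s in _SUMMARY2]
    + [f"flux_{s}" for s in ("mean", "sd", "max")]
    + _family("spec", ("centroid", "spread", "skew", "kurt", "rolloff85",
                       "rolloff95", "flatness", "crest"))
    + _family("band", [f"e{b}" for b in range(8)])
    + _family("ceps", [f"c{k}" for k in range(13)])
    + ["env_mean", "env_sd", "env_mod_depth", "env_attack_slope",
       "env_decay_slope", "env_mod_centroid", "env_mod_2_4", "env_mod_4_8",
       "env_mod_8_16", "zcr_mean", "zcr_sd"]
)
N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 88


def _stats(values: np.ndarray, stats: tuple[str, ...]) -> list[float]:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    out = []
    for s in stats:
        if v.size == 0:
            out.append(0.0)
            continue
        if s == "mean":
            out.append(float(v.mean()))
        elif s == "sd":
            out.append(float(v.std()))
        elif s == "median":
            out.append(float(np.median(v)))
        elif s == "min":
            out.append(float(v.min()))
        elif s == "max":
            out.append(float(v.max()))
        elif s == "range":
            out.append(float(v.max() - v.min()))
        else:
            raise ValueError(s)
    return out


def jitter_shimmer_contours(track: dict) -> tuple[np.ndarray, np.ndarray]:
    """Frame-based jitter and shimmer proxies from a pitch track.

    Jitter: relative change of the period between consecutive voiced frames;
    shimmer: relative change of the frame RMS amplitude between consecutive
    voiced frames.  Both are empty when fewer than two voiced frames exist.
    """
    voiced = track["voiced"]
    f0 = track["f0"][voiced]
    amp = track["frame_rms"][voiced]
    if f0.size < 2:
        return np.zeros(0), np.zeros(0)
    periods = 1.0 / f0
    jitter = np.abs(np.diff(periods)) / periods.mean()
    denom = amp.mean() if amp.mean() > 0 else 1.0
    shimmer = np.abs(np.diff(amp)) / denom
    return jitter, shimmer


def hnr_summary(token: SoundToken, frame_ms: float = 40.0,
                hop_ms: float = 10.0) -> tuple[float, float]:
    """(mean, SD) of the HNR contour; the 2-D texture-matching feature."""
    track = dsp.pitch_hnr_contour(token.samples, token.sample_rate,
                                  frame_ms, hop_ms)
    hnr = track["hnr"][np.isfinite(track["hnr"])]
    if hnr.size == 0:
        return 0.0, 0.0
    return float(hnr.mean()), float(hnr.std())


def ripple_match_summary(token: SoundToken, frame_ms: float = 40.0,
                         hop_ms: float = 10.0) -> np.ndarray:
    """Mean and SD of jitter, shimmer and spectral flux (6-D ripple features)."""
    track = dsp.pitch_hnr_contour(token.samples, token.sample_rate,
                                  frame_ms, hop_ms)
    jitter, shimmer = jitter_shimmer_contours(track)
    _, mags = dsp.magnitude_spectrogram(token.samples, token.sample_rate,
                                        frame_ms, hop_ms)
    flux = dsp.spectral_flux(mags)
    return np.array(
        _stats(jitter, _SUMMARY2) + _stats(shimmer, _SUMMARY2)
        + _stats(flux, _SUMMARY2)
    )


def extract_features(token: SoundToken, frame_ms: float = 40.0,
                     hop_ms: float = 10.0) -> np.ndarray:
    """88-slot feature vector for one token (order: :data:`FEATURE_NAMES`)."""
    sr = token.sample_rate
    frame_len = int(round(frame_ms * sr / 1000.0))
    hop = int(round(hop_ms * sr / 1000.0))
    if token.n_samples < frame_len + 2 * hop:
        raise ValueError(
            f"token too short for feature extraction: {token.n_samples} "
            f"samples < 3 frames of {frame_ms} ms at hop {hop_ms} ms")

    track = dsp.pitch_hnr_contour(token.samples, sr, frame_ms, hop_ms)
    f0 = track["f0"][track["voiced"]]
    values: list[float] = []
    values += _stats(f0, ("mean", "sd", "median", "min", "max", "range"))
    if f0.size >= 2:
        t = track["times"][track["voiced"]]
        values.append(float(np.polyfit(t, f0, 1)[0]))
    else:
        values.append(0.0)
    values.append(float(track["voiced"].mean()) if track["voiced"].size else 0.0)
    values += _stats(track["hnr"], ("mean", "sd", "min", "max"))

    jitter, shimmer = jitter_shimmer_contours(track)
    values += _stats(jitter, _SUMMARY2)
    values += _stats(shimmer, _SUMMARY2)

    freqs, mags = dsp.magnitude_spectrogram(token.samples, sr, frame_ms, hop_ms)
    values += _stats(dsp.spectral_flux(mags), ("mean", "sd", "max"))
    moments = dsp.spectral_moments(freqs, mags)
    for name in ("centroid", "spread", "skew", "kurt", "rolloff85",
                 "rolloff95", "flatness", "crest"):
        values += _stats(moments[name], _SUMMARY2)

    edges8 = dsp.octave_band_edges(sr, n_bands=8)
    be8 = dsp.band_energies(freqs, mags, edges8)
    for b in range(8):
        values += _stats(be8[:, b], _SUMMARY2)

    edges26 = dsp.octave_band_edges(sr, n_bands=26)
    be26 = dsp.band_energies(freqs, mags, edges26)
    ceps = dct(be26, type=2, norm="ortho", axis=1)[:, :13]
    for k in range(13):
        values += _stats(ceps[:, k], _SUMMARY2)

    env = dsp.amplitude_envelope(token.samples, sr)
    env_mean = float(env.mean())
    env_sd = float(env.std())
    mod_depth = env_sd / env_mean if env_mean > 0 else 0.0
    peak_idx = int(np.argmax(env))
    peak = env[peak_idx]
    t_peak = peak_idx / sr
    attack = float(peak / t_peak) if t_peak > 0 else 0.0
    t_rest = (env.size - 1 - peak_idx) / sr
    decay = float((peak - env[-1]) / t_rest) if t_rest > 0 else 0.0
    mfreqs, mspec = dsp.modulation_spectrum(env, sr)
    msum = mspec.sum()
    mod_centroid = float((mfreqs * mspec).sum() / msum) if msum > 0 else 0.0
    mtot = msum if msum > 0 else 1.0

    def mband(lo, hi):
        return float(mspec[(mfreqs >= lo) & (mfreqs < hi)].sum() / mtot)

    zcr = dsp.zero_crossing_rate(dsp.frame_signal(token.samples, frame_len, hop))
    values += [env_mean, env_sd, mod_depth, attack, decay, mod_centroid,
               mband(2, 4), mband(4, 8), mband(8, 16)]
    values += _stats(zcr, _SUMMARY2)

    vec = np.asarray(values, dtype=float)
    assert vec.size == N_FEATURES
    vec[~np.isfinite(vec)] = 0.0
    return vec


def extract_feature_table(tokens, frame_ms: float = 40.0,
                          hop_ms: float = 10.0) -> tuple[np.ndarray, np.ndarray]:
    """Feature matrix and voice/nonvoice label array for a list of tokens."""
    feats = np.stack([extract_features(t, frame_ms, hop_ms) for t in tokens])
    labels = np.array([t.category for t in tokens])
    return feats, labels


def _make_svm(kernel: str, seed: int | None):
    if kernel == "poly3":
        clf = SVC(kernel="poly", degree=3, C=1.0, coef0=1.0,
                  random_state=seed)
    elif kernel == "linear":
        clf = SVC(kernel="linear", C=1.0, random_state=seed)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return make_pipeline(StandardScaler(), clf)


def classify_sounds_cv(features: np.ndarray, labels: np.ndarray,
                       n_folds: int = 5, kernel: str = "poly3",
                       seed: int = 0) -> ClassificationResult:
    """Stratified k-fold voice/nonvoice classification within one sound set."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need samples from both classes")
    if counts.min() < 2:
        raise ValueError("need at least 2 samples per class")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    accs = []
    for train_idx, test_idx in skf.split(features, labels):
        model = _make_svm(kernel, seed)
        model.fit(features[train_idx], labels[train_idx])
        accs.append(model.score(features[test_idx], labels[test_idx]))
    return ClassificationResult("cross_validation", np.asarray(accs),
                                kernel, seed)


def classify_sounds_cross(train_features: np.ndarray, train_labels: np.ndarray,
                          test_features: np.ndarray, test_labels: np.ndarray,
                          kernel: str = "poly3",
                          seed: int = 0) -> ClassificationResult:
    """Train on one sound set (the originals), test on another (an AE set)."""
    train_features = np.asarray(train_features, dtype=float)
    test_features = np.asarray(test_features, dtype=float)
    if train_features.shape[1] != test_features.shape[1]:
        raise ValueError("train and test feature dimensionality differ")
    model = _make_svm(kernel, seed)
    model.fit(train_features, np.asarray(train_labels))
    acc = model.score(test_features, np.asarray(test_labels))
    return ClassificationResult("cross_classification", np.array([acc]),
                                kernel, seed)
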