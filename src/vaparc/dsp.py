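"""Low-level waveform analysis shared by feature extraction and AE synthesis.

Frame-based pitch and harmonics-to-noise ratio (HNR) follow the classic
normalized-autocorrelation approach: within each windowed frame the
autocorrelation is normalized by the window's own autocorrelation, the
highest peak inside the pitch search range gives the period candidate, and
HNR = 10*log10(r / (1 - r)) where r is the (clipped) peak value, i.e. the
periodic-to-aperiodic energy ratio in dB.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import hilbert

# Numerical guards for the periodicity ratio r in HNR = 10*log10(r/(1-r)).
_R_FLOOR = 1e-4
_R_CEIL = 1.0 - 1e-4
#: Normalized-autocorrelation peak above which a frame counts as voiced.
VOICING_THRESHOLD = 0.45


def frame_signal(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    """Slice ``x`` into overlapping frames, shape (n_frames, frame_len)."""
    x = np.asarray(x, dtype=np.float64)
    if x.size < frame_len:
        return np.empty((0, frame_len))
    n_frames = 1 + (x.size - frame_len) // hop
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def _window_acf(window: np.ndarray) -> np.ndarray:
    """Normalized autocorrelation of the analysis window itself."""
    n = window.size
    spec = np.fft.rfft(window, 2 * n)
    acf = np.fft.irfft(spec * np.conj(spec))[:n]
    return acf / acf[0]


def frame_acf(frames: np.ndarray, window: np.ndarray) -> np.ndarray:
    """Window-corrected normalized autocorrelation per frame."""
    n = frames.shape[1]
    fw = (frames - frames.mean(axis=1, keepdims=True)) * window
    spec = np.fft.rfft(fw, 2 * n, axis=1)
    acf = np.fft.irfft(spec * np.conj(spec), axis=1)[:, :n]
    power = acf[:, :1].copy()
    power[power <= 0] = 1.0
    acf = acf / power
    wacf = _window_acf(window)
    wacf = np.where(np.abs(wacf) < 1e-3, 1e-3, wacf)
    return acf / wacf[None, :]


def pitch_hnr_contour(
    x: np.ndarray,
    sample_rate: int,
    frame_ms: float = 40.0,
    hop_ms: float = 10.0,
    fmin: float = 75.0,
    fmax: float = 500.0,
) -> dict:
    """Frame-wise F0 (Hz), HNR (dB) and voicing decisions.

    Returns a dict with arrays ``f0`` (NaN where unvoiced), ``hnr``,
    ``voiced`` (bool), ``times`` (frame centers, s) and ``frame_rms``.
    """
    frame_len = max(int(round(frame_ms * sample_rate / 1000.0)), 8)
    hop = max(int(round(hop_ms * sample_rate / 1000.0)), 1)
    frames = frame_signal(x, frame_len, hop)
    n_frames = frames.shape[0]
    out = {
        "f0": np.full(n_frames, np.nan),
        "hnr": np.full(n_frames, np.nan),
        "voiced": np.zeros(n_frames, dtype=bool),
        "times": (np.arange(n_frames) * hop + frame_len / 2) / sample_rate,
        "frame_rms": np.sqrt((frames ** 2).mean(axis=1)) if n_frames else
        np.empty(0),
    }
    if n_frames == 0:
        return out

    lag_min = max(int(np.floor(sample_rate / fmax)), 2)
    lag_max = int(np.ceil(sample_rate / fmin))
    if lag_max >= frame_len - 1:
        lag_max = frame_len - 2
    if lag_max <= lag_min:
        return out

    window = np.hanning(frame_len)
    acf = frame_acf(frames, window)
    # Taper the window-corrected ACF so spurious long-lag peaks (where the
    # correction blows up) do not win.
    lags = np.arange(lag_min, lag_max + 1)
    seg = acf[:, lag_min:lag_max + 1]
    peak_rel = np.argmax(seg, axis=1)
    peak_lag = lags[peak_rel]
    peak_val = seg[np.arange(n_frames), peak_rel]

    # Parabolic interpolation around the integer-lag peak.
    f0 = np.full(n_frames, np.nan)
    for i in range(n_frames):
        k = peak_lag[i]
        if acf[i, k] <= 0:
            continue
        if 1 <= k < acf.shape[1] - 1:
            ym, y0, yp = acf[i, k - 1], acf[i, k], acf[i, k + 1]
            denom = ym - 2 * y0 + yp
            delta = 0.5 * (ym - yp) / denom if abs(denom) > 1e-12 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        f0[i] = sample_rate / (k + delta)

    r = np.clip(peak_val, _R_FLOOR, _R_CEIL)
    hnr = 10.0 * np.log10(r / (1.0 - r))
    silence = out["frame_rms"] < 1e-6
    voiced = (peak_val >= VOICING_THRESHOLD) & ~silence & np.isfinite(f0)

    out["f0"] = np.where(voiced, f0, np.nan)
    out["hnr"] = np.where(silence, np.nan, hnr)
    out["voiced"] = voiced
    return out


def amplitude_envelope(x: np.ndarray, sample_rate: int,
                       smooth_ms: float = 10.0) -> np.ndarray:
    """Hilbert magnitude envelope, smoothed with a moving average."""
    x = np.asarray(x, dtype=np.float64)
    env = np.abs(hilbert(x))
    win = max(int(round(smooth_ms * sample_rate / 1000.0)), 1)
    if win > 1:
        kernel = np.ones(win) / win
        env = np.convolve(env, kernel, mode="same")
    return env


def rms(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=np.float64)
    return float(np.sqrt(np.mean(x ** 2))) if x.size else 0.0


def magnitude_spectrogram(
    x: np.ndarray, sample_rate: int, frame_ms: float = 40.0,
    hop_ms: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Hann-windowed magnitude spectrogram -> (freqs, n_frames x n_bins)."""
    frame_len = max(int(round(frame_ms * sample_rate / 1000.0)), 8)
    hop = max(int(round(hop_ms * sample_rate / 1000.0)), 1)
    frames = frame_signal(x, frame_len, hop)
    window = np.hanning(frame_len)
    mags = np.abs(np.fft.rfft(frames * window, axis=1))
    freqs = np.fft.rfftfreq(frame_len, 1.0 / sample_rate)
    return freqs, mags


def spectral_flux(mags: np.ndarray) -> np.ndarray:
    """L2 flux between successive frames of a (frames x bins) spectrogram.

    Frames are L2-normalized first so flux reflects spectral shape change,
    not loudness change.
    """
    if mags.shape[0] < 2:
        return np.zeros(0)
    norms = np.linalg.norm(mags, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    unit = mags / norms
    return np.linalg.norm(np.diff(unit, axis=0), axis=1)


def spectral_moments(freqs: np.ndarray, mags: np.ndarray) -> dict:
    """Per-frame centroid, spread, skewness, kurtosis, rolloffs, flatness, crest."""
    power = mags ** 2
    total = power.sum(axis=1, keepdims=True)
    total[total == 0] = 1.0
    w = power / total
    centroid = (w * freqs[None, :]).sum(axis=1)
    dev = freqs[None, :] - centroid[:, None]
    var = (w * dev ** 2).sum(axis=1)
    spread = np.sqrt(var)
    safe = np.where(spread == 0, 1.0, spread)
    skew = (w * dev ** 3).sum(axis=1) / safe ** 3
    kurt = (w * dev ** 4).sum(axis=1) / safe ** 4

    cum = np.cumsum(power, axis=1)
    tot = cum[:, -1:]
    tot_safe = np.where(tot == 0, 1.0, tot)

    def rolloff(frac: float) -> np.ndarray:
        idx = np.argmax(cum >= frac * tot_safe, axis=1)
        return freqs[idx]

    gm = np.exp(np.mean(np.log(mags + 1e-12), axis=1))
    am = mags.mean(axis=1) + 1e-12
    flatness = gm / am
    crest = mags.max(axis=1) / am
    return {
        "centroid": centroid, "spread": spread, "skew": skew, "kurt": kurt,
        "rolloff85": rolloff(0.85), "rolloff95": rolloff(0.95),
        "flatness": flatness, "crest": crest,
    }


def octave_band_edges(sample_rate: int, n_bands: int = 8,
                      fmin: float = 80.0) -> np.ndarray:
    """Logarithmically spaced band edges from fmin to Nyquist."""
    nyq = sample_rate / 2.0
    return np.geomspace(fmin, nyq, n_bands + 1)


def band_energies(freqs: np.ndarray, mags: np.ndarray,
                  edges: np.ndarray) -> np.ndarray:
    """Per-frame log-power in each band, shape (frames x bands)."""
    power = mags ** 2
    out = np.empty((mags.shape[0], edges.size - 1))
    for b in range(edges.size - 1):
        sel = (freqs >= edges[b]) & (freqs < edges[b + 1])
        out[:, b] = np.log10(power[:, sel].sum(axis=1) + 1e-12)
    return out


def envelope_autocorr(env: np.ndarray) -> np.ndarray:
    """Normalized autocorrelation of a (mean-removed) envelope."""
    e = env - env.mean()
    n = e.size
    spec = np.fft.rfft(e, 2 * n)
    acf = np.fft.irfft(spec * np.conj(spec))[:n]
    if acf[0] <= 0:
        return np.zeros(n)
    return acf / acf[0]


def modulation_spectrum(env: np.ndarray, sample_rate: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude spectrum of the mean-removed envelope -> (freqs, amplitude)."""
    e = env - env.mean()
    spec = np.abs(np.fft.rfft(e * np.hanning(e.size)))
    freqs = np.fft.rfftfreq(e.size, 1.0 / sample_rate)
    return freqs, spec


def zero_crossing_rate(frames: np.ndarray) -> np.ndarray:
    """Per-frame fraction of sign changes."""
    if frames.size == 0:
        return np.zeros(0)
    signs = np.signbit(frames)
    return np.mean(signs[:, 1:] != signs[:, :-1], axis=1)
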