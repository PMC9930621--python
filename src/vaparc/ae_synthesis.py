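"""The five acoustic-equivalent (AE) transformations and shared finalization.

Each AE preserves exactly one family of acoustic properties of an original
sound while destroying its identity:

``e_s``  envelope/spectrum chimera: Hilbert-envelope-modulated white noise
         plus noise whose Fourier magnitudes are replaced by the original's;
``scr``  temporal scrambling of overlapping windows within a local window,
         separately per frequency band;
``p_a``  a sinusoid tracking the (gap-interpolated) pitch contour plus white
         noise modulated by the original's intensity envelope;
``rip``  a dynamic moving ripple matched from a pool on jitter/shimmer/flux
         statistics;
``tsp``  a Gaussian-process sound texture matched from a pool on the mean
         and SD of the harmonics-to-noise ratio.

All stochastic components are seeded.  Every AE keeps the duration, sample
rate, category and provenance of its source token.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from . import dsp
from .acoustic_features import hnr_summary, ripple_match_summary
from .core import SoundToken

#: Digital reference: a waveform at RMS 0.05 full scale is defined to play at
#: 70 dB SPL; other levels scale linearly in amplitude (20 dB per decade).
REFERENCE_RMS_70DB = 0.05
REFERENCE_LEVEL_DB = 70.0


# ---------------------------------------------------------------------------
# finalization

def finalize_sound(token: SoundToken, ramp_ms: float = 5.0,
                   target_level_db: float = 70.0) -> SoundToken:
    """Apply raised-cosine on/off ramps, then set the RMS level.

    The level is set after ramping, so the output RMS equals the digital
    reference for ``target_level_db`` exactly.  If the required gain would
    push the peak beyond full scale the token is scaled to peak 1.0 instead
    and flagged with a warning.
    """
    x = np.asarray(token.samples, dtype=np.float64).copy()
    if x.size == 0 or not np.any(x):
        raise ValueError("cannot finalize an all-zero token: level undefined")
    n_ramp = int(round(ramp_ms * token.sample_rate / 1000.0))
    n_ramp = min(n_ramp, x.size // 2)
    if n_ramp > 1:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / (n_ramp - 1)))
        x[:n_ramp] *= ramp
        x[-n_ramp:] *= ramp[::-1]
    target_rms = REFERENCE_RMS_70DB * 10 ** ((target_level_db
                                              - REFERENCE_LEVEL_DB) / 20.0)
    current = dsp.rms(x)
    if current == 0:
        raise ValueError("token became all-zero after ramping")
    x *= target_rms / current
    warning = token.warning
    peak = np.max(np.abs(x))
    if peak > 1.0:
        x /= peak
        warning = (warning or "") + "clipped-headroom;"
    return SoundToken(samples=x, sample_rate=token.sample_rate,
                      category=token.category, variant=token.variant,
                      source_id=token.source_id, token_id=token.token_id,
                      warning=warning)


# ---------------------------------------------------------------------------
# envelope/spectrum AE

def env_spec_components(original: SoundToken, seed: int
                        ) -> tuple[np.ndarray, np.ndarray]:
    """(envelope-preserving, spectrum-preserving) noise components.

    The envelope component is the original's Hilbert amplitude envelope
    multiplied into white noise.  The spectrum component is white noise whose
    one-sided Fourier magnitudes (DC included; its sign is kept from the
    noise) are replaced by the original's magnitude spectrum while keeping
    the noise phases.  Both components are returned at unit RMS.
    """
    x = np.asarray(original.samples, dtype=np.float64)
    if not np.any(x):
        raise ValueError("silent input: envelope undefined up to scale")
    rng = np.random.default_rng(seed)
    env = np.abs(hilbert(x))
    env_comp = env * rng.standard_normal(x.size)

    noise = rng.standard_normal(x.size)
    noise_spec = np.fft.rfft(noise)
    target_mag = np.abs(np.fft.rfft(x))
    phases = np.angle(noise_spec)
    new_spec = target_mag * np.exp(1j * phases)
    new_spec[0] = np.sign(noise_spec[0].real) * target_mag[0]
    spec_comp = np.fft.irfft(new_spec, n=x.size)
    return env_comp / dsp.rms(env_comp), spec_comp / dsp.rms(spec_comp)


def synth_env_spec(original: SoundToken, seed: int = 0) -> SoundToken:
    """Envelope/spectrum-preserving AE (variant ``e_s``)."""
    if original.variant != "orig":
        raise ValueError("AEs are derived from original tokens only")
    env_comp, spec_comp = env_spec_components(original, seed)
    out = env_comp + spec_comp
    out = out / np.max(np.abs(out)) * 0.9
    return original.derived(out, "e_s")


# ---------------------------------------------------------------------------
# scrambled AE

def _band_masks(n_bins: int, sample_rate: int, n_bands: int) -> np.ndarray:
    """Raised-cosine band masks over rfft bins that sum to one everywhere."""
    freqs = np.fft.rfftfreq(2 * (n_bins - 1), 1.0 / sample_rate)
    edges = np.geomspace(50.0, sample_rate / 2.0, n_bands + 1)
    # Log-frequency triangular weights with unit partition; the lowest and
    # highest bands are extended to cover DC and Nyquist.
    logf = np.log(np.maximum(freqs, 1e-6))
    loge = np.log(edges)
    centers = 0.5 * (loge[:-1] + loge[1:])
    masks = np.zeros((n_bands, n_bins))
    for b in range(n_bands):
        lo = centers[b - 1] if b > 0 else -np.inf
        hi = centers[b + 1] if b < n_bands - 1 else np.inf
        c = centers[b]
        up = np.clip((logf - lo) / (c - lo), 0, 1) if np.isfinite(lo) else 1.0
        down = np.clip((hi - logf) / (hi - c), 0, 1) if np.isfinite(hi) else 1.0
        ramp_up = 0.5 * (1 - np.cos(np.pi * up)) if np.isfinite(lo) else 1.0
        ramp_dn = 0.5 * (1 - np.cos(np.pi * down)) if np.isfinite(hi) else 1.0
        masks[b] = ramp_up * ramp_dn
    total = masks.sum(axis=0)
    total[total == 0] = 1.0
    return masks / total[None, :]


def _scramble_one_band(x: np.ndarray, seg: int, local: int,
                       rng: np.random.Generator) -> np.ndarray:
    """Permute overlapping Hann-windowed segments within local windows."""
    n = x.size
    hop = max(seg // 2, 1)
    n_chunks = max(1 + (n - seg) // hop, 1)
    if n_chunks == 1:
        return x.copy()
    window = np.hanning(seg)
    starts = hop * np.arange(n_chunks)
    group = max(local // hop, 1)
    perm = np.arange(n_chunks)
    for g0 in range(0, n_chunks, group):
        g1 = min(g0 + group, n_chunks)
        perm[g0:g1] = g0 + rng.permutation(g1 - g0)
    out = np.zeros(n)
    wsum = np.zeros(n)
    for slot, src in enumerate(perm):
        s_out, s_in = starts[slot], starts[src]
        length = min(seg, n - s_out, n - s_in)
        w = window[:length]
        out[s_out:s_out + length] += x[s_in:s_in + length] * w
        wsum[s_out:s_out + length] += w
    good = wsum > 1e-8
    out[good] /= wsum[good]
    out[~good] = x[~good]
    return out


def synth_scrambled(original: SoundToken, segment_ms: float = 25.0,
                    local_window_ms: float = 250.0, n_bands: int = 8,
                    seed: int = 0) -> SoundToken:
    """Temporally scrambled AE (variant ``scr``).

    The signal is split into log-spaced frequency bands (complementary
    raised-cosine masks that sum to one, so recombination is exact), each
    band's overlapping segments are permuted within their local window with
    cosine cross-fades, and bands are summed again.
    """
    if original.variant != "orig":
        raise ValueError("AEs are derived from original tokens only")
    dur = original.duration_ms
    if not (segment_ms <= local_window_ms <= dur + 0.5):
        raise ValueError(
            f"need segment_ms <= local_window_ms <= duration, got "
            f"({segment_ms}, {local_window_ms}, {dur:.1f})")
    sr = original.sample_rate
    x = np.asarray(original.samples, dtype=np.float64)
    seg = max(int(round(segment_ms * sr / 1000.0)), 2)
    local = max(int(round(local_window_ms * sr / 1000.0)), seg)
    rng = np.random.default_rng(seed)

    spec = np.fft.rfft(x)
    masks = _band_masks(spec.size, sr, n_bands)
    out = np.zeros(x.size)
    for b in range(n_bands):
        band = np.fft.irfft(spec * masks[b], n=x.size)
        out += _scramble_one_band(band, seg, local, rng)
    return original.derived(out, "scr")


# ---------------------------------------------------------------------------
# pitch/amplitude AE

def synth_pitch_amp(original: SoundToken,
                    f0_range_hz: tuple[float, float] = (75.0, 500.0),
                    seed: int = 0) -> SoundToken:
    """Pitch/amplitude-preserving AE (variant ``p_a``).

    The frame-wise F0 contour (autocorrelation tracker) is gap-filled by
    linear interpolation and rendered as a sinusoid via phase accumulation;
    white noise is amplitude-modulated by the original's intensity envelope;
    the two are summed at equal RMS.  The sinusoid carries the same intensity
    envelope so the mixture preserves the original's amplitude dynamics as a
    whole.  With no voiced frames the AE falls back to the noise component
    alone and the token carries a warning flag.
    """
    if original.variant != "orig":
        raise ValueError("AEs are derived from original tokens only")
    x = np.asarray(original.samples, dtype=np.float64)
    if not np.any(x):
        raise ValueError("silent input: pitch and envelope undefined")
    sr = original.sample_rate
    rng = np.random.default_rng(seed)

    env = dsp.amplitude_envelope(x, sr, smooth_ms=10.0)
    noise = rng.standard_normal(x.size) * env
    noise = noise / dsp.rms(noise)

    track = dsp.pitch_hnr_contour(x, sr, fmin=f0_range_hz[0],
                                  fmax=f0_range_hz[1])
    voiced = track["voiced"]
    warning = None
    if voiced.sum() == 0:
        out = noise
        warning = "no-voiced-frames:noise-only;"
    else:
        t_frames = track["times"]
        f0_filled = np.interp(t_frames, t_frames[voiced],
                              track["f0"][voiced])
        t_audio = np.arange(x.size) / sr
        f0_audio = np.interp(t_audio, t_frames, f0_filled)
        phase = 2.0 * np.pi * np.cumsum(f0_audio) / sr
        tone = np.sin(phase) * env
        out = noise + tone / dsp.rms(tone)
    out = out / np.max(np.abs(out)) * 0.9
    return original.derived(out, "p_a", warning=warning)


# ---------------------------------------------------------------------------
# matching pools (ripples and sound textures)

@dataclass
class MatchPool:
    """A pool of candidate AEs with per-member matching features.

    ``kind='ripple'`` pools carry 6-D features (mean and SD of jitter,
    shimmer and spectral flux); ``kind='tsp'`` pools carry 2-D features
    (mean and SD of the HNR contour).  ``center``/``scale`` hold the
    z-scoring parameters from the most recent match (fitted on the pool
    plus the probe, making distances scale-free).
    """

    kind: str
    members: list
    features: np.ndarray
    feature_names: tuple[str, ...]
    member_params: list = field(default_factory=list)
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("ripple", "tsp"):
            raise ValueError("pool kind must be 'ripple' or 'tsp'")
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape[0] != len(self.members):
            raise ValueError("one feature row per member required")
        durations = {m.n_samples for m in self.members}
        rates = {m.sample_rate for m in self.members}
        if len(durations) > 1 or len(rates) > 1:
            raise ValueError("pool members must share duration and rate")


def synth_ripple(velocity_hz: float, density_cyc_oct: float, depth: float,
                 duration_ms: float, sample_rate: int,
                 rng: np.random.Generator, n_carriers: int = 64,
                 f_low: float = 125.0) -> np.ndarray:
    """One dynamic moving ripple: log-spaced carriers with a drifting
    sinusoidal spectro-temporal envelope."""
    n = int(round(duration_ms * sample_rate / 1000.0))
    t = np.arange(n) / sample_rate
    f_high = 0.45 * sample_rate
    freqs = np.geomspace(f_low, f_high, n_carriers)
    octaves = np.log2(freqs / f_low)
    phases = rng.uniform(0, 2 * np.pi, n_carriers)
    ripple_phase = rng.uniform(0, 2 * np.pi)
    # a_i(t) = 1 + depth * sin(2*pi*(velocity*t + density*octave_i) + phi)
    arg = (2 * np.pi * (velocity_hz * t[None, :]
                        + density_cyc_oct * octaves[:, None]) + ripple_phase)
    envel = 1.0 + depth * np.sin(arg)
    carriers = np.sin(2 * np.pi * freqs[:, None] * t[None, :]
                      + phases[:, None])
    x = (envel * carriers).sum(axis=0)
    return x / np.max(np.abs(x)) * 0.9


def gen_ripple_pool(n: int, velocity_range: tuple[float, float] = (1.0, 30.0),
                    density_range: tuple[float, float] = (0.25, 4.0),
                    depth_range: tuple[float, float] = (0.2, 1.0),
                    duration_ms: float = 500.0, sample_rate: int = 16000,
                    seed: int = 0) -> MatchPool:
    """Pool of dynamic moving ripples with log-uniform parameter sampling."""
    if n < 1:
        raise ValueError("pool size must be at least 1")
    rng = np.random.default_rng(seed)
    members, feats, params = [], [], []
    for i in range(n):
        vel = _sample_loguniform(rng, velocity_range)
        den = _sample_loguniform(rng, density_range)
        dep = (_sample_loguniform(rng, depth_range)
               if depth_range[0] > 0 else rng.uniform(*depth_range))
        x = synth_ripple(vel, den, dep, duration_ms, sample_rate, rng)
        tok = SoundToken(x, sample_rate, category="nonvoice", variant="rip",
                         source_id=f"rip_pool_{i}", token_id=f"rip_pool_{i}")
        members.append(tok)
        feats.append(ripple_match_summary(tok))
        params.append({"velocity_hz": vel, "density_cyc_oct": den,
                       "depth": dep})
    names = ("jitter_mean", "jitter_sd", "shimmer_mean", "shimmer_sd",
             "flux_mean", "flux_sd")
    return MatchPool("ripple", members, np.stack(feats), names, params)


def _sample_loguniform(rng: np.random.Generator,
                       bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    if lo <= 0:
        raise ValueError("log-uniform sampling requires positive bounds")
    if lo == hi:
        return float(lo)
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def synth_tsp(temporal_corr: float, frequency_corr: float, duration_ms: float,
              sample_rate: int, rng: np.random.Generator, n_bands: int = 30,
              hop_ms: float = 10.0, level_sd_db: float = 10.0) -> np.ndarray:
    """One Gaussian-process sound texture.

    A Gaussian field with separable exponential correlations (temporal
    length in seconds, spectral length in octaves) is sampled on a
    time x band grid and rendered as per-band level envelopes (dB scale,
    SD ``level_sd_db``) applied to bandpass noise.
    """
    n = int(round(duration_ms * sample_rate / 1000.0))
    hop = max(int(round(hop_ms * sample_rate / 1000.0)), 1)
    n_frames = max(n // hop, 2)
    t = np.arange(n_frames) * hop / sample_rate
    edges = dsp.octave_band_edges(sample_rate, n_bands, fmin=80.0)
    centers_oct = np.log2(np.sqrt(edges[:-1] * edges[1:]) / edges[0])

    def corr_chol(coords: np.ndarray, length: float) -> np.ndarray:
        d = np.abs(coords[:, None] - coords[None, :])
        c = np.exp(-d / max(length, 1e-6))
        return np.linalg.cholesky(c + 1e-9 * np.eye(coords.size))

    lt = corr_chol(t, temporal_corr)
    lf = corr_chol(centers_oct, frequency_corr)
    g = lf @ rng.standard_normal((n_bands, n_frames)) @ lt.T

    noise = rng.standard_normal(n)
    spec = np.fft.rfft(noise)
    freqs = np.fft.rfftfreq(n, 1.0 / sample_rate)
    frame_t = np.arange(n) / sample_rate
    out = np.zeros(n)
    for b in range(n_bands):
        mask = (freqs >= edges[b]) & (freqs < edges[b + 1])
        band = np.fft.irfft(spec * mask, n=n)
        env_db = np.interp(frame_t, t, g[b])
        out += band * 10 ** (level_sd_db * env_db / 20.0)
    return out / np.max(np.abs(out)) * 0.9


def gen_tsp_pool(n: int, corr_range: tuple[float, float] = (0.01, 2.0),
                 duration_ms: float = 500.0, sample_rate: int = 16000,
                 seed: int = 0) -> MatchPool:
    """Pool of sound textures with log-uniform correlation lengths."""
    if n < 1:
        raise ValueError("pool size must be at least 1")
    rng = np.random.default_rng(seed)
    members, feats, params = [], [], []
    for i in range(n):
        lt = _sample_loguniform(rng, corr_range)
        lf = _sample_loguniform(rng, corr_range)
        x = synth_tsp(lt, lf, duration_ms, sample_rate, rng)
        tok = SoundToken(x, sample_rate, category="nonvoice", variant="tsp",
                         source_id=f"tsp_pool_{i}", token_id=f"tsp_pool_{i}")
        members.append(tok)
        feats.append(np.asarray(hnr_summary(tok)))
        params.append({"temporal_corr": lt, "frequency_corr": lf})
    return MatchPool("tsp", members, np.stack(feats),
                     ("hnr_mean", "hnr_sd"), params)


def match_from_pool(original: SoundToken, pool: MatchPool) -> SoundToken:
    """Select the pool member nearest the original in normalized feature space.

    Features are z-scored over the pool plus the probe; the member with the
    smallest Euclidean distance wins (ties -> lowest member index).  The
    selected waveform is re-labeled with the original's category and
    provenance.
    """
    if len(pool.members) == 0:
        raise ValueError("pool is empty")
    if pool.kind == "ripple":
        probe = ripple_match_summary(original)
    else:
        probe = np.asarray(hnr_summary(original))
    stack = np.vstack([pool.features, probe[None, :]])
    center = stack.mean(axis=0)
    scale = stack.std(axis=0)
    scale[scale == 0] = 1.0
    pool.center, pool.scale = center, scale
    z = (pool.features - center) / scale
    zp = (probe - center) / scale
    dists = np.linalg.norm(z - zp[None, :], axis=1)
    best = int(np.argmin(dists))
    variant = "rip" if pool.kind == "ripple" else "tsp"
    member = pool.members[best]
    return SoundToken(samples=member.samples.copy(),
                      sample_rate=member.sample_rate,
                      category=original.category, variant=variant,
                      source_id=original.source_id or original.token_id,
                      token_id=f"{variant}_{original.token_id}")


def make_acoustic_equivalents(original: SoundToken, seed: int,
                              ripple_pool: MatchPool | None = None,
                              tsp_pool: MatchPool | None = None,
                              finalize: bool = True) -> dict[str, SoundToken]:
    """All five AEs for one original token (pools optional)."""
    aes = {
        "e_s": synth_env_spec(original, seed),
        "scr": synth_scrambled(original, seed=seed + 1),
        "p_a": synth_pitch_amp(original, seed=seed + 2),
    }
    if ripple_pool is not None:
        aes["rip"] = match_from_pool(original, ripple_pool)
    if tsp_pool is not None:
        aes["tsp"] = match_from_pool(original, tsp_pool)
    if finalize:
        aes = {k: finalize_sound(v) for k, v in aes.items()}
    return aes
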