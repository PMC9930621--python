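"""The five acoustic-equivalent transformations and finalization."""

import numpy as np
import pytest
from scipy import fft as sp_fft

from vaparc import ae_synthesis as ae
from vaparc import dsp
from vaparc.core import SoundToken

SR = 16000


# ---------------------------------------------------------------------------
# envelope/spectrum AE


def test_env_spec_preserves_duration_and_bookkeeping(voice_token):
    out = ae.synth_env_spec(voice_token, seed=3)
    assert out.n_samples == voice_token.n_samples
    assert out.sample_rate == voice_token.sample_rate
    assert out.variant == "e_s"
    assert out.category == voice_token.category
    assert out.source_id == voice_token.source_id


def test_spectrum_component_matches_original_magnitude_spectrum(sound_set):
    """Cosine similarity > 0.99, spectra computed with an independent FFT."""
    for tok in sound_set[:5]:
        _, spec_comp = ae.env_spec_components(tok, seed=11)
        mag_orig = np.abs(sp_fft.rfft(tok.samples))
        mag_comp = np.abs(sp_fft.rfft(spec_comp))
        # the component is rescaled to unit RMS; cosine similarity is
        # scale-free
        cos = (mag_orig @ mag_comp) / (np.linalg.norm(mag_orig)
                                       * np.linalg.norm(mag_comp))
        assert cos > 0.99


def test_envelope_component_follows_original_envelope(sound_set):
    # 20 ms smoothing: the carrier noise's own Rayleigh envelope caps the
    # attainable correlation at shorter smoothing windows
    for tok in sound_set[:5]:
        env_comp, _ = ae.env_spec_components(tok, seed=7)
        e_orig = dsp.amplitude_envelope(tok.samples, SR, smooth_ms=20)
        e_comp = dsp.amplitude_envelope(env_comp, SR, smooth_ms=20)
        assert np.corrcoef(e_orig, e_comp)[0, 1] > 0.9


def test_env_spec_on_flat_noise_keeps_flat_envelope(noise_token):
    """Flat-envelope input is a fixed point: the output envelope stays flat
    (coefficient of variation on the order of white noise itself, far below
    that of any modulated token)."""
    env_comp, _ = ae.env_spec_components(noise_token, seed=2)
    e_in = dsp.amplitude_envelope(noise_token.samples, SR, smooth_ms=10)
    e_out = dsp.amplitude_envelope(env_comp, SR, smooth_ms=10)
    assert e_in.std() / e_in.mean() < 0.15
    assert e_out.std() / e_out.mean() < 0.15


def test_env_spec_rejects_silence():
    silent = SoundToken(np.zeros(8000), SR, "voice")
    with pytest.raises(ValueError, match="ilent"):
        ae.synth_env_spec(silent, seed=0)


# ---------------------------------------------------------------------------
# scrambled AE


def test_scramble_preserves_long_term_spectrum(voice_token):
    out = ae.synth_scrambled(voice_token, seed=5)
    _, m_in = dsp.magnitude_spectrogram(voice_token.samples, SR)
    _, m_out = dsp.magnitude_spectrogram(out.samples, SR)
    corr = np.corrcoef(m_in.mean(axis=0), m_out.mean(axis=0))[0, 1]
    assert corr > 0.95
    assert out.n_samples == voice_token.n_samples


def test_degenerate_scramble_is_identity(voice_token):
    out = ae.synth_scrambled(voice_token, segment_ms=500,
                             local_window_ms=500, n_bands=1, seed=0)
    assert np.max(np.abs(out.samples - voice_token.samples)) < 1e-10


def test_scramble_destroys_slow_envelope_structure():
    """Envelope autocorrelation beyond the local window drops."""
    t = np.arange(8000) / SR
    carrier = np.random.default_rng(0).standard_normal(8000)
    x = (1.0 + 0.95 * np.sign(np.sin(2 * np.pi * 3 * t))) * carrier
    tok = SoundToken(x / np.abs(x).max(), SR, "nonvoice", token_id="am")
    out = ae.synth_scrambled(tok, segment_ms=25, local_window_ms=100,
                             n_bands=4, seed=8)
    env_in = dsp.amplitude_envelope(tok.samples, SR, smooth_ms=5)
    env_out = dsp.amplitude_envelope(out.samples, SR, smooth_ms=5)
    ac_in = dsp.envelope_autocorr(env_in)
    ac_out = dsp.envelope_autocorr(env_out)
    lag = int(0.160 * SR)  # beyond the 100 ms local window
    assert abs(ac_out[lag]) < abs(ac_in[lag])


def test_scramble_rejects_invalid_windows(voice_token):
    with pytest.raises(ValueError):
        ae.synth_scrambled(voice_token, segment_ms=300, local_window_ms=100)
    with pytest.raises(ValueError):
        ae.synth_scrambled(voice_token, segment_ms=25, local_window_ms=900)


# ---------------------------------------------------------------------------
# pitch/amplitude AE


def test_pitch_amp_tracks_a_pure_tone(tone_token):
    out = ae.synth_pitch_amp(tone_token, seed=1)
    assert out.n_samples == tone_token.n_samples
    assert out.warning is None
    mag = np.abs(sp_fft.rfft(out.samples))
    freqs = np.fft.rfftfreq(out.n_samples, 1.0 / SR)
    sel = (freqs > 50) & (freqs < 7000)
    peak = freqs[sel][np.argmax(mag[sel])]
    assert peak == pytest.approx(200.0, abs=2.0)


def test_pitch_amp_preserves_intensity_envelope(voice_token):
    out = ae.synth_pitch_amp(voice_token, seed=2)
    e_in = dsp.amplitude_envelope(voice_token.samples, SR, smooth_ms=20)
    e_out = dsp.amplitude_envelope(out.samples, SR, smooth_ms=20)
    assert np.corrcoef(e_in, e_out)[0, 1] > 0.9


def test_pitch_amp_falls_back_to_noise_when_unvoiced(noise_token):
    out = ae.synth_pitch_amp(noise_token, seed=3)
    assert out.warning is not None
    assert out.n_samples == noise_token.n_samples


# ---------------------------------------------------------------------------
# pools and matching


def test_ripple_pool_size_and_parameters():
    pool = ae.gen_ripple_pool(12, seed=4)
    assert len(pool.members) == 12
    assert pool.features.shape == (12, 6)
    for p in pool.member_params:
        assert 1.0 <= p["velocity_hz"] <= 30.0
        assert 0.25 <= p["density_cyc_oct"] <= 4.0
        assert 0.2 <= p["depth"] <= 1.0
    with pytest.raises(ValueError):
        ae.gen_ripple_pool(0)


def _narrowband_mod_peak(x: np.ndarray, lo: float, hi: float) -> float:
    spec = sp_fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, 1.0 / SR)
    band = np.where((freqs >= lo) & (freqs < hi), spec, 0)
    env = dsp.amplitude_envelope(np.fft.irfft(band, n=x.size), SR,
                                 smooth_ms=5)
    mf, ms = dsp.modulation_spectrum(env, SR)
    sel = (mf > 1.0) & (mf < 40.0)
    return float(mf[sel][np.argmax(ms[sel])])


def test_ripple_velocity_sets_temporal_modulation_rate():
    rng = np.random.default_rng(0)
    for velocity in (4.0, 8.0):
        x = ae.synth_ripple(velocity, 1.0, 0.9, 500, SR, rng)
        assert _narrowband_mod_peak(x, 950, 1150) == pytest.approx(
            velocity, abs=0.5)


def _nb_mod_prominence(x: np.ndarray, velocity: float) -> float:
    """Peak-to-background ratio at the ripple rate in a narrow band."""
    spec = sp_fft.rfft(x)
    freqs = np.fft.rfftfreq(x.size, 1.0 / SR)
    band = np.where((freqs >= 950) & (freqs < 1150), spec, 0)
    env = dsp.amplitude_envelope(np.fft.irfft(band, n=x.size), SR,
                                 smooth_ms=5)
    mf, ms = dsp.modulation_spectrum(env, SR)
    at_rate = ms[(mf >= velocity - 1) & (mf <= velocity + 1)].max()
    background = np.median(ms[(mf > 1) & (mf < 40)])
    return float(at_rate / background)


def test_zero_depth_ripple_has_no_modulation_peak():
    rng = np.random.default_rng(1)
    x0 = ae.synth_ripple(4.0, 1.0, 0.0, 500, SR, rng)
    x9 = ae.synth_ripple(4.0, 1.0, 0.9, 500, SR, rng)
    assert _nb_mod_prominence(x9, 4.0) > 3 * _nb_mod_prominence(x0, 4.0)


def test_tsp_pool_durations_and_logged_correlations():
    pool = ae.gen_tsp_pool(6, seed=5)
    assert len(pool.members) == 6
    assert all(m.duration_ms == pytest.approx(500.0) for m in pool.members)
    assert pool.features.shape == (6, 2)  # 2-D HNR matching space
    for p in pool.member_params:
        assert 0.01 <= p["temporal_corr"] <= 2.0
        assert 0.01 <= p["frequency_corr"] <= 2.0
    with pytest.raises(ValueError):
        ae.gen_tsp_pool(0)


def test_tsp_temporal_correlation_slows_envelope_dynamics():
    """Longer temporal correlation -> band-level envelopes persist longer.

    Measured as the ensemble-pooled lag correlation of log band energies
    (pooling over textures and bands makes the statistic stable even when a
    single slow realization is nearly constant).
    """

    def lag_corr(lt: float, reps: int = 6, lag_frames: int = 6) -> float:
        rng = np.random.default_rng(2)
        now, later = [], []
        for _ in range(reps):
            x = ae.synth_tsp(lt, 0.5, 500, SR, rng)
            freqs, mags = dsp.magnitude_spectrogram(x, SR, 20, 10)
            be = dsp.band_energies(freqs, mags,
                                   dsp.octave_band_edges(SR, 12))
            now.append(be[:-lag_frames].ravel())
            later.append(be[lag_frames:].ravel())
        return float(np.corrcoef(np.concatenate(now),
                                 np.concatenate(later))[0, 1])

    c_min, c_mid, c_max = (lag_corr(lt) for lt in (0.02, 0.2, 2.0))
    assert c_min < c_mid < c_max


def test_match_from_pool_equals_brute_force(sound_set):
    pool = ae.gen_tsp_pool(40, seed=6)
    for tok in sound_set[:4]:
        chosen = ae.match_from_pool(tok, pool)
        # brute-force oracle: exhaustive distance enumeration
        from vaparc.acoustic_features import hnr_summary
        probe = np.asarray(hnr_summary(tok))
        stack = np.vstack([pool.features, probe])
        center, scale = stack.mean(0), stack.std(0)
        scale[scale == 0] = 1
        z = (pool.features - center) / scale
        zp = (probe - center) / scale
        best = int(np.argmin(((z - zp) ** 2).sum(axis=1)))
        assert np.array_equal(chosen.samples, pool.members[best].samples)
        assert chosen.category == tok.category
        assert chosen.variant == "tsp"


def test_match_returns_exact_duplicate_when_present(voice_token):
    from vaparc.acoustic_features import hnr_summary
    pool = ae.gen_tsp_pool(10, seed=7)
    # plant the probe's own features at index 4
    pool.features[4] = np.asarray(hnr_summary(voice_token))
    chosen = ae.match_from_pool(voice_token, pool)
    assert np.array_equal(chosen.samples, pool.members[4].samples)


def test_match_rejects_empty_pool(voice_token):
    pool = ae.gen_tsp_pool(1, seed=8)
    pool.members = []
    pool.features = np.empty((0, 2))
    with pytest.raises(ValueError):
        ae.match_from_pool(voice_token, pool)


# ---------------------------------------------------------------------------
# finalization


def test_ramp_follows_half_cosine():
    tok = SoundToken(np.ones(8000), SR, "voice")
    out = ae.finalize_sound(tok, ramp_ms=5.0)
    n = 80  # 5 ms at 16 kHz
    expected = 0.5 * (1 - np.cos(np.pi * np.arange(n) / (n - 1)))
    gain = out.samples[:n] / out.samples[n:2 * n].mean()
    assert np.max(np.abs(gain - expected)) < 1e-6


def test_finalized_tokens_share_rms_exactly(sound_set):
    rms_values = [dsp.rms(ae.finalize_sound(t).samples) for t in sound_set]
    ref = rms_values[0]
    for r in rms_values[1:]:
        assert abs(r - ref) / ref < 1e-9


def test_finalize_level_scaling_and_idempotent_rms(voice_token):
    quiet = ae.finalize_sound(voice_token, target_level_db=64.0)
    loud = ae.finalize_sound(voice_token, target_level_db=70.0)
    assert dsp.rms(loud.samples) / dsp.rms(quiet.samples) == pytest.approx(
        10 ** (6 / 20), rel=1e-9)
    twice = ae.finalize_sound(loud)
    assert dsp.rms(twice.samples) == pytest.approx(dsp.rms(loud.samples),
                                                   rel=1e-12)


def test_finalize_rejects_silence():
    with pytest.raises(ValueError):
        ae.finalize_sound(SoundToken(np.zeros(100), SR, "voice"))


def test_every_ae_keeps_duration_rate_and_category(sound_set):
    tok = sound_set[1]
    rip_pool = ae.gen_ripple_pool(5, seed=9)
    tsp_pool = ae.gen_tsp_pool(5, seed=10)
    aes = ae.make_acoustic_equivalents(tok, seed=3, ripple_pool=rip_pool,
                                       tsp_pool=tsp_pool)
    assert set(aes) == {"e_s", "scr", "p_a", "rip", "tsp"}
    for variant, out in aes.items():
        assert out.variant == variant
        assert out.n_samples == tok.n_samples
        assert out.sample_rate == tok.sample_rate
        assert out.category == tok.category
        assert out.source_id == tok.source_id
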