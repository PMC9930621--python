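"""Shared fixtures: small sound sets and a compact synthetic cohort."""

import numpy as np
import pytest

from vaparc import synthetic_data as sd
from vaparc.core import GridSpec, SoundToken


@pytest.fixture(scope="session")
def sound_set():
    """20 finalized tokens (10 voice / 10 nonvoice), 500 ms at 16 kHz."""
    return sd.gen_sound_set(10, 10, 500, 16000, seed=7)


@pytest.fixture(scope="session")
def voice_token(sound_set):
    return next(t for t in sound_set if t.category == "voice")


@pytest.fixture(scope="session")
def tone_token():
    sr = 16000
    t = np.arange(8000) / sr
    return SoundToken(0.5 * np.sin(2 * np.pi * 200.0 * t), sr, "voice",
                      token_id="tone200")


@pytest.fixture(scope="session")
def noise_token():
    rng = np.random.default_rng(123)
    return SoundToken(0.1 * rng.standard_normal(8000), 16000, "nonvoice",
                      token_id="wn")


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(shape=(12, 12, 8))


@pytest.fixture(scope="session")
def small_gt(small_grid):
    """Ground truth on a 12x12x8 grid (small but able to host all blobs)."""
    return sd.gen_ground_truth(small_grid,
                               {"core": 0.05, "acoustic": 0.10,
                                "accessory": 0.06}, seed=5)


@pytest.fixture(scope="session")
def small_cohort(small_gt):
    """12-subject, 4-run cohort at the default SNR on the small grid."""
    return sd.gen_subject_betas(small_gt, n_runs=4, n_subjects=12, seed=9)


@pytest.fixture(scope="session")
def noiseless_cohort(small_gt):
    """Fully deterministic cohort: betas equal the class means exactly."""
    return sd.gen_subject_betas(small_gt, noise_sd=0.0, n_runs=4,
                                n_subjects=4, seed=1, subject_sd_frac=0.0,
                                accessory_ae_sd=0.0)
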