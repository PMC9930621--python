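"""Block-design schedule, design matrix, voxel-wise GLM and group contrasts.

The experiment is a block design: each run contains 12 mini-blocks (one per
condition: 6 sound sets x voice/nonvoice), each block presenting 9 sounds
with jittered inter-sound gaps, separated by silent inter-block gaps.  Task
regressors are block boxcars convolved with a canonical two-gamma HRF plus
one button-press regressor (13 task columns); nuisance columns are 6 motion
parameters and 18 RETROICOR Fourier regressors (cardiac order 3, respiratory
order 4, interaction order 1).

Group inference replaces the classic pooled-error factorial by per-voxel
one-sample t-tests on subject-level contrast values, with Bonferroni
family-wise or Benjamini-Hochberg FDR correction over the analysis mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats
from scipy.special import gammaln

from .core import (AE_VARIANTS, CONDITION_NAMES, N_CONDITIONS, GridSpec,
                   StatMap, Threshold, condition_index)

# ---------------------------------------------------------------------------
# schedule


@dataclass
class Block:
    condition: str
    onset_s: float
    duration_s: float
    sound_onsets: np.ndarray
    repetition: bool = False


@dataclass
class RunSchedule:
    blocks: list
    button_presses: np.ndarray
    duration_s: float


@dataclass
class ExperimentSchedule:
    runs: list
    sound_duration_s: float
    jitter_s: tuple[float, float]
    gap_s: float
    seed: int

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def n_blocks(self) -> int:
        return sum(len(r.blocks) for r in self.runs)

    @property
    def n_repetition_blocks(self) -> int:
        return sum(b.repetition for r in self.runs for b in r.blocks)


def rating_trial_count(n_originals: int = 140, n_ae_variants: int = 5) -> int:
    """Trials in the perceptual similarity rating: one per (original, AE) pair."""
    return n_originals * n_ae_variants


def build_schedule(n_runs: int = 8, blocks_per_run: int = 12,
                   sounds_per_block: int = 9,
                   jitter_s: tuple[float, float] = (0.8, 1.2),
                   gap_s: float = 15.0, n_repetition_blocks: int = 24,
                   seed: int = 0,
                   sound_duration_s: float = 0.5) -> ExperimentSchedule:
    """Randomized block schedule with every condition once per run.

    Block slots are spaced deterministically at the mean block duration plus
    the inter-block gap (so every run has the same nominal length); the
    inter-sound gaps inside a block are jittered uniformly in ``jitter_s``.
    In ``n_repetition_blocks`` of the blocks (chosen over the whole
    experiment) one sound is played twice consecutively and a button press is
    recorded at the block end.
    """
    if blocks_per_run != N_CONDITIONS:
        raise ValueError(
            f"blocks_per_run must equal the number of conditions "
            f"({N_CONDITIONS}), got {blocks_per_run}")
    if n_runs < 1 or sounds_per_block < 1:
        raise ValueError("need at least one run and one sound per block")
    if not (0 < jitter_s[0] <= jitter_s[1]):
        raise ValueError("jitter interval must be positive and ordered")
    if gap_s < 0:
        raise ValueError("inter-block gap must be non-negative")
    total_blocks = n_runs * blocks_per_run
    if not 0 <= n_repetition_blocks <= total_blocks:
        raise ValueError("repetition blocks exceed total block count")

    rng = np.random.default_rng(seed)
    mean_jitter = 0.5 * (jitter_s[0] + jitter_s[1])
    mean_block = (sounds_per_block * sound_duration_s
                  + (sounds_per_block - 1) * mean_jitter)
    slot = mean_block + gap_s
    run_duration = blocks_per_run * mean_block + (blocks_per_run - 1) * gap_s

    rep_flags = np.zeros(total_blocks, dtype=bool)
    rep_flags[rng.choice(total_blocks, size=n_repetition_blocks,
                         replace=False)] = True

    runs = []
    for r in range(n_runs):
        order = rng.permutation(N_CONDITIONS)
        blocks = []
        presses = []
        for b, cond_idx in enumerate(order):
            onset = b * slot
            gaps = rng.uniform(jitter_s[0], jitter_s[1],
                               max(sounds_per_block - 1, 0))
            onsets = onset + np.concatenate(
                [[0.0], np.cumsum(sound_duration_s + gaps)])
            duration = float(onsets[-1] + sound_duration_s - onset)
            is_rep = bool(rep_flags[r * blocks_per_run + b])
            blocks.append(Block(CONDITION_NAMES[cond_idx], onset, duration,
                                onsets, is_rep))
            if is_rep:
                presses.append(onset + duration + 0.5)
        runs.append(RunSchedule(blocks, np.asarray(presses), run_duration))
    return ExperimentSchedule(runs, sound_duration_s, tuple(jitter_s), gap_s,
                              seed)


# ---------------------------------------------------------------------------
# HRF and design matrix


def canonical_hrf(dt: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical two-gamma HRF (peak 6 s, undershoot 16 s, ratio 6), unit sum."""
    t = np.arange(0, duration_s, dt)

    def gamma_pdf(x, shape, scale=1.0):
        x = np.maximum(x, 1e-12)
        return np.exp((shape - 1) * np.log(x) - x / scale
                      - gammaln(shape) - shape * np.log(scale))

    h = gamma_pdf(t, 6.0) - gamma_pdf(t, 16.0) / 6.0
    return h / h.sum()


@dataclass
class DesignMatrix:
    matrix: np.ndarray
    names: list
    tr_s: float
    n_task: int = 13

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def task(self) -> np.ndarray:
        return self.matrix[:, :self.n_task]


@dataclass
class PhysioTrace:
    """Cardiac and respiratory phase time courses sampled at the volume grid."""

    cardiac_phase: np.ndarray
    resp_phase: np.ndarray


def simulate_physio_phases(n_volumes: int, tr_s: float, seed: int = 0,
                           heart_rate_hz: float = 1.1,
                           resp_rate_hz: float = 0.28) -> PhysioTrace:
    """Slowly drifting cardiac/respiratory phases for RETROICOR simulation."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_volumes) * tr_s
    card_rate = heart_rate_hz * (1 + 0.05 * np.sin(2 * np.pi * 0.01 * t
                                                   + rng.uniform(0, 2 * np.pi)))
    resp_rate = resp_rate_hz * (1 + 0.1 * np.sin(2 * np.pi * 0.005 * t
                                                 + rng.uniform(0, 2 * np.pi)))
    cardiac = 2 * np.pi * np.cumsum(card_rate) * tr_s
    resp = 2 * np.pi * np.cumsum(resp_rate) * tr_s
    return PhysioTrace(cardiac, resp)


def retroicor_columns(physio: PhysioTrace,
                      orders: tuple[int, int, int] = (3, 4, 1)
                      ) -> tuple[np.ndarray, list]:
    """Fourier expansion of the physiological phases.

    Orders (cardiac, respiratory, interaction) give 2c + 2r + 4i columns:
    sin/cos of k*phase for each order k, and sin/cos of the sum and
    difference phases for the interaction terms.
    """
    c_ord, r_ord, i_ord = orders
    cols, names = [], []
    for k in range(1, c_ord + 1):
        cols += [np.sin(k * physio.cardiac_phase),
                 np.cos(k * physio.cardiac_phase)]
        names += [f"cardiac_sin{k}", f"cardiac_cos{k}"]
    for k in range(1, r_ord + 1):
        cols += [np.sin(k * physio.resp_phase), np.cos(k * physio.resp_phase)]
        names += [f"resp_sin{k}", f"resp_cos{k}"]
    for k in range(1, i_ord + 1):
        plus = k * (physio.cardiac_phase + physio.resp_phase)
        minus = k * (physio.cardiac_phase - physio.resp_phase)
        cols += [np.sin(plus), np.cos(plus), np.sin(minus), np.cos(minus)]
        names += [f"inter_sin{k}p", f"inter_cos{k}p",
                  f"inter_sin{k}m", f"inter_cos{k}m"]
    return np.column_stack(cols), names


def build_design(schedule: ExperimentSchedule, run: int = 0,
                 tr_s: float = 1.6, n_volumes: int = 197,
                 motion: np.ndarray | None = None,
                 physio: PhysioTrace | None = None,
                 physio_orders: tuple[int, int, int] | None = None,
                 button_duration_s: float = 0.5,
                 dt: float = 0.1) -> DesignMatrix:
    """HRF-convolved design matrix for one run.

    Task columns are the 12 condition block boxcars plus a button-press
    regressor, convolved with the canonical HRF and sampled at the TR grid.
    """
    run_sched = schedule.runs[run]
    if n_volumes * tr_s < run_sched.duration_s:
        raise ValueError(
            f"{n_volumes} volumes at TR {tr_s}s cover {n_volumes * tr_s:.1f}s"
            f" < run length {run_sched.duration_s:.1f}s")
    if physio_orders is not None and physio is None:
        raise ValueError("physio regressors requested but no phase traces")
    if not run_sched.blocks:
        raise ValueError("schedule contains no events")

    n_fine = int(np.ceil(n_volumes * tr_s / dt)) + 1
    boxcars = np.zeros((n_fine, N_CONDITIONS + 1))
    for block in run_sched.blocks:
        ci = CONDITION_NAMES.index(block.condition)
        i0 = int(round(block.onset_s / dt))
        i1 = int(round((block.onset_s + block.duration_s) / dt))
        boxcars[i0:i1, ci] = 1.0
    for press in run_sched.button_presses:
        i0 = int(round(press / dt))
        i1 = int(round((press + button_duration_s) / dt))
        boxcars[i0:i1, N_CONDITIONS] = 1.0
    if np.any(boxcars[:, :N_CONDITIONS].sum(axis=0) == 0):
        missing = [CONDITION_NAMES[i] for i in range(N_CONDITIONS)
                   if boxcars[:, i].sum() == 0]
        raise ValueError(f"conditions without events in run {run}: {missing}")

    hrf = canonical_hrf(dt)
    conv = np.apply_along_axis(lambda col: np.convolve(col, hrf)[:n_fine],
                               0, boxcars)
    vol_idx = np.round(np.arange(n_volumes) * tr_s / dt).astype(int)
    task = conv[vol_idx]
    names = list(CONDITION_NAMES) + ["button_press"]
    cols = [task]

    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n_volumes, 6):
            raise ValueError("motion must be (n_volumes, 6)")
        cols.append(motion)
        names += [f"motion_{i}" for i in range(6)]
    if physio is not None:
        orders = physio_orders or (3, 4, 1)
        if physio.cardiac_phase.size != n_volumes:
            raise ValueError("physio phase traces must match n_volumes")
        pcols, pnames = retroicor_columns(physio, orders)
        cols.append(pcols)
        names += pnames
    return DesignMatrix(np.column_stack(cols) if len(cols) > 1 else task,
                        names, tr_s, n_task=N_CONDITIONS + 1)


# ---------------------------------------------------------------------------
# fitting and group statistics


def fit_glm(timeseries: np.ndarray, design: DesignMatrix
            ) -> tuple[np.ndarray, np.ndarray, int]:
    """Voxel-wise ordinary least squares.

    Returns (betas (voxels x regressors), residual variance (voxels,), df).
    ``timeseries`` is (voxels x time); a 1-D series is treated as one voxel.
    """
    y = np.atleast_2d(np.asarray(timeseries, dtype=float))
    x = design.matrix
    if y.shape[1] != x.shape[0]:
        raise ValueError(
            f"time dimension mismatch: data {y.shape[1]} vs design "
            f"{x.shape[0]}")
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # Identify offending columns from the QR diagonal.
        _, r = np.linalg.qr(x)
        diag = np.abs(np.diag(r))
        bad = [design.names[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"design matrix is rank deficient; offending "
                         f"columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(x, y.T, rcond=None)
    resid = y.T - x @ beta
    df = x.shape[0] - rank
    var = (resid ** 2).sum(axis=0) / max(df, 1)
    return beta.T, var, df


def smooth_subject_maps(values: np.ndarray, grid: GridSpec,
                        fwhm_mm: float) -> np.ndarray:
    """Gaussian-smooth per-subject voxel maps (subjects x voxels)."""
    if fwhm_mm <= 0:
        return values
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) \
        / grid.voxel_size_mm
    out = np.empty_like(values)
    for s in range(values.shape[0]):
        vol = values[s].reshape(grid.shape)
        out[s] = ndimage.gaussian_filter(vol, sigma_vox).ravel()
    return out


def one_sample_t(values: np.ndarray, popmean: float = 0.0
                 ) -> tuple[np.ndarray, np.ndarray, int]:
    """One-sided one-sample t over axis 0, robust to zero variance.

    Returns (t, one-sided p for the positive direction, df).  Voxels whose
    values are all identical get t = +/-inf (p = 0 or 1) when off the null
    mean and t = 0 (p = 0.5) when exactly on it.
    """
    n = values.shape[0]
    mean = values.mean(axis=0) - popmean
    sd = values.std(axis=0, ddof=1)
    df = n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_sd = sd == 0
    t[zero_sd & (mean > 0)] = np.inf
    t[zero_sd & (mean < 0)] = -np.inf
    t[zero_sd & (mean == 0)] = 0.0
    p = stats.t.sf(t, df)
    p[np.isposinf(t)] = 0.0
    p[np.isneginf(t)] = 1.0
    return t, p, df


def group_contrast(subject_betas: np.ndarray, weights: np.ndarray,
                   grid: GridSpec,
                   threshold: Threshold = Threshold("fwe", 0.05),
                   smoothing_fwhm_mm: float = 8.0,
                   analysis_mask: np.ndarray | None = None,
                   contrast_name: str = "contrast") -> StatMap:
    """Group one-sample t-map of a weighted condition combination.

    ``subject_betas`` is (subjects x conditions x voxels), i.e. run-averaged
    condition estimates per subject.  Subject contrast images are smoothed
    before the voxel-wise one-sample t-test (one-sided, positive direction).
    """
    subject_betas = np.asarray(subject_betas, dtype=float)
    if subject_betas.ndim == 4:  # (subjects, runs, conditions, voxels)
        subject_betas = subject_betas.mean(axis=1)
    n_subjects = subject_betas.shape[0]
    if n_subjects < 3:
        raise ValueError("group statistics need at least 3 subjects")
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (subject_betas.shape[1],):
        raise ValueError("one weight per condition required")
    con = np.einsum("c,scv->sv", weights, subject_betas)
    con = smooth_subject_maps(con, grid, smoothing_fwhm_mm)
    t, p, df = one_sample_t(con)
    if analysis_mask is None:
        analysis_mask = np.ones(grid.shape, dtype=bool)
    mask = threshold.apply(p.reshape(grid.shape), analysis_mask)
    return StatMap(t.reshape(grid.shape), p.reshape(grid.shape), mask,
                   threshold, df, contrast_name, grid, analysis_mask)


def interaction_contrast(ae_variant: str, reverse: bool = False) -> np.ndarray:
    """Weights for [(ORIGvoice > ORIGnonvoice) - (AEvoice > AEnonvoice)].

    The reversed interaction (AE contrast exceeding the original contrast)
    is the negation.
    """
    if ae_variant not in AE_VARIANTS:
        raise ValueError(f"unknown AE variant {ae_variant!r}; "
                         f"expected one of {AE_VARIANTS}")
    w = np.zeros(N_CONDITIONS)
    w[condition_index("orig", "voice")] = 1.0
    w[condition_index("orig", "nonvoice")] = -1.0
    w[condition_index(ae_variant, "voice")] = -1.0
    w[condition_index(ae_variant, "nonvoice")] = 1.0
    return -w if reverse else w


def va_contrast() -> np.ndarray:
    """Weights for the voice-area definition [ORIGvoice > ORIGnonvoice]."""
    w = np.zeros(N_CONDITIONS)
    w[condition_index("orig", "voice")] = 1.0
    w[condition_index("orig", "nonvoice")] = -1.0
    return w


def conjunction_mask(stat_maps: list[StatMap]) -> np.ndarray:
    """Minimum-statistic conjunction: significant in every component map."""
    if not stat_maps:
        raise ValueError("need at least one statistic map")
    grid = stat_maps[0].grid
    rule = stat_maps[0].threshold
    for m in stat_maps[1:]:
        if m.grid.shape != grid.shape:
            raise ValueError("conjunction requires maps on a shared grid")
        if m.threshold != rule:
            raise ValueError("conjunction requires a shared threshold rule")
    mask = stat_maps[0].mask.copy()
    for m in stat_maps[1:]:
        mask &= m.mask
    return mask


def selectivity_map(subject_betas: np.ndarray, criterion: float = 1.0 / 3.0
                    ) -> dict:
    """Voice-selectivity maps from the scaled-magnitude criterion.

    Per subject and voxel, every condition c is scaled as
    ``(beta_c - beta_ORIGnonvoice) / (beta_ORIGvoice - beta_ORIGnonvoice)``
    so the original nonvoice condition maps to 0 and the original voice
    condition to 1.  A voxel is voice selective iff all 10 AE conditions stay
    strictly below ``criterion``.  Voxels with a zero denominator are invalid
    and excluded from the group sum.

    Returns dict with ``selective`` (subjects x voxels bool), ``valid``
    (same shape), ``group_sum`` (voxels,), ``n_invalid`` (int) and
    ``scaled`` (subjects x conditions x voxels).
    """
    subject_betas = np.asarray(subject_betas, dtype=float)
    if subject_betas.ndim == 4:
        subject_betas = subject_betas.mean(axis=1)
    iv = condition_index("orig", "voice")
    inv = condition_index("orig", "nonvoice")
    denom = subject_betas[:, iv, :] - subject_betas[:, inv, :]
    valid = denom != 0
    safe = np.where(valid, denom, 1.0)
    scaled = (subject_betas - subject_betas[:, inv:inv + 1, :]) \
        / safe[:, None, :]
    ae_idx = [condition_index(v, c) for v in AE_VARIANTS
              for c in ("voice", "nonvoice")]
    selective = np.all(scaled[:, ae_idx, :] < criterion, axis=1) & valid
    group_sum = selective.sum(axis=0)
    return {
        "selective": selective,
        "valid": valid,
        "group_sum": group_sum,
        "n_invalid": int((~valid).sum()),
        "scaled": scaled,
    }
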