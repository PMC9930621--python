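"""Synthetic sounds and synthetic multi-subject voxel cohorts.

Because no recorded stimuli or brain data ship with the package, this module
generates both sides of the experiment:

* sound tokens with voice-like (harmonic, formant-shaped, amplitude-
  modulated) and nonvoice-like (noise burst, tone, chirp, click train)
  structure, for the stimulus-side analyses;

* voxel "beta" cohorts on a small 3-D grid with four ground-truth voxel
  classes mirroring the parcellation the pipeline is meant to recover:

  - ``core``       voxels respond more to voice than nonvoice for the
                   *original* sounds only (a univariate amplitude effect);
  - ``acoustic``   voxels carry (i) a shared voice>nonvoice amplitude effect
                   for originals and the envelope/spectrum and scrambled AEs
                   (so the interaction contrast with those AEs vanishes) and
                   (ii) a zero-mean multivoxel pattern distinguishing voice
                   from nonvoice, shared across {orig, e_s, scr}, which only
                   multivariate decoding can see;
  - ``accessory``  voxels show a weak voice amplitude effect for the
                   originals and a weaker one for e_s/scr;
  - ``null``       voxels contain noise only.

The multivoxel pattern lives on the morphological erosion of the acoustic
field by the searchlight ball.  A searchlight centered anywhere in the
labeled acoustic field then overlaps the pattern, while a searchlight
centered outside sees none of it: the set of decodable centers equals the
labeled field instead of a dilated version of it, which makes voxel-level
recovery scoring meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import chirp as _chirp

from . import glm
from .ae_synthesis import finalize_sound
from .core import (CONDITIONS, N_CONDITIONS, GridSpec, SoundToken,
                   condition_index)

CLASS_NULL = 0
CLASS_CORE = 1
CLASS_ACOUSTIC = 2
CLASS_ACCESSORY = 3
CLASS_NAMES = {CLASS_NULL: "null", CLASS_CORE: "core",
               CLASS_ACOUSTIC: "acoustic", CLASS_ACCESSORY: "accessory"}

#: Fraction of the voice>nonvoice effect carried by each class and condition
#: (columns scaled by ``effect_size`` when betas are generated).
_PATTERN_VARIANTS = ("orig", "e_s", "scr")


# ---------------------------------------------------------------------------
# sound tokens


def _voice_token(rng: np.random.Generator, n: int, sr: int,
                 f0_range: tuple[float, float]) -> np.ndarray:
    """Harmonic complex with time-varying F0, formants and syllabic AM."""
    t = np.arange(n) / sr
    f0_lo, f0_hi = f0_range
    base = rng.uniform(f0_lo * 1.1, f0_hi * 0.8)
    drift = rng.uniform(-0.25, 0.25) * base
    vibrato = rng.uniform(0.005, 0.02) * base
    f0 = base + drift * (t / t[-1] - 0.5) \
        + vibrato * np.sin(2 * np.pi * rng.uniform(3, 7) * t
                           + rng.uniform(0, 2 * np.pi))
    f0 = np.clip(f0, f0_lo, f0_hi)
    phase0 = 2 * np.pi * np.cumsum(f0) / sr

    formants = (rng.uniform(300, 900), rng.uniform(1000, 2500))
    bandwidths = (150.0, 250.0)
    x = np.zeros(n)
    n_harm = int(0.45 * sr / f0.max())
    for h in range(1, max(n_harm, 3) + 1):
        fh = h * f0.mean()
        if fh > 0.45 * sr:
            break
        gain = sum(np.exp(-0.5 * ((fh - fc) / bw) ** 2)
                   for fc, bw in zip(formants, bandwidths))
        gain = (0.15 + gain) / h ** 0.5
        x += gain * np.sin(h * phase0 + rng.uniform(0, 2 * np.pi) * 0.0)

    # syllable-like amplitude modulation
    n_syll = rng.integers(1, 4)
    env = np.zeros(n)
    for k in range(n_syll):
        center = (k + 0.5) / n_syll * t[-1] + rng.uniform(-0.03, 0.03)
        width = t[-1] / n_syll * rng.uniform(0.35, 0.5)
        env += np.exp(-0.5 * ((t - center) / width) ** 2)
    env = 0.25 + env / env.max()
    x *= env
    x += 0.01 * np.sqrt((x ** 2).mean()) * rng.standard_normal(n)  # breath
    return x


def _nonvoice_token(rng: np.random.Generator, n: int, sr: int,
                    kind: str) -> np.ndarray:
    t = np.arange(n) / sr
    if kind == "noise":
        x = rng.standard_normal(n)
        lo = rng.uniform(200, 2000)
        hi = lo * rng.uniform(2, 6)
        spec = np.fft.rfft(x)
        freqs = np.fft.rfftfreq(n, 1 / sr)
        spec[(freqs < lo) | (freqs > min(hi, 0.45 * sr))] = 0
        x = np.fft.irfft(spec, n=n)
        env = 0.3 + 0.7 * np.abs(np.sin(2 * np.pi * rng.uniform(2, 8) * t))
        return x * env
    if kind == "tone":
        f = rng.uniform(300, 3000)
        return np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    if kind == "chirp":
        f0 = rng.uniform(200, 1000)
        f1 = f0 * rng.uniform(2, 5)
        return _chirp(t, f0=f0, f1=f1, t1=t[-1], method="logarithmic")
    if kind == "clicks":
        rate = rng.uniform(20, 100)
        x = np.zeros(n)
        period = int(sr / rate)
        decay = np.exp(-np.arange(min(period, 200)) / (0.002 * sr))
        for start in range(rng.integers(0, period), n, period):
            seg = min(decay.size, n - start)
            x[start:start + seg] += decay[:seg] * rng.uniform(0.7, 1.0)
        return x
    raise ValueError(kind)


def gen_sound_set(n_voice: int, n_nonvoice: int, duration_ms: float = 500.0,
                  sample_rate: int = 16000, seed: int = 0,
                  f0_range: tuple[float, float] = (100.0, 300.0),
                  finalize: bool = True) -> list[SoundToken]:
    """Seeded synthetic voice and nonvoice token sets.

    Voice tokens are harmonic complexes with time-varying F0 in ``f0_range``,
    a two-formant spectral envelope and syllabic amplitude modulation;
    nonvoice tokens cycle through noise bursts, pure tones, chirps and click
    trains.  All tokens are finalized (5 ms ramps, common level) by default.
    """
    if n_voice < 0 or n_nonvoice < 0:
        raise ValueError("token counts must be non-negative")
    if duration_ms <= 0 or sample_rate <= 0:
        raise ValueError("duration and sample rate must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_ms * sample_rate / 1000.0))
    kinds = ("noise", "tone", "chirp", "clicks")
    tokens: list[SoundToken] = []
    for i in range(n_voice):
        x = _voice_token(rng, n, sample_rate, f0_range)
        tokens.append(SoundToken(x, sample_rate, "voice", "orig",
                                 token_id=f"voice_{i:03d}",
                                 source_id=f"voice_{i:03d}"))
    for i in range(n_nonvoice):
        x = _nonvoice_token(rng, n, sample_rate, kinds[i % len(kinds)])
        tokens.append(SoundToken(x, sample_rate, "nonvoice", "orig",
                                 token_id=f"nonvoice_{i:03d}",
                                 source_id=f"nonvoice_{i:03d}"))
    if finalize:
        tokens = [finalize_sound(tok) for tok in tokens]
    return tokens


# ---------------------------------------------------------------------------
# ground truth voxel map


def searchlight_ball(radius_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Boolean structuring element of voxel offsets within ``radius_mm``."""
    r_vox = int(np.floor(radius_mm / voxel_size_mm))
    size = 2 * r_vox + 1
    grid = np.indices((size, size, size)) - r_vox
    dist = np.sqrt((grid ** 2).sum(axis=0)) * voxel_size_mm
    return dist <= radius_mm + 1e-9


@dataclass
class GroundTruthMap:
    """Synthetic voxel class labels and effect parameters.

    ``voxel_class`` holds {0 null, 1 core, 2 acoustic, 3 accessory} on the
    grid.  ``pattern`` holds the signed multivoxel pattern weights (zero
    outside its support, which is the acoustic field eroded by the
    searchlight ball; the sign alternates like a checkerboard so weights sum
    to ~0 within any searchlight-sized neighborhood).
    ``amplitude_effects`` maps class name -> length-12 array of condition
    amplitudes per unit effect size.
    """

    grid: GridSpec
    voxel_class: np.ndarray
    pattern: np.ndarray
    amplitude_effects: dict
    pattern_scale: float
    searchlight_radius_mm: float
    seed: int
    blob_centers: dict = field(default_factory=dict)

    def class_mask(self, label: int) -> np.ndarray:
        return self.voxel_class == label

    @property
    def pattern_support(self) -> np.ndarray:
        return self.pattern != 0

    def condition_means(self, effect_size: float = 1.0) -> np.ndarray:
        """Noise-free condition means (conditions x voxels)."""
        v = self.voxel_class.ravel()
        pat = self.pattern.ravel()
        means = np.zeros((N_CONDITIONS, v.size))
        for label, name in CLASS_NAMES.items():
            if name == "null":
                continue
            sel = v == label
            means[:, sel] += self.amplitude_effects[name][:, None]
        for variant in _PATTERN_VARIANTS:
            means[condition_index(variant, "voice")] += pat
            means[condition_index(variant, "nonvoice")] -= pat
        return means * effect_size


def _default_amplitudes() -> dict:
    """Per-class condition amplitudes per unit effect size.

    core:       voice>nonvoice for originals only (full effect);
    acoustic:   roughly half effect for the voice condition of orig/e_s/scr
                -- shared across those sets so the e_s/scr interaction
                contrasts stay small while the voxels sit inside the
                univariate voice area.  The original sounds get a small
                extra margin (0.55 vs 0.50) so the original contrast
                dominates its AE counterparts at every acoustic voxel, as
                in the observed effect-size profile;
    accessory:  effect/3 for original voice, effect/6 for e_s/scr voice.
    """
    amp = {name: np.zeros(N_CONDITIONS) for name in
           ("core", "acoustic", "accessory")}
    amp["core"][condition_index("orig", "voice")] = 1.0
    for variant in _PATTERN_VARIANTS:
        amp["acoustic"][condition_index(variant, "voice")] = 0.5
    amp["acoustic"][condition_index("orig", "voice")] = 0.55
    amp["accessory"][condition_index("orig", "voice")] = 1.0 / 3.0
    amp["accessory"][condition_index("e_s", "voice")] = 1.0 / 6.0
    amp["accessory"][condition_index("scr", "voice")] = 1.0 / 6.0
    return amp


def _place_blobs(grid: GridSpec, counts: dict, rng: np.random.Generator,
                 acoustic_margin_vox: float) -> tuple[np.ndarray, dict]:
    """Place one quasi-spherical blob per class per hemisphere."""
    shape = np.array(grid.shape)
    labels = np.zeros(grid.shape, dtype=np.int8)
    coords = np.indices(grid.shape).reshape(3, -1).T.astype(float)
    left_mask, right_mask = grid.hemisphere_masks()
    centers: dict = {}

    radii = {lab: (3 * cnt / (4 * np.pi)) ** (1 / 3)
             for lab, cnt in counts.items() if cnt > 0}
    # The acoustic blob is placed first (it must stay a full ball so that its
    # erosion by the searchlight ball is well formed); the others may be
    # truncated by earlier blobs and only need enough separation to stay
    # contiguous.
    order = sorted(radii, key=lambda k: (k != CLASS_ACOUSTIC, -radii[k]))

    for hemi_name, hemi_mask in (("left", left_mask), ("right", right_mask)):
        hemi_flat = hemi_mask.ravel()
        if sum(counts.values()) > hemi_flat.sum():
            raise ValueError("grid too small to host the requested regions")
        placed: list[tuple[np.ndarray, float]] = []
        axis = grid.split_axis
        lo = np.zeros(3)
        hi = shape.astype(float) - 1
        if hemi_name == "left":
            hi[axis] = grid.split_index - 1
        else:
            lo[axis] = grid.split_index
        for lab in order:
            r = radii[lab]
            margin = np.full(3, 1.0)
            if lab == CLASS_ACOUSTIC:
                # acoustic blobs stay fully inside the grid so the pattern
                # support (erosion by the searchlight ball) is well formed
                margin = np.full(3, r + acoustic_margin_vox)
                margin = np.minimum(margin, (hi - lo) / 2.0 - 0.51)
            box_lo = lo + margin
            box_hi = hi - margin
            if np.any(box_hi < box_lo):
                raise ValueError(
                    f"grid too small to place the {CLASS_NAMES[lab]} region")
            center = None
            for _ in range(2000):
                cand = rng.uniform(box_lo, box_hi)
                ok = True
                for (c, rc, c_lab) in placed:
                    if CLASS_ACOUSTIC in (lab, c_lab):
                        need = r + rc + 0.5  # keep the acoustic ball intact
                    else:
                        need = max(r, rc) + 1.0  # truncation is acceptable
                    if np.linalg.norm(cand - c) < need:
                        ok = False
                        break
                if ok:
                    center = cand
                    break
            if center is None:
                raise ValueError(
                    f"could not place the {CLASS_NAMES[lab]} region; "
                    "grid too small for the requested fractions")
            placed.append((center, r, lab))
            dist = np.linalg.norm(coords - center, axis=1)
            free = (labels.ravel() == 0) & hemi_flat
            cand_idx = np.where(free)[0]
            nearest = cand_idx[np.argsort(dist[cand_idx],
                                          kind="stable")[:counts[lab]]]
            flat = labels.ravel()
            flat[nearest] = lab
            labels = flat.reshape(grid.shape)
            centers[(CLASS_NAMES[lab], hemi_name)] = center
    return labels, centers


def gen_ground_truth(grid: GridSpec | tuple[int, int, int] = GridSpec(),
                     region_fractions: dict | None = None, seed: int = 0,
                     pattern_scale: float = 0.1,
                     searchlight_radius_mm: float = 5.0) -> GroundTruthMap:
    """Ground-truth voxel classes as contiguous blobs per hemisphere.

    ``region_fractions`` maps class names to fractions of the whole grid
    (defaults: core 0.05, acoustic 0.05, accessory 0.08); remaining voxels
    are null.  The multivoxel pattern (amplitude ``pattern_scale`` per unit
    effect) is placed on the erosion of the acoustic field by the
    searchlight ball and alternates sign like a checkerboard.
    """
    if not isinstance(grid, GridSpec):
        grid = GridSpec(shape=tuple(grid))
    fractions = {"core": 0.05, "acoustic": 0.05, "accessory": 0.08}
    if region_fractions is not None:
        fractions.update(region_fractions)
    if any(f < 0 for f in fractions.values()) or sum(fractions.values()) > 1:
        raise ValueError("region fractions must be >= 0 and sum to <= 1")

    rng = np.random.default_rng(seed)
    label_of = {"core": CLASS_CORE, "acoustic": CLASS_ACOUSTIC,
                "accessory": CLASS_ACCESSORY}
    counts = {label_of[name]: int(round(fractions[name] * grid.n_voxels / 2))
              for name in fractions}
    counts = {lab: c for lab, c in counts.items() if c > 0}
    if counts:
        ball = searchlight_ball(searchlight_radius_mm, grid.voxel_size_mm)
        margin = (np.array(ball.shape[0]) // 2) + 0.5
        labels = centers = None
        last_err: Exception | None = None
        for _ in range(30):  # random placement can need a few restarts
            try:
                labels, centers = _place_blobs(grid, counts, rng,
                                               float(margin))
                break
            except ValueError as err:
                last_err = err
        if labels is None:
            raise ValueError(str(last_err))
    else:
        labels = np.zeros(grid.shape, dtype=np.int8)
        centers = {}

    pattern = np.zeros(grid.shape)
    if CLASS_ACOUSTIC in counts:
        ball = searchlight_ball(searchlight_radius_mm, grid.voxel_size_mm)
        support = ndimage.binary_erosion(labels == CLASS_ACOUSTIC,
                                         structure=ball, border_value=0)
        if not support.any():
            raise ValueError(
                "acoustic region too small to carry a pattern once eroded "
                "by the searchlight ball; increase its fraction or the grid")
        idx = np.indices(grid.shape).sum(axis=0)
        checker = np.where(idx % 2 == 0, 1.0, -1.0)
        pattern = np.where(support, checker * pattern_scale, 0.0)

    return GroundTruthMap(grid, labels, pattern, _default_amplitudes(),
                          pattern_scale, searchlight_radius_mm, seed, centers)


# ---------------------------------------------------------------------------
# cohorts of beta maps


@dataclass
class SyntheticCohort:
    """Multi-subject, multi-run voxel betas plus their generating truth.

    ``betas`` has shape (subjects, runs, conditions, voxels) with conditions
    in the canonical order of :data:`vaparc.core.CONDITIONS`.
    """

    betas: np.ndarray
    ground_truth: GroundTruthMap
    effect_size: float
    noise_sd: float
    subject_sd_frac: float
    seed: int
    subject_gains: np.ndarray | None = None

    @property
    def n_subjects(self) -> int:
        return self.betas.shape[0]

    @property
    def n_runs(self) -> int:
        return self.betas.shape[1]

    @property
    def grid(self) -> GridSpec:
        return self.ground_truth.grid

    def subject_condition_means(self) -> np.ndarray:
        """(subjects x conditions x voxels) run-averaged betas."""
        return self.betas.mean(axis=1)

    def run_patterns(self, subject: int, variant: str
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-run voice/nonvoice patterns for decoding.

        Returns (X (2*runs x voxels), y (+1 voice / -1 nonvoice), run ids).
        """
        iv = condition_index(variant, "voice")
        inv = condition_index(variant, "nonvoice")
        runs = self.betas.shape[1]
        x = np.concatenate([self.betas[subject, :, iv, :],
                            self.betas[subject, :, inv, :]], axis=0)
        y = np.concatenate([np.ones(runs), -np.ones(runs)])
        groups = np.concatenate([np.arange(runs), np.arange(runs)])
        return x, y, groups


def gen_subject_betas(gt: GroundTruthMap, effect_size: float = 1.0,
                      noise_sd: float = 0.35, n_runs: int = 8,
                      n_subjects: int = 25, seed: int = 0,
                      subject_sd_frac: float = 0.2,
                      accessory_ae_sd: float = 3.0) -> SyntheticCohort:
    """Simulate per-run condition betas for a cohort.

    Per subject, the class-and-condition means from the ground truth are
    scaled by a multiplicative subject gain (one gain per subject and voxel
    class, shared across that class's voxels and conditions) whose SD is
    calibrated so the subject-level SD of the class's peak response equals
    ``subject_sd_frac * effect_size`` -- an absolute between-subject SD of
    20% of the effect by default, making Cohen's d proportional to each
    class's mean response (largest in core).  I.i.d. Gaussian noise of SD
    ``noise_sd`` is added independently per run, condition and voxel.

    The accessory field's weak e_s/scr response gets its own subject gain
    1 + N(0, ``accessory_ae_sd``): its group mean stays at effect/6 (so the
    interaction contrast with e_s/scr stays small and keeps accessory out of
    the core conjunction), but its sign is inconsistent across subjects, so
    group-level cross-decoding of that offset stays at chance -- weak,
    nonspecific AE responsiveness rather than a shared representation.

    ``noise_sd=0`` with ``subject_sd_frac=0`` and ``accessory_ae_sd=0``
    reproduces the deterministic class means exactly.
    """
    if n_runs < 2:
        raise ValueError("cross-validation needs at least 2 runs")
    if noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    rng = np.random.default_rng(seed)
    base = gt.condition_means(effect_size)  # (conditions, voxels)
    v = gt.voxel_class.ravel()
    n_vox = v.size
    class_labels = (CLASS_CORE, CLASS_ACOUSTIC, CLASS_ACCESSORY)
    # Gain SD per class: absolute subject SD of subject_sd_frac*effect at the
    # class's peak response amplitude.
    peaks = np.array([max(gt.amplitude_effects[CLASS_NAMES[lab]].max(), 1e-12)
                      for lab in class_labels])
    gain_sd = subject_sd_frac / peaks
    gains = 1.0 + gain_sd[None, :] * rng.standard_normal(
        (n_subjects, len(class_labels)))
    ae_gains = 1.0 + accessory_ae_sd * rng.standard_normal(n_subjects)

    acc_ae_rows = [condition_index(var, "voice") for var in ("e_s", "scr")]
    accessory = v == CLASS_ACCESSORY
    betas = np.empty((n_subjects, n_runs, N_CONDITIONS, n_vox))
    for s in range(n_subjects):
        subj_mean = base.copy()
        for gi, lab in enumerate(class_labels):
            subj_mean[:, v == lab] *= gains[s, gi]
        for row in acc_ae_rows:
            subj_mean[row, accessory] = (base[row, accessory]
                                         * ae_gains[s])
        noise = noise_sd * rng.standard_normal((n_runs, N_CONDITIONS, n_vox))
        betas[s] = subj_mean[None, :, :] + noise
    return SyntheticCohort(betas, gt, effect_size, noise_sd, subject_sd_frac,
                           seed, gains)


# ---------------------------------------------------------------------------
# BOLD time series for one run


def gen_bold_run(schedule: glm.ExperimentSchedule, run: int,
                 betas_run: np.ndarray, noise_sd: float = 0.0,
                 physio: bool = False, seed: int = 0, tr_s: float = 1.6,
                 n_volumes: int = 197,
                 physio_amp: float = 0.5) -> tuple[np.ndarray, glm.DesignMatrix]:
    """Voxel x time BOLD series for one run from condition betas.

    The series is design x betas (+ physiological confounds when ``physio``
    is set, with random per-voxel amplitudes on the 18 RETROICOR columns)
    plus white noise.  Returns (timeseries (voxels x volumes), the design
    matrix actually used to generate the data, including physio columns
    when enabled).
    """
    betas_run = np.atleast_2d(np.asarray(betas_run, dtype=float))
    if betas_run.shape[0] != N_CONDITIONS:
        raise ValueError(
            f"betas_run must be (n_conditions={N_CONDITIONS}, voxels)")
    rng = np.random.default_rng(seed)
    traces = glm.simulate_physio_phases(n_volumes, tr_s, seed=seed) \
        if physio else None
    design = glm.build_design(schedule, run=run, tr_s=tr_s,
                              n_volumes=n_volumes, physio=traces,
                              physio_orders=(3, 4, 1) if physio else None)
    n_vox = betas_run.shape[1]
    full_betas = np.zeros((design.matrix.shape[1], n_vox))
    full_betas[:N_CONDITIONS] = betas_run
    if physio:
        full_betas[design.n_task:] = physio_amp * rng.standard_normal(
            (design.matrix.shape[1] - design.n_task, n_vox))
    ts = (design.matrix @ full_betas).T
    if noise_sd > 0:
        ts = ts + noise_sd * rng.standard_normal(ts.shape)
    return ts, design
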