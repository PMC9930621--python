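"""Shared domain types for the voice-area parcellation pipeline.

The experiment presents six sound sets -- the original recordings plus five
families of acoustic equivalents (AEs) -- each split into a voice and a
nonvoice category, giving 12 experimental conditions.  Everything downstream
(GLM contrasts, searchlight decoding, parcellation) indexes conditions
through :data:`CONDITIONS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Sound-set variants: the originals and the five acoustic-equivalent families
#: (envelope/spectrum, scrambled, pitch/amplitude, ripple, sound texture).
VARIANTS: tuple[str, ...] = ("orig", "e_s", "scr", "p_a", "rip", "tsp")
AE_VARIANTS: tuple[str, ...] = ("e_s", "scr", "p_a", "rip", "tsp")
CATEGORIES: tuple[str, ...] = ("voice", "nonvoice")

#: The 12 experimental conditions in canonical order (variant-major).
CONDITIONS: tuple[tuple[str, str], ...] = tuple(
    (v, c) for v in VARIANTS for c in CATEGORIES
)
CONDITION_NAMES: tuple[str, ...] = tuple(f"{v}_{c}" for v, c in CONDITIONS)
N_CONDITIONS = len(CONDITIONS)


def condition_index(variant: str, category: str) -> int:
    """Index of a (variant, category) pair in the canonical condition order."""
    try:
        return CONDITIONS.index((variant, category))
    except ValueError:
        raise KeyError(f"unknown condition {variant!r}/{category!r}") from None


@dataclass
class SoundToken:
    """A fixed-duration mono waveform with category and provenance labels.

    ``category`` is the voice/nonvoice label of the *source* recording; AEs
    inherit it so that the same voice-vs-nonvoice contrasts can be run on
    every sound set.  ``variant='orig'`` tokens are their own source.
    """

    samples: np.ndarray
    sample_rate: int
    category: str
    variant: str = "orig"
    source_id: str = ""
    token_id: str = ""
    warning: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("samples must be a 1-D mono waveform")
        if self.category not in CATEGORIES:
            raise ValueError(f"category must be one of {CATEGORIES}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if not self.token_id:
            self.token_id = f"{self.variant}_{self.category}_anon"
        if self.variant == "orig" and not self.source_id:
            self.source_id = self.token_id

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.samples.size / self.sample_rate

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def derived(self, samples: np.ndarray, variant: str,
                warning: str | None = None) -> "SoundToken":
        """A new token derived from this one, keeping category and provenance."""
        return SoundToken(
            samples=samples,
            sample_rate=self.sample_rate,
            category=self.category,
            variant=variant,
            source_id=self.source_id or self.token_id,
            token_id=f"{variant}_{self.token_id}",
            warning=warning,
        )


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the voxel grid: shape, isotropic size and hemisphere split.

    Voxels with index < ``split_index`` along ``split_axis`` belong to the
    left hemisphere; voxels on or beyond the split plane are right.
    """

    shape: tuple[int, int, int] = (20, 20, 12)
    voxel_size_mm: float = 2.75
    split_axis: int = 0
    split_index: int | None = None

    def __post_init__(self) -> None:
        if self.split_index is None:
            object.__setattr__(self, "split_index",
                               self.shape[self.split_axis] // 2)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def hemisphere_masks(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (left, right) hemisphere masks on the grid."""
        idx = np.arange(self.shape[self.split_axis])
        left_1d = idx < self.split_index
        shape = [1, 1, 1]
        shape[self.split_axis] = -1
        left = np.broadcast_to(left_1d.reshape(shape), self.shape).copy()
        return left, ~left


@dataclass(frozen=True)
class Threshold:
    """A voxel-wise significance rule.

    kind:
        ``uncorrected`` -- per-voxel p < alpha;
        ``fwe``        -- Bonferroni over in-mask voxels, p < alpha / n;
        ``fdr``        -- Benjamini-Hochberg at level alpha over in-mask voxels.
    """

    kind: str = "fwe"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.kind not in ("uncorrected", "fwe", "fdr"):
            raise ValueError(f"unknown threshold kind {self.kind!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")

    def apply(self, p: np.ndarray, analysis_mask: np.ndarray | None = None
              ) -> np.ndarray:
        """Binary significance mask for a map of one-sided p-values."""
        p = np.asarray(p, dtype=float)
        if analysis_mask is None:
            analysis_mask = np.ones(p.shape, dtype=bool)
        mask = np.zeros(p.shape, dtype=bool)
        pm = p[analysis_mask]
        if pm.size == 0:
            return mask
        if self.kind == "uncorrected":
            sig = pm < self.alpha
        elif self.kind == "fwe":
            sig = pm < self.alpha / pm.size
        else:  # fdr, Benjamini-Hochberg
            from statsmodels.stats.multitest import multipletests
            sig = multipletests(pm, alpha=self.alpha, method="fdr_bh")[0]
        mask[analysis_mask] = sig
        return mask


@dataclass
class StatMap:
    """Voxel grid of group statistics with its thresholding provenance."""

    t: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    threshold: Threshold
    df: int
    contrast: str
    grid: GridSpec
    analysis_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.t.shape != self.grid.shape:
            raise ValueError("statistic shape does not match grid")
        if self.t.shape != self.p.shape or self.t.shape != self.mask.shape:
            raise ValueError("t, p and mask shapes must agree")


@dataclass
class AccuracyMap:
    """Per-subject voxel grid of decoding accuracies.

    ``scheme`` records how the accuracy was obtained, e.g. ``cv(orig)`` for
    leave-one-run-out cross-validation within a sound set, or
    ``cross(orig->e_s)`` for cross-classification.  Voxels outside the
    analysis mask hold NaN (undefined), never a fake chance value.
    """

    accuracy: np.ndarray
    scheme: str
    radius_mm: float
    n_folds: int
    grid: GridSpec
    subject: int | str = "group"

    def __post_init__(self) -> None:
        finite = self.accuracy[np.isfinite(self.accuracy)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("accuracies must lie in [0, 1]")


@dataclass
class ClassificationResult:
    """Outcome of a voice/nonvoice sound classification."""

    scheme: str
    fold_accuracies: np.ndarray
    kernel: str
    seed: int | None = None

    def __post_init__(self) -> None:
        self.fold_accuracies = np.asarray(self.fold_accuracies, dtype=float)
        if self.fold_accuracies.size == 0:
            raise ValueError("at least one fold accuracy required")
        if self.fold_accuracies.min() < 0 or self.fold_accuracies.max() > 1:
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def mean_accuracy(self) -> float:
        return float(self.fold_accuracies.mean())

    @property
    def n_folds(self) -> int:
        return int(self.fold_accuracies.size)


@dataclass
class Parcellation:
    """Voxel labels {outside=0, core=1, acoustic=2, accessory=3} plus sources."""

    labels: np.ndarray
    original_mask: np.ndarray
    core_mask: np.ndarray
    acoustic_mask: np.ndarray
    grid: GridSpec
    threshold_provenance: dict = field(default_factory=dict)

    LABEL_OUTSIDE = 0
    LABEL_CORE = 1
    LABEL_ACOUSTIC = 2
    LABEL_ACCESSORY = 3

    @property
    def accessory_mask(self) -> np.ndarray:
        return self.labels == self.LABEL_ACCESSORY
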