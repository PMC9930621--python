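"""Assembly of the voice-area parcellation and its coverage statistics.

The original voice area (VA) is the significance mask of the group contrast
[original voice > original nonvoice].  The *core* VA is the conjunction of
the five interaction contrasts [(ORIGvoice > ORIGnonvoice) minus
(AEvoice > AEnonvoice)], intersected with the original VA: voxels whose voice
preference cannot be reduced to any AE.  The *acoustic* VA is the significant
part of the averaged originals->AE cross-classification map inside the
original VA, minus core voxels (core wins on overlap).  Whatever remains of
the original VA is *accessory*.  Coverage percentages are reported per
hemisphere relative to the original VA size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import glm, mvpa
from .core import (AE_VARIANTS, GridSpec, Parcellation, StatMap, Threshold,
                   condition_index)


def round_half_up(x: float, decimals: int = 1) -> float:
    """Decimal rounding with ties away from zero (100*549/1653 -> 33.2)."""
    factor = 10 ** decimals
    return float(np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x))


def coverage_percent(count: int, total: int) -> float:
    """Subfield coverage as a percentage of the original VA, one decimal."""
    if total <= 0:
        return 0.0
    return round_half_up(100.0 * count / total, 1)


@dataclass
class CoverageReport:
    """Per-hemisphere voxel counts, coverage percentages and effect sizes."""

    per_hemisphere: dict
    effect_sizes: dict = field(default_factory=dict)

    def summary_table(self):
        import pandas as pd
        rows = []
        for hemi, d in self.per_hemisphere.items():
            rows.append({"hemisphere": hemi, **d})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mask definitions


def define_original_va(cohort_betas: np.ndarray, grid: GridSpec,
                       threshold: Threshold = Threshold("fwe", 0.05),
                       smoothing_fwhm_mm: float = 0.0,
                       analysis_mask: np.ndarray | None = None) -> StatMap:
    """Group [ORIGvoice > ORIGnonvoice] map; its mask is the original VA."""
    return glm.group_contrast(cohort_betas, glm.va_contrast(), grid,
                              threshold, smoothing_fwhm_mm, analysis_mask,
                              contrast_name="original_va")


def interaction_maps(cohort_betas: np.ndarray, grid: GridSpec,
                     threshold: Threshold = Threshold("fwe", 0.05),
                     smoothing_fwhm_mm: float = 0.0,
                     analysis_mask: np.ndarray | None = None,
                     reverse: bool = False) -> dict[str, StatMap]:
    """The five [(ORIG contrast) minus (AE contrast)] interaction maps."""
    return {
        variant: glm.group_contrast(
            cohort_betas, glm.interaction_contrast(variant, reverse), grid,
            threshold, smoothing_fwhm_mm, analysis_mask,
            contrast_name=f"interaction[{variant}]{'-rev' if reverse else ''}")
        for variant in AE_VARIANTS
    }


def define_core_va(interaction_stat_maps: dict[str, StatMap],
                   original_va_mask: np.ndarray) -> np.ndarray:
    """Conjunction of all five interaction maps inside the original VA."""
    missing = [v for v in AE_VARIANTS if v not in interaction_stat_maps]
    if missing:
        raise ValueError(f"missing interaction maps for {missing}")
    conj = glm.conjunction_mask([interaction_stat_maps[v]
                                 for v in AE_VARIANTS])
    return conj & original_va_mask


def define_acoustic_va(average_cross_map: StatMap,
                       original_va_mask: np.ndarray,
                       core_mask: np.ndarray) -> np.ndarray:
    """Significant averaged cross-classification voxels inside the VA,
    excluding core voxels (core takes precedence on overlap)."""
    if average_cross_map.mask.shape != original_va_mask.shape:
        raise ValueError("masks must share a grid")
    return average_cross_map.mask & original_va_mask & ~core_mask


def assemble_parcellation(original_va: StatMap | np.ndarray,
                          core_mask: np.ndarray, acoustic_mask: np.ndarray,
                          grid: GridSpec,
                          provenance: dict | None = None
                          ) -> tuple[Parcellation, CoverageReport]:
    """Partition the original VA into core / acoustic / accessory.

    Requires core and acoustic to be disjoint subsets of the original VA;
    accessory is the remainder.  Coverage percentages are per hemisphere,
    relative to the original VA voxel count, rounded half-up to one decimal.
    """
    va_mask = original_va.mask if isinstance(original_va, StatMap) \
        else np.asarray(original_va, dtype=bool)
    core_mask = np.asarray(core_mask, dtype=bool)
    acoustic_mask = np.asarray(acoustic_mask, dtype=bool)
    n_core_out = int((core_mask & ~va_mask).sum())
    n_ac_out = int((acoustic_mask & ~va_mask).sum())
    if n_core_out or n_ac_out:
        raise ValueError(
            f"subfields must lie inside the original VA "
            f"({n_core_out} core, {n_ac_out} acoustic voxels outside)")
    n_overlap = int((core_mask & acoustic_mask).sum())
    if n_overlap:
        raise ValueError(
            f"core and acoustic masks overlap in {n_overlap} voxels")

    labels = np.zeros(grid.shape, dtype=np.int8)
    labels[va_mask] = Parcellation.LABEL_ACCESSORY
    labels[acoustic_mask] = Parcellation.LABEL_ACOUSTIC
    labels[core_mask] = Parcellation.LABEL_CORE

    parc = Parcellation(labels, va_mask, core_mask, acoustic_mask, grid,
                        provenance or {})
    left, right = grid.hemisphere_masks()
    per_hemi = {}
    for name, hemi in (("left", left), ("right", right)):
        n_orig = int((va_mask & hemi).sum())
        counts = {
            "n_original": n_orig,
            "n_core": int((core_mask & hemi).sum()),
            "n_acoustic": int((acoustic_mask & hemi).sum()),
            "n_accessory": int((parc.accessory_mask & hemi).sum()),
        }
        counts["percent_core"] = coverage_percent(counts["n_core"], n_orig)
        counts["percent_acoustic"] = coverage_percent(counts["n_acoustic"],
                                                      n_orig)
        counts["percent_accessory"] = coverage_percent(
            counts["n_accessory"], n_orig)
        per_hemi[name] = counts
    return parc, CoverageReport(per_hemi)


def effect_sizes(cohort_betas: np.ndarray, parc: Parcellation) -> dict:
    """Group Cohen's d of (voice - nonvoice) per subfield and sound set.

    Per subject and subfield, the voice-nonvoice beta difference is averaged
    over the subfield's voxels; d = mean / SD across subjects.  Empty
    subfields, and subfields with zero between-subject SD, are flagged with
    d = None.
    """
    betas = np.asarray(cohort_betas, dtype=float)
    if betas.ndim == 4:
        betas = betas.mean(axis=1)
    flat_labels = parc.labels.ravel()
    out: dict = {}
    subfields = {"core": Parcellation.LABEL_CORE,
                 "acoustic": Parcellation.LABEL_ACOUSTIC,
                 "accessory": Parcellation.LABEL_ACCESSORY}
    from .core import VARIANTS
    for sub_name, label in subfields.items():
        sel = flat_labels == label
        out[sub_name] = {}
        for variant in VARIANTS:
            if not sel.any():
                out[sub_name][variant] = {"d": None, "flag": "empty subfield"}
                continue
            iv = condition_index(variant, "voice")
            inv = condition_index(variant, "nonvoice")
            diff = (betas[:, iv, sel] - betas[:, inv, sel]).mean(axis=1)
            sd = diff.std(ddof=1)
            if sd == 0:
                out[sub_name][variant] = {"d": None,
                                          "flag": "zero between-subject SD"}
            else:
                out[sub_name][variant] = {"d": float(diff.mean() / sd),
                                          "flag": None}
    return out


# ---------------------------------------------------------------------------
# end-to-end pipeline and recovery scoring


@dataclass
class PipelineResult:
    original_va: StatMap
    interactions: dict
    cross_group_maps: dict
    average_cross: StatMap
    parcellation: Parcellation
    coverage: CoverageReport
    effect_sizes: dict


def run_parcellation_pipeline(cohort,
                              va_threshold: Threshold = Threshold("fwe", 0.05),
                              interaction_threshold: Threshold =
                              Threshold("fwe", 0.05),
                              cross_threshold: Threshold =
                              Threshold("uncorrected", 0.001),
                              smoothing_fwhm_mm: float = 0.0,
                              radius_mm: float = 5.0) -> PipelineResult:
    """Full analysis: GLM contrasts, searchlight cross-decoding, parcellation.

    Recovery runs default to unsmoothed maps: on a desk-scale grid with
    compact ground-truth fields, smoothing only blurs region boundaries that
    the recovery score is judged against (see the methods note).  Paper-style
    maps can be produced by passing ``smoothing_fwhm_mm=8``.
    """
    grid = cohort.grid
    betas = cohort.subject_condition_means()
    original_va = define_original_va(betas, grid, va_threshold,
                                     smoothing_fwhm_mm)
    inter = interaction_maps(betas, grid, interaction_threshold,
                             smoothing_fwhm_mm)
    core = define_core_va(inter, original_va.mask)

    cross_group: dict[str, StatMap] = {}
    subject_maps = {v: [] for v in AE_VARIANTS}
    for s in range(cohort.n_subjects):
        per_variant = mvpa.searchlight_cross_maps(cohort, s,
                                                  radius_mm=radius_mm)
        for v in AE_VARIANTS:
            subject_maps[v].append(per_variant[v])
    for v in AE_VARIANTS:
        cross_group[v] = mvpa.group_accuracy_map(
            subject_maps[v], smoothing_fwhm_mm=smoothing_fwhm_mm,
            threshold=cross_threshold)
    avg_cross = mvpa.average_cross_maps(cross_group, cross_threshold)

    acoustic = define_acoustic_va(avg_cross, original_va.mask, core)
    parc, coverage = assemble_parcellation(
        original_va, core, acoustic, grid,
        provenance={"va": va_threshold, "interaction": interaction_threshold,
                    "cross": cross_threshold,
                    "smoothing_fwhm_mm": smoothing_fwhm_mm})
    coverage.effect_sizes = effect_sizes(cohort.betas, parc)
    return PipelineResult(original_va, inter, cross_group, avg_cross, parc,
                          coverage, coverage.effect_sizes)


def jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    union = (a | b).sum()
    if union == 0:
        return 1.0
    return float((a & b).sum() / union)


def score_recovery(parc: Parcellation, ground_truth) -> dict:
    """Voxel-level recovery of the ground-truth classes.

    Returns Jaccard indices for core and acoustic, recall of the original VA
    against all effect-carrying voxels, and the fraction of ground-truth
    null voxels that received any label.
    """
    from .synthetic_data import CLASS_ACCESSORY, CLASS_ACOUSTIC, CLASS_CORE
    gt = ground_truth.voxel_class
    truth_core = gt == CLASS_CORE
    truth_acoustic = gt == CLASS_ACOUSTIC
    truth_any = gt != 0
    null_voxels = ~truth_any
    labeled = parc.labels > 0
    return {
        "jaccard_core": jaccard(parc.core_mask, truth_core),
        "jaccard_acoustic": jaccard(parc.acoustic_mask, truth_acoustic),
        "va_recall": float((parc.original_mask & truth_any).sum()
                           / max(truth_any.sum(), 1)),
        "accessory_recall": float(
            (parc.accessory_mask & (gt == CLASS_ACCESSORY)).sum()
            / max((gt == CLASS_ACCESSORY).sum(), 1)),
        "null_labeled_fraction": float((labeled & null_voxels).sum()
                                       / max(null_voxels.sum(), 1)),
    }
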