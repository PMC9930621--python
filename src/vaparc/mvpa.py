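"""Searchlight and ROI decoding of voice vs. nonvoice activation patterns.

Decoding uses a linear support vector machine (C = 1).  Because a searchlight
analysis refits the classifier for every voxel, fold and subject (~10^6 tiny
fits per cohort), the SVM is solved here by dual coordinate descent on the
hinge-loss dual in kernel form, compiled with numba.  The solver is
equivalent to a standard linear C-SVM without intercept on per-fold
standardized features (train-set mean/SD), which makes accuracies invariant
to voxel-wise affine rescalings applied equally to train and test patterns;
scikit-learn's SVC serves as an independent cross-check in the test suite,
not as the execution path.

Two decoding schemes are supported, mirroring the two questions asked of the
data: leave-one-run-out cross-validation within one sound set ("can this
neighborhood distinguish voice from nonvoice here at all?"), and
cross-classification with training on the original sounds and testing on an
AE set ("is the voice/nonvoice representation shared with sounds that only
preserve certain acoustic features?").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import ndimage, stats

from .core import (AE_VARIANTS, AccuracyMap, GridSpec, StatMap, Threshold)
from .glm import one_sample_t

# ---------------------------------------------------------------------------
# linear SVM by dual coordinate descent (kernel form)


@njit(cache=True)
def _dcd_alpha(gram: np.ndarray, y: np.ndarray, c: float, max_passes: int,
               tol: float) -> np.ndarray:
    """Hinge-loss dual coordinate descent; returns the dual coefficients."""
    n = gram.shape[0]
    alpha = np.zeros(n)
    for _ in range(max_passes):
        max_pg = 0.0
        for i in range(n):
            qii = gram[i, i]
            if qii <= 1e-12:
                continue
            g = 0.0
            for j in range(n):
                g += alpha[j] * y[j] * gram[i, j]
            g = g * y[i] - 1.0
            if alpha[i] <= 0.0:
                pg = g if g < 0.0 else 0.0
            elif alpha[i] >= c:
                pg = g if g > 0.0 else 0.0
            else:
                pg = g
            if abs(pg) > max_pg:
                max_pg = abs(pg)
            if pg != 0.0:
                a_new = alpha[i] - g / qii
                if a_new < 0.0:
                    a_new = 0.0
                elif a_new > c:
                    a_new = c
                alpha[i] = a_new
        if max_pg < tol:
            break
    return alpha


@njit(cache=True)
def _accuracy_one_sphere(x_train: np.ndarray, y_train: np.ndarray,
                         x_test: np.ndarray, y_test: np.ndarray,
                         c: float, max_passes: int, tol: float) -> float:
    """Standardize on the train set, fit, and score the test set."""
    n_tr, k = x_train.shape
    n_te = x_test.shape[0]
    xt = np.empty((n_tr, k))
    xe = np.empty((n_te, k))
    for f in range(k):
        m = 0.0
        for i in range(n_tr):
            m += x_train[i, f]
        m /= n_tr
        var = 0.0
        for i in range(n_tr):
            d = x_train[i, f] - m
            var += d * d
        sd = np.sqrt(var / n_tr)
        if sd <= 0.0:
            sd = 1.0
        for i in range(n_tr):
            xt[i, f] = (x_train[i, f] - m) / sd
        for i in range(n_te):
            xe[i, f] = (x_test[i, f] - m) / sd
    gram = xt @ xt.T
    alpha = _dcd_alpha(gram, y_train, c, max_passes, tol)
    correct = 0
    for i in range(n_te):
        f_val = 0.0
        for j in range(n_tr):
            if alpha[j] > 0.0:
                dot = 0.0
                for f in range(k):
                    dot += xt[j, f] * xe[i, f]
                f_val += alpha[j] * y_train[j] * dot
        pred = 1.0 if f_val >= 0.0 else -1.0
        if pred == y_test[i]:
            correct += 1
    return correct / n_te


@njit(cache=True)
def _searchlight_cross(x_train: np.ndarray, y_train: np.ndarray,
                       x_test: np.ndarray, y_test: np.ndarray,
                       neigh: np.ndarray, counts: np.ndarray,
                       c: float, max_passes: int, tol: float) -> np.ndarray:
    """Cross-classification accuracy per searchlight center."""
    n_centers = neigh.shape[0]
    acc = np.empty(n_centers)
    for v in range(n_centers):
        k = counts[v]
        xt = np.empty((x_train.shape[0], k))
        xe = np.empty((x_test.shape[0], k))
        for f in range(k):
            col = neigh[v, f]
            for i in range(x_train.shape[0]):
                xt[i, f] = x_train[i, col]
            for i in range(x_test.shape[0]):
                xe[i, f] = x_test[i, col]
        acc[v] = _accuracy_one_sphere(xt, y_train, xe, y_test, c,
                                      max_passes, tol)
    return acc


@njit(cache=True)
def _searchlight_cv(x: np.ndarray, y: np.ndarray, groups: np.ndarray,
                    neigh: np.ndarray, counts: np.ndarray,
                    c: float, max_passes: int, tol: float) -> np.ndarray:
    """Leave-one-group-out cross-validated accuracy per searchlight center."""
    n_centers = neigh.shape[0]
    n = x.shape[0]
    unique = np.unique(groups)
    acc = np.zeros(n_centers)
    for v in range(n_centers):
        k = counts[v]
        total_correct = 0.0
        total = 0
        for gi in range(unique.size):
            g = unique[gi]
            n_te = 0
            for i in range(n):
                if groups[i] == g:
                    n_te += 1
            n_tr = n - n_te
            xt = np.empty((n_tr, k))
            yt = np.empty(n_tr)
            xe = np.empty((n_te, k))
            ye = np.empty(n_te)
            it = 0
            ie = 0
            for i in range(n):
                if groups[i] == g:
                    for f in range(k):
                        xe[ie, f] = x[i, neigh[v, f]]
                    ye[ie] = y[i]
                    ie += 1
                else:
                    for f in range(k):
                        xt[it, f] = x[i, neigh[v, f]]
                    yt[it] = y[i]
                    it += 1
            fold_acc = _accuracy_one_sphere(xt, yt, xe, ye, c, max_passes,
                                            tol)
            total_correct += fold_acc * n_te
            total += n_te
        acc[v] = total_correct / total
    return acc


# ---------------------------------------------------------------------------
# python-level decoding API

_C_DEFAULT = 1.0
_MAX_PASSES = 200
_TOL = 1e-4


def decode_cross(x_train: np.ndarray, y_train: np.ndarray,
                 x_test: np.ndarray, y_test: np.ndarray,
                 c: float = _C_DEFAULT) -> float:
    """Accuracy of a single model trained on all training rows.

    Labels are +/-1 (or any two values; they are recoded).  Train and test
    must share the voxel (feature) dimension.
    """
    x_train = np.ascontiguousarray(x_train, dtype=np.float64)
    x_test = np.ascontiguousarray(x_test, dtype=np.float64)
    if x_train.shape[1] != x_test.shape[1]:
        raise ValueError("train and test voxel sets differ")
    y_train, y_test = _recode_labels(np.asarray(y_train),
                                     np.asarray(y_test))
    return float(_accuracy_one_sphere(x_train, y_train, x_test, y_test,
                                      c, _MAX_PASSES, _TOL))


def decode_cv(x: np.ndarray, y: np.ndarray, groups: np.ndarray,
              c: float = _C_DEFAULT) -> float:
    """Leave-one-group-out (one run per fold) cross-validated accuracy."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    y = np.asarray(y)
    groups = np.asarray(groups)
    unique = np.unique(groups)
    if unique.size < 2:
        raise ValueError("cross-validation needs at least 2 runs")
    for g in unique:
        train_labels = np.unique(y[groups != g])
        if train_labels.size < 2:
            raise ValueError(f"training fold leaving out run {g} is missing "
                             "a label")
    correct = 0
    total = 0
    for g in unique:
        te = groups == g
        acc = decode_cross(x[~te], y[~te], x[te], y[te], c)
        correct += acc * te.sum()
        total += te.sum()
    return float(correct / total)


def _recode_labels(y_train: np.ndarray, y_test: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Map the two training classes to -1/+1 consistently for both sets."""
    classes = np.unique(y_train)
    if classes.size != 2:
        raise ValueError("binary decoding needs exactly 2 training classes")
    if not np.all(np.isin(y_test, classes)):
        raise ValueError("test labels contain classes unseen in training")
    return (np.where(y_train == classes[1], 1.0, -1.0).astype(np.float64),
            np.where(y_test == classes[1], 1.0, -1.0).astype(np.float64))


# ---------------------------------------------------------------------------
# searchlight geometry


def sphere_offsets(radius_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Integer voxel offsets whose centers lie within ``radius_mm``."""
    r_vox = int(np.floor(radius_mm / voxel_size_mm)) if radius_mm > 0 else 0
    rng = np.arange(-r_vox, r_vox + 1)
    grid = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), axis=-1)
    offsets = grid.reshape(-1, 3)
    dist = np.linalg.norm(offsets * voxel_size_mm, axis=1)
    return offsets[dist <= radius_mm + 1e-9]


def searchlight_indices(grid: GridSpec, radius_mm: float = 5.0,
                        mask: np.ndarray | None = None
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Neighbor lists for every in-mask voxel.

    Returns (centers, neighbors, counts): ``centers`` are flat indices of
    the in-mask searchlight centers, ``neighbors`` is a padded
    (n_centers x max_k) int array of flat voxel indices (padding repeats the
    center, with ``counts`` giving the true neighborhood size).  Neighbors
    are restricted to in-mask, in-bounds voxels.
    """
    if radius_mm < 0:
        raise ValueError("searchlight radius must be non-negative")
    if mask is None:
        mask = np.ones(grid.shape, dtype=bool)
    offsets = sphere_offsets(radius_mm, grid.voxel_size_mm)
    shape = np.array(grid.shape)
    centers_ijk = np.argwhere(mask)
    n_centers = centers_ijk.shape[0]
    max_k = offsets.shape[0]
    neigh = np.empty((n_centers, max_k), dtype=np.int64)
    counts = np.zeros(n_centers, dtype=np.int64)
    center_flat = np.ravel_multi_index(centers_ijk.T, grid.shape)
    for oi, off in enumerate(offsets):
        cand = centers_ijk + off[None, :]
        inb = np.all((cand >= 0) & (cand < shape[None, :]), axis=1)
        flat = np.zeros(n_centers, dtype=np.int64)
        flat[inb] = np.ravel_multi_index(cand[inb].T, grid.shape)
        ok = inb.copy()
        ok[inb] &= mask.ravel()[flat[inb]]
        rows = np.where(ok)[0]
        neigh[rows, counts[rows]] = flat[rows]
        counts[rows] += 1
    # pad with the center voxel so the array is rectangular
    for row in range(n_centers):
        neigh[row, counts[row]:] = center_flat[row]
    return center_flat, neigh, counts


def neighbor_lists(grid: GridSpec, radius_mm: float = 5.0,
                   mask: np.ndarray | None = None) -> list[np.ndarray]:
    """Per-center neighbor index arrays (convenience view)."""
    centers, neigh, counts = searchlight_indices(grid, radius_mm, mask)
    return [neigh[i, :counts[i]].copy() for i in range(centers.size)]


# ---------------------------------------------------------------------------
# searchlight maps


def searchlight_cv_map(cohort, subject: int, variant: str = "orig",
                       radius_mm: float = 5.0,
                       mask: np.ndarray | None = None,
                       c: float = _C_DEFAULT) -> AccuracyMap:
    """Leave-one-run-out searchlight decoding map for one subject."""
    x, y, groups = cohort.run_patterns(subject, variant)
    grid = cohort.grid
    centers, neigh, counts = searchlight_indices(grid, radius_mm, mask)
    acc_flat = _searchlight_cv(np.ascontiguousarray(x), y.astype(np.float64),
                               groups.astype(np.int64), neigh, counts,
                               c, _MAX_PASSES, _TOL)
    out = np.full(grid.n_voxels, np.nan)
    out[centers] = acc_flat
    return AccuracyMap(out.reshape(grid.shape), f"cv({variant})", radius_mm,
                       int(np.unique(groups).size), grid, subject)


def searchlight_cross_maps(cohort, subject: int,
                           variants: tuple[str, ...] = AE_VARIANTS,
                           radius_mm: float = 5.0,
                           mask: np.ndarray | None = None,
                           c: float = _C_DEFAULT) -> dict[str, AccuracyMap]:
    """Originals->AE cross-classification maps for one subject.

    The classifier is trained once per searchlight on all original-sound
    runs and tested on each AE variant's patterns.
    """
    grid = cohort.grid
    centers, neigh, counts = searchlight_indices(grid, radius_mm, mask)
    x_tr, y_tr, _ = cohort.run_patterns(subject, "orig")
    x_tr = np.ascontiguousarray(x_tr)
    maps: dict[str, AccuracyMap] = {}
    for variant in variants:
        x_te, y_te, _ = cohort.run_patterns(subject, variant)
        acc_flat = _searchlight_cross(x_tr, y_tr.astype(np.float64),
                                      np.ascontiguousarray(x_te),
                                      y_te.astype(np.float64),
                                      neigh, counts, c, _MAX_PASSES, _TOL)
        out = np.full(grid.n_voxels, np.nan)
        out[centers] = acc_flat
        maps[variant] = AccuracyMap(out.reshape(grid.shape),
                                    f"cross(orig->{variant})", radius_mm,
                                    1, grid, subject)
    return maps


def group_accuracy_map(accuracy_maps: list[AccuracyMap], chance: float = 0.5,
                       smoothing_fwhm_mm: float = 0.0,
                       threshold: Threshold = Threshold("fwe", 0.05),
                       analysis_mask: np.ndarray | None = None) -> StatMap:
    """Group one-sample t-map of (accuracy - chance) across subjects.

    Ceiling voxels where every subject hits the same accuracy (zero
    between-subject SD) get their t clipped to +/-100 so averaged maps stay
    finite.
    """
    if len(accuracy_maps) < 3:
        raise ValueError("group statistics need at least 3 subjects")
    grid = accuracy_maps[0].grid
    scheme = accuracy_maps[0].scheme
    for m in accuracy_maps[1:]:
        if m.grid.shape != grid.shape:
            raise ValueError("accuracy maps must share a grid")
    vals = np.stack([m.accuracy.ravel() for m in accuracy_maps])
    defined = np.all(np.isfinite(vals), axis=0)
    vals = np.where(np.isfinite(vals), vals, chance)
    if smoothing_fwhm_mm > 0:
        from .glm import smooth_subject_maps
        vals = smooth_subject_maps(vals, grid, smoothing_fwhm_mm)
    t, p, df = one_sample_t(vals, popmean=chance)
    t = np.clip(t, -100.0, 100.0)
    p = stats.t.sf(t, df)
    if analysis_mask is None:
        analysis_mask = defined.reshape(grid.shape)
    else:
        analysis_mask = analysis_mask & defined.reshape(grid.shape)
    mask = threshold.apply(p.reshape(grid.shape), analysis_mask)
    return StatMap(t.reshape(grid.shape), p.reshape(grid.shape), mask,
                   threshold, df, f"group[{scheme}]", grid, analysis_mask)


def average_cross_maps(variant_maps: dict[str, StatMap],
                       threshold: Threshold = Threshold("uncorrected", 0.001)
                       ) -> StatMap:
    """Voxel-wise mean of the five cross-classification statistic maps.

    The threshold is applied to the averaged map.  Comparing the average of
    five t-maps against a single-map t quantile is conservative: under the
    null the average has standard deviation ~1/sqrt(5) of a single map.
    """
    missing = [v for v in AE_VARIANTS if v not in variant_maps]
    if missing:
        raise ValueError(f"missing cross-classification maps for {missing}")
    maps = [variant_maps[v] for v in AE_VARIANTS]
    grid = maps[0].grid
    for m in maps[1:]:
        if m.grid.shape != grid.shape:
            raise ValueError("maps must share a grid")
    avg_t = np.mean([m.t for m in maps], axis=0)
    df = maps[0].df
    p = stats.t.sf(avg_t, df)
    analysis = maps[0].analysis_mask
    if analysis is None:
        analysis = np.ones(grid.shape, dtype=bool)
    mask = threshold.apply(p, analysis)
    return StatMap(avg_t, p, mask, threshold, df, "cross_average", grid,
                   analysis)


# ---------------------------------------------------------------------------
# functional patches and ROI analysis


@dataclass
class ROISet:
    """Named voxel sets with construction provenance."""

    rois: dict
    kind: str
    grid: GridSpec
    centers: dict = field(default_factory=dict)
    radius_mm: float | None = None
    log: list = field(default_factory=list)


def _local_maxima(stat: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """26-connectivity local maxima of ``stat`` inside ``mask`` (flat idx),
    ordered by descending statistic (ties: first index)."""
    footprint = np.ones((3, 3, 3), dtype=bool)
    filt = ndimage.maximum_filter(stat, footprint=footprint,
                                  mode="constant", cval=-np.inf)
    peaks = (stat >= filt) & mask & np.isfinite(stat)
    idx = np.flatnonzero(peaks)
    order = np.argsort(-stat.ravel()[idx], kind="stable")
    return idx[order]


def define_functional_patches(subject_stat: StatMap, group_mask: np.ndarray,
                              reference_coords_mm: np.ndarray,
                              names: list[str] | None = None,
                              n_peaks: int = 10, min_sep_mm: float = 10.0,
                              radius_mm: float = 5.0) -> ROISet:
    """Subject-specific spherical patches around contrast peaks.

    The top ``n_peaks`` local maxima of the subject statistic inside the
    group-level mask are candidate centers; each patch takes the candidate
    nearest its reference coordinate.  When no candidate exists, or two
    chosen centers fall closer than ``min_sep_mm``, the affected patches
    fall back to their reference coordinates; every fallback is logged.
    """
    if not group_mask.any():
        raise ValueError("group mask is empty")
    grid = subject_stat.grid
    refs = np.atleast_2d(np.asarray(reference_coords_mm, dtype=float))
    if names is None:
        names = [f"patch_{i}" for i in range(refs.shape[0])]
    log: list[str] = []
    peak_idx = _local_maxima(subject_stat.t, group_mask)[:n_peaks]
    peak_mm = (np.array(np.unravel_index(peak_idx, grid.shape)).T
               * grid.voxel_size_mm)

    centers_mm = {}
    for name, ref in zip(names, refs):
        if peak_mm.shape[0] == 0:
            centers_mm[name] = ref
            log.append(f"{name}: no peaks in mask, reference used")
            continue
        d = np.linalg.norm(peak_mm - ref[None, :], axis=1)
        centers_mm[name] = peak_mm[int(np.argmin(d))]

    # enforce the minimum separation rule pairwise
    name_list = list(centers_mm)
    for i, a in enumerate(name_list):
        for b in name_list[i + 1:]:
            sep = np.linalg.norm(centers_mm[a] - centers_mm[b])
            if sep < min_sep_mm:
                centers_mm[a] = refs[names.index(a)]
                centers_mm[b] = refs[names.index(b)]
                log.append(f"{a}/{b}: centers {sep:.1f} mm apart "
                           f"< {min_sep_mm} mm, references used")

    coords_mm = (np.indices(grid.shape).reshape(3, -1).T
                 * grid.voxel_size_mm)
    rois = {}
    for name, center in centers_mm.items():
        d = np.linalg.norm(coords_mm - center[None, :], axis=1)
        rois[name] = np.flatnonzero(d <= radius_mm + 1e-9)
    return ROISet(rois, "functional_patch", grid, centers_mm, radius_mm, log)


def toy_anatomical_atlas(grid: GridSpec) -> ROISet:
    """A toy anatomical parcellation standing in for cytoarchitectonic maps.

    Each hemisphere is split into five equal slabs along the second grid
    axis, named Te1.0, Te1.1, Te1.2, PTe and Te3 (synthetic stand-ins, no
    anatomical claim).  Real label volumes can be supplied instead wherever
    an ROISet is accepted.
    """
    names = ("Te1.0", "Te1.1", "Te1.2", "PTe", "Te3")
    left, right = grid.hemisphere_masks()
    ny = grid.shape[1]
    edges = np.linspace(0, ny, len(names) + 1).astype(int)
    rois = {}
    yy = np.indices(grid.shape)[1]
    for hemi_name, hemi in (("L", left), ("R", right)):
        for i, name in enumerate(names):
            sel = hemi & (yy >= edges[i]) & (yy < edges[i + 1])
            rois[f"{hemi_name}_{name}"] = np.flatnonzero(sel.ravel())
    return ROISet(rois, "anatomical", grid)


def roi_analysis(cohort, roi_set: ROISet,
                 variants: tuple[str, ...] = ("orig",) + AE_VARIANTS,
                 schemes: tuple[str, ...] = ("cv", "cross"),
                 fdr_q: float = 0.05, c: float = _C_DEFAULT):
    """Decoding accuracies per ROI and scheme with FDR-corrected inference.

    For every ROI and sound set, per-subject accuracies are computed on the
    ROI's voxels (leave-one-run-out CV within the set, and originals->AE
    cross-classification for AE sets), tested against chance with a
    one-sample t-test, and Benjamini-Hochberg corrected across the whole
    table.  Empty ROIs yield flagged rows rather than disappearing.
    """
    import pandas as pd
    from statsmodels.stats.multitest import multipletests

    rows = []
    for roi_name, voxels in roi_set.rois.items():
        for scheme in schemes:
            for variant in variants:
                if scheme == "cross" and variant == "orig":
                    continue
                if voxels.size == 0:
                    rows.append({"roi": roi_name, "scheme": scheme,
                                 "variant": variant, "n_voxels": 0,
                                 "mean_accuracy": np.nan, "t": np.nan,
                                 "p": np.nan, "flag_empty": True})
                    continue
                accs = []
                for s in range(cohort.n_subjects):
                    if scheme == "cv":
                        x, y, groups = cohort.run_patterns(s, variant)
                        accs.append(decode_cv(x[:, voxels], y, groups, c))
                    else:
                        x_tr, y_tr, _ = cohort.run_patterns(s, "orig")
                        x_te, y_te, _ = cohort.run_patterns(s, variant)
                        accs.append(decode_cross(x_tr[:, voxels], y_tr,
                                                 x_te[:, voxels], y_te, c))
                accs = np.asarray(accs)
                t, p, _ = one_sample_t(accs[:, None], popmean=0.5)
                rows.append({"roi": roi_name, "scheme": scheme,
                             "variant": variant, "n_voxels": int(voxels.size),
                             "mean_accuracy": float(accs.mean()),
                             "t": float(np.clip(t[0], -100, 100)),
                             "p": float(p[0]), "flag_empty": False})
    table = pd.DataFrame(rows)
    tested = table["p"].notna()
    table["significant_fdr"] = False
    if tested.any():
        rej = multipletests(table.loc[tested, "p"].to_numpy(), alpha=fdr_q,
                            method="fdr_bh")[0]
        table.loc[tested, "significant_fdr"] = rej
    return table
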