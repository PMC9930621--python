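"""Searchlight geometry, linear-SVM decoding, group maps, patches, ROIs."""

import itertools

import numpy as np
import pytest

from vaparc import mvpa
from vaparc import synthetic_data as sd
from vaparc.core import AccuracyMap, GridSpec, Threshold

# ---------------------------------------------------------------------------
# the decoder itself


def _two_class(rng, n_per_class, d, sep):
    x = rng.standard_normal((2 * n_per_class, d))
    y = np.repeat([1, -1], n_per_class)
    x[y == 1] += sep
    return x, y


def test_decoder_agrees_with_sklearn_svc():
    """Our dual-coordinate-descent SVM vs sklearn's SVC on identically
    standardized data: accuracies agree to within a few test samples."""
    from sklearn.svm import SVC
    rng = np.random.default_rng(0)
    diffs = []
    for rep in range(25):
        sep = rng.uniform(0.3, 1.5)
        x_tr, y_tr = _two_class(rng, 8, 12, sep)
        x_te, y_te = _two_class(rng, 8, 12, sep)
        ours = mvpa.decode_cross(x_tr, y_tr, x_te, y_te)
        mu, sdv = x_tr.mean(0), x_tr.std(0)
        sdv[sdv == 0] = 1.0
        ref = SVC(kernel="linear", C=1.0).fit((x_tr - mu) / sdv, y_tr)
        diffs.append(abs(ours - ref.score((x_te - mu) / sdv, y_te)))
    assert np.mean(diffs) < 0.05  # no-intercept solver, small deviations


def test_separable_patterns_decode_perfectly():
    rng = np.random.default_rng(1)
    x, y = _two_class(rng, 8, 10, sep=20.0)
    groups = np.tile(np.arange(8), 2)
    assert mvpa.decode_cv(x, y, groups) == 1.0


def test_cv_has_one_fold_per_run():
    rng = np.random.default_rng(2)
    x, y = _two_class(rng, 8, 5, sep=1.0)
    groups = np.tile(np.arange(8), 2)
    accs = []
    for g in np.unique(groups):
        te = groups == g
        assert te.sum() == 2  # one voice + one nonvoice pattern per run
        accs.append(mvpa.decode_cross(x[~te], y[~te], x[te], y[te]))
    assert mvpa.decode_cv(x, y, groups) == pytest.approx(np.mean(accs))


def test_label_shuffled_decoding_is_at_chance():
    rng = np.random.default_rng(3)
    accs = []
    for rep in range(20):
        x = rng.standard_normal((16, 20))
        y = rng.permutation(np.repeat([1, -1], 8))
        accs.append(mvpa.decode_cv(x, y, np.tile(np.arange(8), 2)))
    accs = np.array(accs)
    se = accs.std(ddof=1) / np.sqrt(accs.size)
    assert abs(accs.mean() - 0.5) <= 3 * se


def test_resubstitution_beats_cross_validation_on_average():
    rng = np.random.default_rng(4)
    resub, cv = [], []
    for rep in range(20):
        x, y = _two_class(rng, 8, 15, sep=0.5)
        groups = np.tile(np.arange(8), 2)
        resub.append(mvpa.decode_cross(x, y, x, y))
        cv.append(mvpa.decode_cv(x, y, groups))
    assert np.mean(resub) >= np.mean(cv)


def test_flipping_test_labels_complements_accuracy():
    rng = np.random.default_rng(5)
    x_tr, y_tr = _two_class(rng, 8, 10, sep=0.8)
    x_te, y_te = _two_class(rng, 8, 10, sep=0.8)
    acc = mvpa.decode_cross(x_tr, y_tr, x_te, y_te)
    flipped = mvpa.decode_cross(x_tr, y_tr, x_te, -y_te)
    assert acc + flipped == pytest.approx(1.0)


def test_accuracy_invariant_to_voxelwise_affine_rescaling():
    rng = np.random.default_rng(6)
    x_tr, y_tr = _two_class(rng, 8, 10, sep=0.7)
    x_te, y_te = _two_class(rng, 8, 10, sep=0.7)
    scale = rng.uniform(0.1, 10, 10)
    shift = rng.uniform(-5, 5, 10)
    base = mvpa.decode_cross(x_tr, y_tr, x_te, y_te)
    rescaled = mvpa.decode_cross(x_tr * scale + shift, y_tr,
                                 x_te * scale + shift, y_te)
    assert base == rescaled


def test_decoder_input_validation():
    rng = np.random.default_rng(7)
    x, y = _two_class(rng, 4, 5, 1.0)
    with pytest.raises(ValueError, match="voxel sets"):
        mvpa.decode_cross(x, y, x[:, :3], y)
    with pytest.raises(ValueError, match="missing a label"):
        groups = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        mvpa.decode_cv(x, y, groups)  # leaving out run 1 removes class -1


# ---------------------------------------------------------------------------
# searchlight geometry


def test_searchlight_neighbors_match_exhaustive_enumeration():
    grid = GridSpec((8, 8, 6))
    centers, neigh, counts = mvpa.searchlight_indices(grid, 5.0)
    rng = np.random.default_rng(8)
    for flat in rng.choice(centers, 10, replace=False):
        row = int(np.flatnonzero(centers == flat)[0])
        cijk = np.array(np.unravel_index(flat, grid.shape))
        brute = [
            np.ravel_multi_index(ijk, grid.shape)
            for ijk in itertools.product(*(range(s) for s in grid.shape))
            if np.linalg.norm((np.array(ijk) - cijk)
                              * grid.voxel_size_mm) <= 5.0
        ]
        assert set(neigh[row, :counts[row]]) == set(brute)
        assert counts[row] == len(brute)


def test_searchlight_radius_zero_is_single_voxel():
    grid = GridSpec((5, 5, 4))
    centers, neigh, counts = mvpa.searchlight_indices(grid, 0.0)
    assert (counts == 1).all()
    assert np.array_equal(neigh[:, 0], centers)


def test_searchlight_respects_mask_and_bounds():
    grid = GridSpec((6, 6, 4))
    mask = np.zeros(grid.shape, dtype=bool)
    mask[:3] = True
    centers, neigh, counts = mvpa.searchlight_indices(grid, 5.0, mask)
    flat_mask = np.flatnonzero(mask.ravel())
    for row in range(centers.size):
        assert set(neigh[row, :counts[row]]) <= set(flat_mask)


# ---------------------------------------------------------------------------
# group accuracy maps


def _acc_maps(values, grid):
    return [AccuracyMap(v.reshape(grid.shape), "cv(orig)", 5.0, 8, grid, s)
            for s, v in enumerate(values)]


def test_group_accuracy_map_null_case():
    grid = GridSpec((4, 4, 3))
    vals = [np.full(grid.n_voxels, 0.5) for _ in range(6)]
    stat = mvpa.group_accuracy_map(_acc_maps(vals, grid),
                                   threshold=Threshold("uncorrected", 0.001))
    assert not stat.mask.any()


def test_group_accuracy_map_matches_hand_computed_t():
    grid = GridSpec((2, 2, 1))
    accs = np.array([0.6, 0.6, 0.6, 0.6])
    vals = [np.full(grid.n_voxels, a) for a in accs]
    # jitter one voxel so the SD is nonzero there
    for i, v in enumerate(vals):
        v[0] = [0.55, 0.6, 0.65, 0.6][i]
    stat = mvpa.group_accuracy_map(_acc_maps(vals, grid))
    mean = np.mean([0.55, 0.6, 0.65, 0.6]) - 0.5
    sd = np.std([0.55, 0.6, 0.65, 0.6], ddof=1)
    expected = mean / (sd / np.sqrt(4))
    assert stat.t.ravel()[0] == pytest.approx(expected)
    assert stat.t.ravel()[1] == 100.0  # ceiling voxels clipped, not inf


def test_average_cross_maps_identity_linearity_and_validation(small_cohort):
    from vaparc import glm
    from vaparc.core import AE_VARIANTS
    means = small_cohort.subject_condition_means()
    thr = Threshold("uncorrected", 0.001)
    base = glm.group_contrast(means, glm.va_contrast(), small_cohort.grid,
                              thr, 0.0)
    same = {v: base for v in AE_VARIANTS}
    avg = mvpa.average_cross_maps(same, thr)
    assert np.allclose(avg.t, base.t)  # averaging identical maps

    null = glm.group_contrast(means, np.zeros(12), small_cohort.grid, thr,
                              0.0)
    one_hot = {v: null for v in AE_VARIANTS}
    one_hot["e_s"] = base
    avg2 = mvpa.average_cross_maps(one_hot, thr)
    assert np.allclose(avg2.t, base.t / 5.0)  # linearity

    with pytest.raises(ValueError, match="missing"):
        mvpa.average_cross_maps({"e_s": base}, thr)


# ---------------------------------------------------------------------------
# functional patches


def _stat_map_from(t, grid):
    from vaparc.core import StatMap
    from scipy import stats as sps
    p = sps.norm.sf(t)
    return StatMap(t, p, p < 0.001, Threshold("uncorrected", 0.001), 10,
                   "test", grid)


def test_patches_found_at_well_separated_peaks():
    grid = GridSpec((20, 20, 12))
    t = np.zeros(grid.shape)
    peaks = [(3, 3, 6), (3, 10, 6), (3, 17, 6)]
    for pk in peaks:
        t[pk] = 10.0
    refs = np.array(peaks) * grid.voxel_size_mm
    rois = mvpa.define_functional_patches(
        _stat_map_from(t, grid), np.ones(grid.shape, bool), refs,
        names=["a", "m", "p"])
    assert rois.log == []
    for name, pk in zip(["a", "m", "p"], peaks):
        assert np.allclose(rois.centers[name],
                           np.array(pk) * grid.voxel_size_mm)
        center_flat = np.ravel_multi_index(pk, grid.shape)
        assert center_flat in rois.rois[name]


def test_patches_fall_back_on_flat_statistic():
    grid = GridSpec((10, 10, 6))
    t = np.zeros(grid.shape)
    refs = np.array([[5.5, 5.5, 5.5], [22.0, 22.0, 11.0]])
    rois = mvpa.define_functional_patches(
        _stat_map_from(t, grid), np.ones(grid.shape, bool), refs,
        names=["x", "y"])
    # flat map: every voxel ties as a "peak"; the nearest-to-reference rule
    # plus the separation fallback must leave centers at the references
    assert len(rois.log) >= 1
    assert np.allclose(rois.centers["x"], refs[0], atol=3.0)


def test_patches_closer_than_10mm_replaced_by_references():
    grid = GridSpec((20, 20, 12))
    t = np.zeros(grid.shape)
    t[5, 5, 5] = 10.0
    t[5, 8, 5] = 9.0  # 3 voxels = 8.25 mm from the first peak
    refs = np.array([[13.75, 13.75, 13.75], [13.75, 22.0, 13.75]])
    rois = mvpa.define_functional_patches(
        _stat_map_from(t, grid), np.ones(grid.shape, bool), refs,
        names=["p1", "p2"], n_peaks=2)
    assert any("references used" in line for line in rois.log)
    assert np.allclose(rois.centers["p1"], refs[0])
    assert np.allclose(rois.centers["p2"], refs[1])


def test_patches_require_nonempty_group_mask():
    grid = GridSpec((5, 5, 4))
    with pytest.raises(ValueError):
        mvpa.define_functional_patches(
            _stat_map_from(np.zeros(grid.shape), grid),
            np.zeros(grid.shape, bool), np.zeros((1, 3)))


# ---------------------------------------------------------------------------
# ROI analysis


def test_roi_analysis_recovers_acoustic_region(small_cohort):
    gt = small_cohort.ground_truth
    roi = mvpa.ROISet(
        {"acoustic_truth": np.flatnonzero(
            gt.class_mask(sd.CLASS_ACOUSTIC).ravel()),
         "null_region": np.flatnonzero(gt.class_mask(0).ravel())[:60],
         "empty": np.array([], dtype=int)},
        "anatomical", small_cohort.grid)
    table = mvpa.roi_analysis(small_cohort, roi, variants=("orig", "e_s"),
                              schemes=("cv",))
    row = table[(table.roi == "acoustic_truth")
                & (table.variant == "orig")].iloc[0]
    assert row.mean_accuracy > 0.9 and row.significant_fdr
    empty_rows = table[table.roi == "empty"]
    assert len(empty_rows) > 0  # flagged, not silently dropped
    assert empty_rows["flag_empty"].all()
    assert empty_rows["mean_accuracy"].isna().all()


def test_bh_fdr_hand_example():
    from statsmodels.stats.multitest import multipletests
    rej = multipletests([0.001, 0.2, 0.9], alpha=0.05, method="fdr_bh")[0]
    assert list(rej) == [True, False, False]


def test_toy_atlas_covers_grid_disjointly(small_grid):
    atlas = mvpa.toy_anatomical_atlas(small_grid)
    assert len(atlas.rois) == 10  # 5 regions x 2 hemispheres
    all_idx = np.concatenate(list(atlas.rois.values()))
    assert all_idx.size == small_grid.n_voxels
    assert np.unique(all_idx).size == all_idx.size


def test_zero_noise_cohort_decodes_exactly(noiseless_cohort):
    """Deterministic cohort: perfect decoding inside the acoustic field,
    exact chance for searchlights that see only null voxels, and NaN
    (undefined, not 0.5) outside the analysis mask."""
    gt = noiseless_cohort.ground_truth
    grid = noiseless_cohort.grid
    acc_map = mvpa.searchlight_cv_map(noiseless_cohort, 0, "orig")
    acoustic = gt.class_mask(sd.CLASS_ACOUSTIC)
    assert np.all(acc_map.accuracy[acoustic] == 1.0)

    # centers whose whole sphere is null-class: every feature is constant
    # zero, so the decision function is zero and accuracy is exact chance
    centers, neigh, counts = mvpa.searchlight_indices(grid, 5.0)
    null_flat = gt.voxel_class.ravel() == 0
    flat_acc = acc_map.accuracy.ravel()
    pure_null = [c for row, c in enumerate(centers)
                 if null_flat[neigh[row, :counts[row]]].all()]
    assert len(pure_null) > 0
    assert np.all(flat_acc[pure_null] == 0.5)

    mask = np.zeros(grid.shape, bool)
    mask[tuple(np.argwhere(acoustic)[0])] = True
    masked_map = mvpa.searchlight_cv_map(noiseless_cohort, 0, "orig",
                                         mask=mask)
    assert np.isnan(masked_map.accuracy[~mask]).all()
    assert np.isfinite(masked_map.accuracy[mask]).all()
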