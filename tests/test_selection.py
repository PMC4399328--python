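import numpy as np
import pytest
from scipy import stats

from soundmvpa.selection import (
    FeatureTable,
    SelectionResult,
    assemble_features,
    build_roi_mask,
    permutation_null,
    run_fold_selection,
    select_voxels,
    standardize_features,
    train_svm_weights,
    voxel_pvalues,
)


def random_table(rng, n_rows=40, n_vox=20, condition="left_vs_right"):
    """Label-independent features: pure noise."""
    labels = np.array([1, -1] * (n_rows // 2))
    return FeatureTable(
        features=rng.normal(size=(n_rows, n_vox)),
        labels=labels,
        run_ids=np.repeat(np.arange(n_rows // 10), 10)[:n_rows],
        location_ids=np.arange(n_rows) % 16,
        voxel_indices=np.arange(n_vox),
        condition=condition,
    )


class TestBuildRoiMask:
    def test_box_smoothing_behavior(self):
        """Measured on a 10^3 box: at threshold 0.5 faces are kept, convex
        corners erode, so the volume lands near (slightly below) the
        original; the interior is always preserved."""
        from scipy import ndimage

        base = np.zeros((16, 16, 16), dtype=bool)
        base[3:13, 3:13, 3:13] = True
        roi = build_roi_mask(base, fwhm_mm=3.0, voxel_size_mm=(1, 1, 1))
        interior = ndimage.binary_erosion(base, iterations=2)
        assert roi[interior].all()
        dilated = ndimage.binary_dilation(base, iterations=2)
        assert not roi[~dilated].any()
        assert 0.8 * base.sum() <= roi.sum() <= 1.2 * base.sum()

    def test_low_threshold_dilates(self):
        base = np.zeros((16, 16, 16), dtype=bool)
        base[3:13, 3:13, 3:13] = True
        roi = build_roi_mask(base, fwhm_mm=3.0, voxel_size_mm=(1, 1, 1), threshold=0.2)
        assert roi.sum() > base.sum()
        assert roi[base].all()

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            build_roi_mask(np.zeros((6, 6, 6), dtype=bool), fwhm_mm=3.0)

    def test_zero_fwhm_identity(self):
        base = np.zeros((8, 8, 8), dtype=bool)
        base[2:5, 2:5, 2:5] = True
        np.testing.assert_array_equal(build_roi_mask(base, 0.0), base)


class TestAssembleFeatures:
    @pytest.mark.parametrize(
        "condition,expected_rows",
        [("left_vs_right", 70), ("up_vs_down", 56), ("front_vs_back", 63)],
    )
    def test_row_counts_for_seven_training_runs(
        self, null_subject, labelings, condition, expected_rows
    ):
        spec, _, responses = null_subject
        ft = assemble_features(
            responses, labelings[condition], spec.roi_mask, runs=list(range(7))
        )
        assert ft.n_rows == expected_rows
        assert ft.n_voxels == spec.roi_mask.sum()

    def test_excluded_locations_never_appear(self, null_subject, labelings):
        spec, _, responses = null_subject
        for lab in labelings.values():
            ft = assemble_features(responses, lab, spec.roi_mask)
            assert not set(ft.location_ids) & set(lab.excluded)

    def test_labels_match_classes(self, null_subject, labelings):
        spec, _, responses = null_subject
        lab = labelings["left_vs_right"]
        ft = assemble_features(responses, lab, spec.roi_mask, runs=[0])
        for lid, y in zip(ft.location_ids, ft.labels):
            assert y == lab.label_of(lid)

    def test_unknown_run_errors(self, null_subject, labelings):
        spec, _, responses = null_subject
        with pytest.raises(KeyError):
            assemble_features(responses, labelings["up_vs_down"], spec.roi_mask, runs=[99])


class TestPermutationNull:
    def test_deterministic(self):
        rng = np.random.default_rng(0)
        ft = random_table(rng)
        a = permutation_null(ft, n_perm=50, seed=3)
        b = permutation_null(ft, n_perm=50, seed=3)
        np.testing.assert_array_equal(a.null_mean, b.null_mean)
        np.testing.assert_array_equal(a.null_sd, b.null_sd)

    def test_default_n_perm_matches_protocol(self):
        from soundmvpa.selection import DEFAULT_N_PERM

        assert DEFAULT_N_PERM == 2000

    def test_degenerate_voxels_flagged(self):
        rng = np.random.default_rng(1)
        ft = random_table(rng)
        ft.features[:, 5] = 7.0  # zero variance
        null = permutation_null(ft, n_perm=50, seed=0)
        assert null.degenerate[5]
        assert null.null_sd[5] == 0.0

    def test_single_class_errors(self):
        rng = np.random.default_rng(2)
        ft = random_table(rng)
        object.__setattr__(ft, "labels", np.ones(ft.n_rows, dtype=int))
        with pytest.raises(ValueError, match="both classes"):
            permutation_null(ft, n_perm=10, seed=0)

    def test_n_perm_minimum(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            permutation_null(random_table(rng), n_perm=1, seed=0)

    def test_null_standardized_true_weight_rate(self):
        """On label-free data ~5% of voxels exceed |z| = 1.96 (tol +/-2%)."""
        rng = np.random.default_rng(4)
        rates = []
        for rep in range(20):
            ft = random_table(rng, n_rows=40, n_vox=30)
            X, _, _ = standardize_features(ft.features)
            w = train_svm_weights(X, ft.labels)
            null = permutation_null(ft, n_perm=120, seed=rep)
            z = np.abs(w - null.null_mean) / null.null_sd
            rates.append((z > 1.96).mean())
        assert abs(np.mean(rates) - 0.05) < 0.02


class TestVoxelPvalues:
    def _null(self, mean, sd):
        from soundmvpa.selection import GaussianNull

        mean = np.asarray(mean, dtype=float)
        sd = np.asarray(sd, dtype=float)
        return GaussianNull(mean, sd, n_perm=100, degenerate=sd == 0)

    def test_weight_at_centre(self):
        p = voxel_pvalues(np.array([1.5]), self._null([1.5], [0.3]))
        assert p[0] == pytest.approx(1.0)

    def test_gaussian_quantile(self):
        p = voxel_pvalues(np.array([1.959964]), self._null([0.0], [1.0]))
        assert p[0] == pytest.approx(0.05, abs=1e-6)

    def test_degenerate_rules(self):
        null = self._null([0.0, 2.0], [0.0, 0.0])
        p = voxel_pvalues(np.array([0.0, 1.0]), null)
        assert p[0] == 1.0 and p[1] == 0.0

    def test_symmetry(self):
        null = self._null([0.0, 0.0], [1.0, 1.0])
        p = voxel_pvalues(np.array([2.0, -2.0]), null)
        assert p[0] == pytest.approx(p[1])


class TestSelectVoxels:
    def test_strict_threshold(self):
        res = select_voxels(np.array([0.01, 0.049, 0.05, 0.9]), alpha=0.05)
        np.testing.assert_array_equal(res.selected, [True, True, False, False])
        assert not res.fallback

    def test_fallback_to_full_roi(self):
        res = select_voxels(np.full(5, 0.5), alpha=0.05)
        assert res.selected.all()
        assert res.fallback

    def test_alpha_one_selects_everything(self):
        res = select_voxels(np.array([0.2, 0.7, 0.999]), alpha=1.0)
        assert res.selected.all()

    def test_excluded_never_selected(self):
        res = select_voxels(
            np.array([0.01, 0.01, 0.5]), alpha=0.05, exclude=np.array([True, False, False])
        )
        np.testing.assert_array_equal(res.selected, [False, True, False])

    def test_bad_pvalues_rejected(self):
        with pytest.raises(ValueError):
            select_voxels(np.array([-0.1, 0.5]))

    def test_json_round_trip(self, tmp_path):
        res = select_voxels(
            np.array([0.01, 0.6]), alpha=0.05, condition="up_vs_down", fold_id=3
        )
        res.to_json(tmp_path / "sel.json")
        back = SelectionResult.from_json(tmp_path / "sel.json")
        assert back.condition == "up_vs_down" and back.fold_id == 3
        np.testing.assert_array_equal(back.selected, res.selected)


class TestCalibrationAndOracle:
    def test_gaussian_fit_vs_empirical_permutation_pvalues(self):
        """Kolmogorov distance between Gaussian-fit p and rank-based
        empirical p < 0.1 on small instances (20 voxels, 500 perms)."""
        rng = np.random.default_rng(10)
        gauss_p, emp_p = [], []
        for rep in range(5):
            ft = random_table(rng, n_rows=40, n_vox=20)
            X, _, _ = standardize_features(ft.features)
            w = train_svm_weights(X, ft.labels)
            n_perm = 500
            perm_rng = np.random.default_rng(100 + rep)
            weights = np.empty((n_perm, ft.n_voxels))
            for i in range(n_perm):
                weights[i] = train_svm_weights(X, perm_rng.permutation(ft.labels))
            null = permutation_null(ft, n_perm=n_perm, seed=200 + rep)
            gauss_p.extend(voxel_pvalues(w, null))
            # empirical two-sided rank p against the same-kind null
            centred = np.abs(weights - weights.mean(axis=0))
            true_dev = np.abs(w - weights.mean(axis=0))
            emp_p.extend((1 + (centred >= true_dev).sum(axis=0)) / (1 + n_perm))
        ks = stats.ks_2samp(gauss_p, emp_p).statistic
        assert ks < 0.1

    def test_type_one_calibration(self):
        """Per-voxel selection rate ~ alpha on label-independent data."""
        rng = np.random.default_rng(42)
        rates = []
        for rep in range(30):
            ft = random_table(rng, n_rows=40, n_vox=25)
            res = run_fold_selection(ft, fold_id=0, n_perm=150, alpha=0.05, seed=rep)
            rates.append(0.0 if res.fallback else res.selected.mean())
        assert abs(np.mean(rates) - 0.05) < 0.02

    def test_run_fold_selection_deterministic(self):
        rng = np.random.default_rng(5)
        ft = random_table(rng)
        a = run_fold_selection(ft, fold_id=1, n_perm=60, seed=9)
        b = run_fold_selection(ft, fold_id=1, n_perm=60, seed=9)
        np.testing.assert_array_equal(a.p_values, b.p_values)
        np.testing.assert_array_equal(a.selected, b.selected)
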