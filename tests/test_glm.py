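import numpy as np
import pytest

from soundmvpa.glm import (
    ContrastResult,
    build_design_matrix,
    canonical_hrf,
    fit_run_glm,
    smooth_series,
    smooth_volume,
    univariate_contrast,
)
from soundmvpa.synth import (
    N_TRIALS,
    VolumeSeries,
    make_run_design,
    simulate_subject,
)

from conftest import small_spec


def bh_step_up_oracle(pvals, alpha):
    """Brute-force Benjamini-Hochberg: largest k with p_(k) <= k/m * alpha."""
    m = len(pvals)
    order = np.argsort(pvals)
    k_star = 0
    for k in range(1, m + 1):
        if pvals[order[k - 1]] <= k / m * alpha:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


class TestCanonicalHrf:
    def test_zero_at_onset(self):
        assert canonical_hrf(0.0) == pytest.approx(0.0, abs=1e-12)

    def test_peak_normalized(self):
        t = np.linspace(0, 30, 3001)
        assert canonical_hrf(t).max() == pytest.approx(1.0, rel=1e-6)

    def test_peak_time_in_expected_window(self):
        t = np.linspace(0, 30, 3001)
        assert 5.0 <= t[np.argmax(canonical_hrf(t))] <= 6.0

    def test_undershoot(self):
        # frozen from evaluating the chosen double-gamma parameterization
        v = canonical_hrf(25.0)
        assert v <= 0.0 or v < 1e-3
        assert abs(v) < 0.2

    def test_negative_time_is_zero(self):
        assert np.all(canonical_hrf(np.array([-5.0, -0.1])) == 0)


class TestBuildDesignMatrix:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_shape_and_rank(self, seed):
        dm = build_design_matrix(make_run_design(seed))
        assert dm.matrix.shape == (N_TRIALS, 18)
        assert np.linalg.matrix_rank(dm.matrix) == 18

    def test_column_names(self):
        dm = build_design_matrix(make_run_design(1))
        assert dm.column_names[-2:] == ("trend", "intercept")
        assert all(n.startswith("loc_") for n in dm.column_names[:16])

    def test_zero_hrf_raises_rank_error(self):
        with pytest.raises(ValueError, match="rank deficient"):
            build_design_matrix(make_run_design(1), hrf=lambda t: np.zeros_like(np.atleast_1d(t)))

    def test_location_columns_are_localized(self):
        """A location's column is (near) zero until its first trial."""
        design = make_run_design(4)
        dm = build_design_matrix(design)
        for lid in range(16):
            first = min(t.index for t in design.stimulus_trials(lid))
            col = dm.column(f"loc_{lid:02d}")
            assert np.allclose(col[:first + 1], 0.0, atol=1e-6)


class TestFitRunGlm:
    def test_exact_recovery_of_planted_betas(self):
        """OLS identity: data built as dm @ beta* recovers beta* exactly."""
        rng = np.random.default_rng(0)
        dm = build_design_matrix(make_run_design(2))
        grid = (4, 3, 2)
        beta_star = rng.normal(size=(18, np.prod(grid)))
        data = (dm.matrix @ beta_star).T.reshape(*grid, N_TRIALS)
        vol = VolumeSeries(data=data, acquisition_times_s=np.arange(N_TRIALS) * 5.5, voxel_size_mm=(3, 3, 3))
        resp = fit_run_glm(vol, dm)
        np.testing.assert_allclose(
            resp.betas.reshape(16, -1), beta_star[:16], rtol=1e-8, atol=1e-8
        )
        assert np.all(resp.residual_variance < 1e-16)

    def test_128_beta_maps_per_subject(self):
        spec = small_spec(0.0, noise_sd=0.1)
        ds = simulate_subject(spec, seed=3)
        total = 0
        for r, (design, vol) in enumerate(ds.runs):
            resp = fit_run_glm(vol, build_design_matrix(design), run_id=r)
            assert resp.n_beta_maps == 16
            total += resp.n_beta_maps
        assert total == 128

    def test_pure_drift_recovery(self):
        """Drift-only data: location betas ~ 0, trend coefficient = slope."""
        dm = build_design_matrix(make_run_design(5))
        slope = 0.37
        trend = dm.column("trend")
        data = np.tile(100.0 + slope * trend, (2, 2, 1, 1))
        vol = VolumeSeries(data=data, acquisition_times_s=np.arange(N_TRIALS) * 5.5, voxel_size_mm=(3, 3, 3))
        resp = fit_run_glm(vol, dm)
        np.testing.assert_allclose(resp.betas, 0.0, atol=1e-9)
        np.testing.assert_allclose(resp.extra_betas["trend"], slope, rtol=1e-9)

    def test_dimension_mismatch(self):
        dm = build_design_matrix(make_run_design(1))
        vol = VolumeSeries(
            data=np.zeros((2, 2, 2, 10)),
            acquisition_times_s=np.arange(10.0),
            voxel_size_mm=(3, 3, 3),
        )
        with pytest.raises(ValueError, match="does not match design rows"):
            fit_run_glm(vol, dm)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(7)
        dm = build_design_matrix(make_run_design(7))
        data = rng.normal(100, 1, size=(3, 3, 2, N_TRIALS))
        vol = VolumeSeries(data=data, acquisition_times_s=np.arange(N_TRIALS) * 5.5, voxel_size_mm=(3, 3, 3))
        resp = fit_run_glm(vol, dm)
        Y = data.reshape(-1, N_TRIALS).T
        coef = np.vstack(
            [resp.betas.reshape(16, -1)]
            + [resp.extra_betas[n].reshape(1, -1) for n in ("trend", "intercept")]
        )
        resid = Y - dm.matrix @ coef
        assert np.abs(dm.matrix.T @ resid).max() < 1e-7

    def test_beta_recovery_is_unbiased(self):
        """Mean bias over repeated noisy fits < 3 SEM per location beta."""
        rng = np.random.default_rng(11)
        dm = build_design_matrix(make_run_design(9))
        beta_star = rng.normal(0, 1, size=18)
        clean = dm.matrix @ beta_star
        n_rep = 100
        est = np.empty((n_rep, 16))
        for i in range(n_rep):
            noisy = clean + rng.normal(0, 0.5, size=N_TRIALS)
            vol = VolumeSeries(
                data=noisy.reshape(1, 1, 1, N_TRIALS),
                acquisition_times_s=np.arange(N_TRIALS) * 5.5,
                voxel_size_mm=(3, 3, 3),
            )
            est[i] = fit_run_glm(vol, dm).betas.ravel()
        bias = est.mean(axis=0) - beta_star[:16]
        sem = est.std(axis=0, ddof=1) / np.sqrt(n_rep)
        assert np.all(np.abs(bias) < 3 * sem)


class TestSmoothVolume:
    def test_impulse_fwhm(self):
        grid = np.zeros((21, 21, 21))
        grid[10, 10, 10] = 1.0
        out = smooth_volume(grid, fwhm_mm=5.0, voxel_size_mm=(1, 1, 1))
        profile = out[:, 10, 10]
        half = profile.max() / 2
        above = np.flatnonzero(profile >= half)
        width_mm = above[-1] - above[0] + 1
        assert abs(width_mm - 5.0) <= 1.0  # within a voxel of the nominal FWHM

    def test_sum_preserved(self):
        rng = np.random.default_rng(1)
        grid = np.zeros((30, 30, 30))
        grid[10:20, 10:20, 10:20] = rng.random((10, 10, 10))
        out = smooth_volume(grid, fwhm_mm=4.0, voxel_size_mm=(2, 2, 2))
        assert out.sum() == pytest.approx(grid.sum(), rel=1e-6)

    def test_constant_field_unchanged(self):
        grid = np.full((8, 8, 8), 3.3)
        out = smooth_volume(grid, fwhm_mm=5.0, voxel_size_mm=(1, 1, 1))
        np.testing.assert_allclose(out[2:-2, 2:-2, 2:-2], 3.3, atol=1e-9)

    def test_zero_fwhm_identity(self):
        rng = np.random.default_rng(2)
        grid = rng.random((5, 5, 5))
        np.testing.assert_array_equal(smooth_volume(grid, 0.0, (1, 1, 1)), grid)

    def test_negative_fwhm(self):
        with pytest.raises(ValueError):
            smooth_volume(np.zeros((3, 3, 3)), -1.0, (1, 1, 1))


class TestUnivariateContrast:
    def test_bh_matches_step_up_oracle(self):
        from statsmodels.stats.multitest import multipletests

        p = np.array([0.001, 0.01, 0.02, 0.04, 0.2])
        reject, _, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_array_equal(reject, bh_step_up_oracle(p, 0.05))

    @pytest.mark.parametrize("seed", [0, 1])
    def test_bh_oracle_random_vectors(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.random(50)
        reject, _, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_array_equal(reject, bh_step_up_oracle(p, 0.05))

    def test_requires_two_runs(self, null_subject):
        _, ds, _ = null_subject
        with pytest.raises(ValueError, match="at least 2 runs"):
            univariate_contrast([ds.runs[0]])

    def test_null_data_calibration(self):
        """Label-free white-noise data: ~5% raw p below 0.05, BH mask
        (near) empty.  AR(1)-free so the OLS t statistic is exact."""
        spec = small_spec(0.0, noise_sd=1.0, ar1_coeff=0.0, baseline_amplitude=0.0)
        ds = simulate_subject(spec, seed=31)
        result = univariate_contrast(list(ds.runs), alpha=0.05, smooth_fwhm_mm=None)
        frac = (result.p_map < 0.05).mean()
        assert 0.02 < frac < 0.09
        assert result.significance_mask.mean() < 0.01

    def test_recovers_planted_baseline_response(self):
        """Strong common auditory response: ROI voxels dominate the mask."""
        spec = small_spec(0.0, noise_sd=0.5, baseline_amplitude=3.0)
        ds = simulate_subject(spec, seed=21)
        result = univariate_contrast(list(ds.runs), alpha=0.05, smooth_fwhm_mm=None)
        roi = spec.roi_mask
        sensitivity = result.significance_mask[roi].mean()
        assert sensitivity >= 0.9
        assert result.significance_mask[~roi].mean() < 0.05

    def test_smoothed_path(self, null_subject):
        _, ds, _ = null_subject
        result = univariate_contrast(list(ds.runs)[:3], alpha=0.05, smooth_fwhm_mm=5.0)
        assert isinstance(result, ContrastResult)
        assert result.t_map.shape == ds.runs[0][1].data.shape[:3]


class TestSmoothSeries:
    def test_preserves_metadata(self, null_subject):
        _, ds, _ = null_subject
        vol = ds.runs[0][1]
        sm = smooth_series(vol, fwhm_mm=5.0)
        assert sm.data.shape == vol.data.shape
        np.testing.assert_array_equal(sm.acquisition_times_s, vol.acquisition_times_s)
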