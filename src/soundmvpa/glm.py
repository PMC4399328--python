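"""Per-run beta-series GLM and the univariate stimulus-vs-silent contrast.

Each run is fit separately and without spatial smoothing with one
regressor per sound location (4 pooled trials each), a mean-centred linear
trend, and an intercept — 18 columns for 76 volumes — yielding 16 response
maps per run and 128 per subject.  The univariate path pools all stimulus
trials into one regressor on smoothed data and thresholds the voxelwise t
map with Benjamini–Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy import stats
from statsmodels.stats.multitest import multipletests

from soundmvpa.hrf import canonical_hrf, sample_event_regressor
from soundmvpa.synth import N_LOCATIONS, RunDesign, VolumeSeries

__all__ = [
    "DesignMatrix",
    "ResponseImage",
    "ContrastResult",
    "canonical_hrf",
    "build_design_matrix",
    "fit_run_glm",
    "smooth_volume",
    "smooth_series",
    "univariate_contrast",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class DesignMatrix:
    """Design with named columns; rows are acquired volumes."""

    matrix: np.ndarray
    column_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.matrix.shape[1] != len(self.column_names):
            raise ValueError("one name per column required")

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.column_names.index(name)]


@dataclass(frozen=True)
class ResponseImage:
    """Per-location beta maps for one run (the MVPA feature source)."""

    run_id: int
    betas: np.ndarray  # (16, x, y, z)
    residual_variance: np.ndarray  # (x, y, z)
    extra_betas: dict | None = None  # trend / intercept coefficient maps

    def __post_init__(self) -> None:
        if self.betas.shape[0] != N_LOCATIONS:
            raise ValueError(f"expected {N_LOCATIONS} beta maps, got {self.betas.shape[0]}")
        if self.betas.shape[1:] != self.residual_variance.shape:
            raise ValueError("beta and variance grids disagree")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.betas.shape[1:]

    @property
    def n_beta_maps(self) -> int:
        return self.betas.shape[0]


@dataclass(frozen=True)
class ContrastResult:
    t_map: np.ndarray
    p_map: np.ndarray
    significance_mask: np.ndarray
    alpha: float
    method: str = "fdr_bh"

    def __post_init__(self) -> None:
        finite = np.isfinite(self.p_map)
        if np.any((self.p_map[finite] < 0) | (self.p_map[finite] > 1)):
            raise ValueError("p values must lie in [0, 1]")
        if np.any(self.significance_mask & ~finite):
            raise ValueError("significance mask marks voxels without finite p")


def _trend_and_intercept(n_rows: int) -> tuple[np.ndarray, np.ndarray]:
    trend = np.arange(n_rows, dtype=float)
    trend -= trend.mean()
    return trend, np.ones(n_rows)


def build_design_matrix(
    design: RunDesign,
    hrf=canonical_hrf,
    acquisition_times: np.ndarray | None = None,
    dt_s: float = 0.1,
) -> DesignMatrix:
    """76 × 18 design: 16 location regressors + linear trend + intercept.

    Each location's column is its four stimulus boxcars convolved with the
    HRF on a fine grid and sampled at the acquisition times.  Silent
    trials contribute no column.  Raises on rank deficiency, naming the
    offending columns.
    """
    times = (
        np.asarray(acquisition_times, dtype=float)
        if acquisition_times is not None
        else design.acquisition_times_s
    )
    n = len(design.trials)
    cols = []
    names = []
    for lid in range(N_LOCATIONS):
        trials = design.stimulus_trials(lid)
        col = sample_event_regressor(
            np.array([t.stim_onset_s for t in trials]),
            np.array([t.stim_duration_s for t in trials]),
            times,
            hrf=hrf,
            dt_s=dt_s,
        )
        cols.append(col)
        names.append(f"loc_{lid:02d}")
    trend, intercept = _trend_and_intercept(n)
    cols += [trend, intercept]
    names += ["trend", "intercept"]
    X = np.column_stack(cols)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        null_cols = [names[j] for j in range(X.shape[1]) if np.allclose(X[:, j], 0)]
        detail = f" (all-zero columns: {null_cols})" if null_cols else ""
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}){detail}"
        )
    return DesignMatrix(matrix=X, column_names=tuple(names))


def _ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS for many voxels at once: coefficients, residual variance, (X'X)^-1."""
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ X.T @ Y
    resid = Y - X @ coef
    dof = X.shape[0] - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / dof
    return coef, sigma2, xtx_inv


def fit_run_glm(vol: VolumeSeries, dm: DesignMatrix, run_id: int = 0) -> ResponseImage:
    """Voxelwise ordinary least squares; no spatial smoothing is applied."""
    if vol.n_volumes != dm.n_rows:
        raise ValueError(
            f"volume count {vol.n_volumes} does not match design rows {dm.n_rows}"
        )
    grid_shape = vol.data.shape[:3]
    Y = vol.data.reshape(-1, vol.n_volumes).T  # (n_volumes, n_voxels)
    coef, sigma2, _ = _ols(dm.matrix, Y)

    loc_idx = [dm.column_names.index(f"loc_{l:02d}") for l in range(N_LOCATIONS)]
    betas = coef[loc_idx, :].reshape(N_LOCATIONS, *grid_shape)
    extra = {
        name: coef[dm.column_names.index(name), :].reshape(grid_shape)
        for name in ("trend", "intercept")
        if name in dm.column_names
    }
    return ResponseImage(
        run_id=run_id,
        betas=betas,
        residual_variance=sigma2.reshape(grid_shape),
        extra_betas=extra,
    )


def smooth_volume(
    grid_3d: np.ndarray,
    fwhm_mm: float | Sequence[float],
    voxel_size_mm: Sequence[float],
) -> np.ndarray:
    """Separable Gaussian smoothing; width given as FWHM per axis in mm."""
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,))
    if np.any(fwhm < 0):
        raise ValueError("fwhm must be non-negative")
    sigma_vox = fwhm * _FWHM_TO_SIGMA / np.asarray(voxel_size_mm, dtype=float)
    if np.all(sigma_vox == 0):
        return grid_3d.copy()
    return ndimage.gaussian_filter(grid_3d, sigma=sigma_vox, mode="nearest")


def smooth_series(vol: VolumeSeries, fwhm_mm: float) -> VolumeSeries:
    """Smooth every volume of a series (univariate path only)."""
    smoothed = np.stack(
        [
            smooth_volume(vol.data[..., t], fwhm_mm, vol.voxel_size_mm)
            for t in range(vol.n_volumes)
        ],
        axis=-1,
    )
    return VolumeSeries(
        data=smoothed,
        acquisition_times_s=vol.acquisition_times_s,
        voxel_size_mm=vol.voxel_size_mm,
    )


def _stimulus_design(design: RunDesign, times: np.ndarray, hrf, dt_s: float) -> np.ndarray:
    trials = design.stimulus_trials()
    stim = sample_event_regressor(
        np.array([t.stim_onset_s for t in trials]),
        np.array([t.stim_duration_s for t in trials]),
        times,
        hrf=hrf,
        dt_s=dt_s,
    )
    trend, intercept = _trend_and_intercept(len(times))
    return np.column_stack([stim, trend, intercept])


def univariate_contrast(
    all_runs: Sequence[tuple[RunDesign, VolumeSeries]],
    alpha: float = 0.05,
    smooth_fwhm_mm: float | None = 5.0,
    hrf=canonical_hrf,
    dt_s: float = 0.1,
) -> ContrastResult:
    """Stimulus-vs-silent activation map across runs, BH-FDR thresholded.

    Per run a three-column GLM (pooled stimulus regressor, trend,
    intercept) is fit to (optionally smoothed) data; per-run stimulus
    betas are combined fixed-effects (summed estimates over pooled
    standard error) into one t statistic per voxel.
    """
    if len(all_runs) < 2:
        raise ValueError("univariate contrast needs at least 2 runs")

    beta_sum = None
    var_sum = None
    total_dof = 0
    grid_shape = None
    for design, vol in all_runs:
        if smooth_fwhm_mm:
            vol = smooth_series(vol, smooth_fwhm_mm)
        grid_shape = vol.data.shape[:3]
        X = _stimulus_design(design, vol.acquisition_times_s, hrf, dt_s)
        Y = vol.data.reshape(-1, vol.n_volumes).T
        coef, sigma2, xtx_inv = _ols(X, Y)
        beta = coef[0, :]
        var = sigma2 * xtx_inv[0, 0]
        beta_sum = beta if beta_sum is None else beta_sum + beta
        var_sum = var if var_sum is None else var_sum + var
        total_dof += X.shape[0] - X.shape[1]

    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta_sum / np.sqrt(var_sum)
    p = 2.0 * stats.t.sf(np.abs(t), df=total_dof)
    finite = np.isfinite(p)
    mask = np.zeros_like(finite)
    if finite.any():
        reject, _, _, _ = multipletests(p[finite], alpha=alpha, method="fdr_bh")
        mask[finite] = reject
    return ContrastResult(
        t_map=t.reshape(grid_shape),
        p_map=p.reshape(grid_shape),
        significance_mask=mask.reshape(grid_shape),
        alpha=alpha,
    )
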