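"""Permutation-test voxel selection from linear-SVM weights.

For one training set, class labels are permuted ``n_perm`` times (default
2000) and a linear SVM is trained on each permutation; the per-voxel
weight samples are summarized by a Gaussian fit (mean, sd).  The weight
obtained with the true labels is then converted to a two-sided Gaussian
tail p-value per voxel, and voxels with p below the significance level
are selected.  Selection is always computed from training runs only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage, stats
from sklearn.svm import SVC

from soundmvpa.geometry import ConditionLabeling
from soundmvpa.glm import ResponseImage, smooth_volume
from soundmvpa.rng import substream

__all__ = [
    "FeatureTable",
    "GaussianNull",
    "SelectionResult",
    "build_roi_mask",
    "assemble_features",
    "train_svm_weights",
    "permutation_null",
    "voxel_pvalues",
    "select_voxels",
    "run_fold_selection",
]

DEFAULT_N_PERM = 2000
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class FeatureTable:
    """(run, location) response rows × ROI-voxel columns for one condition."""

    features: np.ndarray  # (n_rows, n_voxels)
    labels: np.ndarray  # +1 (class_a) / -1 (class_b) per row
    run_ids: np.ndarray  # per row
    location_ids: np.ndarray  # per row
    voxel_indices: np.ndarray  # flat grid index per column
    condition: str

    def __post_init__(self) -> None:
        n = self.features.shape[0]
        if not (len(self.labels) == len(self.run_ids) == len(self.location_ids) == n):
            raise ValueError("row annotations must match feature rows")
        if self.features.shape[1] != len(self.voxel_indices):
            raise ValueError("one voxel index per column required")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be +/-1")

    @property
    def n_rows(self) -> int:
        return self.features.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.features.shape[1]


@dataclass(frozen=True)
class GaussianNull:
    """Per-voxel Gaussian fit of the permuted-label SVM weights."""

    null_mean: np.ndarray
    null_sd: np.ndarray
    n_perm: int
    degenerate: np.ndarray  # voxels with zero feature variance

    def __post_init__(self) -> None:
        if np.any(self.null_sd < 0):
            raise ValueError("null_sd must be non-negative")
        if self.n_perm < 2:
            raise ValueError("need at least 2 permutations")


@dataclass(frozen=True)
class SelectionResult:
    """Thresholded voxel selection for one training fold."""

    condition: str
    fold_id: int
    p_values: np.ndarray
    selected: np.ndarray  # boolean per voxel column
    voxel_indices: np.ndarray
    alpha: float = DEFAULT_ALPHA
    fallback: bool = False  # empty selection replaced by the full ROI

    def __post_init__(self) -> None:
        if np.any((self.p_values < 0) | (self.p_values > 1)):
            raise ValueError("p values must lie in [0, 1]")
        if len(self.selected) != len(self.p_values) or len(self.voxel_indices) != len(
            self.p_values
        ):
            raise ValueError("per-voxel arrays must align")

    @property
    def selected_voxel_indices(self) -> np.ndarray:
        return self.voxel_indices[self.selected]

    def to_json(self, path: str | Path, include_pvalues: bool = True) -> None:
        payload = {
            "condition": self.condition,
            "fold_id": int(self.fold_id),
            "alpha": self.alpha,
            "fallback": bool(self.fallback),
            "voxel_indices": self.voxel_indices.tolist(),
            "selected": self.selected.astype(int).tolist(),
        }
        if include_pvalues:
            payload["p_values"] = self.p_values.tolist()
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionResult":
        d = json.loads(Path(path).read_text())
        n = len(d["voxel_indices"])
        return cls(
            condition=d["condition"],
            fold_id=d["fold_id"],
            p_values=np.asarray(d.get("p_values", [1.0] * n), dtype=float),
            selected=np.asarray(d["selected"], dtype=bool),
            voxel_indices=np.asarray(d["voxel_indices"], dtype=int),
            alpha=d["alpha"],
            fallback=d["fallback"],
        )


def build_roi_mask(
    base_mask: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: Sequence[float] = (1.0, 1.0, 1.0),
    threshold: float = 0.5,
) -> np.ndarray:
    """Gaussian-smooth a binary mask and re-binarize it.

    Raises if the result is empty; the number of connected components is
    checked (a disconnected result is legal — bilateral ROIs have two).
    """
    base = np.asarray(base_mask).astype(float)
    smoothed = smooth_volume(base, fwhm_mm, voxel_size_mm)
    roi = smoothed >= threshold
    if not roi.any():
        raise ValueError("ROI mask is empty after smoothing and thresholding")
    ndimage.label(roi)  # validates connectivity structure; count is informational
    return roi


def assemble_features(
    responses: Sequence[ResponseImage],
    labeling: ConditionLabeling,
    roi_mask: np.ndarray,
    runs: Sequence[int] | None = None,
) -> FeatureTable:
    """One row per (run, included location); columns are ROI voxels.

    ``runs`` selects run ids (``ResponseImage.run_id``); default all.
    """
    by_id = {r.run_id: r for r in responses}
    run_ids = sorted(by_id) if runs is None else list(runs)
    if not run_ids:
        raise ValueError("at least one run required")
    roi_flat = np.flatnonzero(np.asarray(roi_mask, dtype=bool).ravel())
    included = sorted(labeling.included)

    rows, labels, row_runs, row_locs = [], [], [], []
    for rid in run_ids:
        if rid not in by_id:
            raise KeyError(f"run {rid} not among supplied responses")
        resp = by_id[rid]
        flat = resp.betas.reshape(resp.n_beta_maps, -1)
        for lid in included:
            rows.append(flat[lid, roi_flat])
            labels.append(labeling.label_of(lid))
            row_runs.append(rid)
            row_locs.append(lid)
    return FeatureTable(
        features=np.asarray(rows),
        labels=np.asarray(labels),
        run_ids=np.asarray(row_runs),
        location_ids=np.asarray(row_locs),
        voxel_indices=roi_flat,
        condition=labeling.condition,
    )


def standardize_features(
    X: np.ndarray, mean: np.ndarray | None = None, sd: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-voxel z-scoring; zero-variance voxels are left centred only."""
    if mean is None:
        mean = X.mean(axis=0)
    if sd is None:
        sd = X.std(axis=0)
    safe_sd = np.where(sd > 0, sd, 1.0)
    return (X - mean) / safe_sd, mean, sd


def train_svm_weights(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> np.ndarray:
    """Weight vector of a linear SVM trained on (X, y)."""
    clf = SVC(kernel="linear", C=C)
    clf.fit(X, y)
    return clf.coef_.ravel().copy()


def permutation_null(
    ft: FeatureTable,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | np.random.Generator = 0,
    C: float = 1.0,
    standardize: bool = True,
) -> GaussianNull:
    """Gaussian null of each voxel's SVM weight under label permutation."""
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    if len(np.unique(ft.labels)) < 2:
        raise ValueError("both classes must be present")
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "permutation")

    X = ft.features
    degenerate = X.std(axis=0) == 0
    if standardize:
        X, _, _ = standardize_features(X)

    weights = np.empty((n_perm, ft.n_voxels))
    for i in range(n_perm):
        perm_labels = rng.permutation(ft.labels)
        weights[i] = train_svm_weights(X, perm_labels, C=C)
    null_sd = weights.std(axis=0, ddof=1)
    null_sd[degenerate] = 0.0
    return GaussianNull(
        null_mean=weights.mean(axis=0),
        null_sd=null_sd,
        n_perm=n_perm,
        degenerate=degenerate,
    )


def voxel_pvalues(true_weights: np.ndarray, null: GaussianNull) -> np.ndarray:
    """Two-sided Gaussian tail p per voxel: 2·Φ(−|w − μ|/σ).

    Degenerate voxels (σ = 0) get p = 1 when the weight equals the null
    mean and p = 0 otherwise.
    """
    w = np.asarray(true_weights, dtype=float)
    p = np.ones_like(w)
    ok = null.null_sd > 0
    p[ok] = 2.0 * stats.norm.sf(np.abs(w[ok] - null.null_mean[ok]) / null.null_sd[ok])
    zero = ~ok
    p[zero] = np.where(w[zero] == null.null_mean[zero], 1.0, 0.0)
    return np.clip(p, 0.0, 1.0)


def select_voxels(
    p_values: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    voxel_indices: np.ndarray | None = None,
    condition: str = "",
    fold_id: int = -1,
    exclude: np.ndarray | None = None,
) -> SelectionResult:
    """Strict threshold p < alpha; empty selections fall back to all voxels.

    ``exclude`` (e.g. degenerate voxels) are never selected.  The fallback
    keeps cross-validation folds populated and is flagged on the result.
    """
    p = np.asarray(p_values, dtype=float)
    if voxel_indices is None:
        voxel_indices = np.arange(len(p))
    selected = p < alpha
    if exclude is not None:
        selected &= ~np.asarray(exclude, dtype=bool)
    fallback = False
    if not selected.any():
        selected = np.ones_like(selected, dtype=bool)
        if exclude is not None:
            selected &= ~np.asarray(exclude, dtype=bool)
        fallback = True
    return SelectionResult(
        condition=condition,
        fold_id=fold_id,
        p_values=p,
        selected=selected,
        voxel_indices=np.asarray(voxel_indices),
        alpha=alpha,
        fallback=fallback,
    )


def run_fold_selection(
    ft: FeatureTable,
    fold_id: int,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = DEFAULT_ALPHA,
    seed: int | np.random.Generator = 0,
    C: float = 1.0,
    standardize: bool = True,
) -> SelectionResult:
    """Full selection for one training fold: null, p-values, threshold."""
    X = ft.features
    if standardize:
        X, _, _ = standardize_features(X)
    true_w = train_svm_weights(X, ft.labels, C=C)
    null = permutation_null(ft, n_perm=n_perm, seed=seed, C=C, standardize=standardize)
    p = voxel_pvalues(true_w, null)
    return select_voxels(
        p,
        alpha=alpha,
        voxel_indices=ft.voxel_indices,
        condition=ft.condition,
        fold_id=fold_id,
        exclude=null.degenerate,
    )
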