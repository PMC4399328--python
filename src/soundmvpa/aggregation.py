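"""Effective-voxel conjunctions and the exact binomial significance bound.

A voxel selected in more than four of a subject's eight cross-validation
folds is an effective voxel (EV); an EV shared by at least three subjects
is a significant effective voxel (SEV).  Treating per-subject EV status as
a Bernoulli trial with success probability p, the subject count X is
binomial and the SEV criterion is justified by the upper tail P(X >= 3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np

from soundmvpa.selection import SelectionResult
from soundmvpa.synth import N_RUNS

__all__ = [
    "EVMask",
    "SEVMask",
    "effective_voxels",
    "significant_effective_voxels",
    "binomial_tail",
    "recovery_scores",
]

DEFAULT_MIN_FOLDS = 5  # "more than four" of 8 folds
DEFAULT_MIN_SUBJECTS = 3


@dataclass(frozen=True)
class EVMask:
    """Per-subject conjunction of fold selections for one condition."""

    subject_id: str
    condition: str
    mask: np.ndarray  # boolean grid
    fold_counts: np.ndarray  # integer grid, 0..8
    min_folds: int = DEFAULT_MIN_FOLDS

    def __post_init__(self) -> None:
        if self.mask.shape != self.fold_counts.shape:
            raise ValueError("mask and fold_counts grids disagree")
        if self.fold_counts.max(initial=0) > N_RUNS:
            raise ValueError(f"fold counts cannot exceed {N_RUNS}")
        if not np.array_equal(self.mask, self.fold_counts >= self.min_folds):
            raise ValueError("mask must equal fold_counts >= min_folds")

    @property
    def n_effective(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class SEVMask:
    """Cross-subject conjunction of EV masks for one condition."""

    condition: str
    mask: np.ndarray
    subject_counts: np.ndarray
    min_subjects: int = DEFAULT_MIN_SUBJECTS

    def __post_init__(self) -> None:
        if self.mask.shape != self.subject_counts.shape:
            raise ValueError("mask and subject_counts grids disagree")
        if not np.array_equal(self.mask, self.subject_counts >= self.min_subjects):
            raise ValueError("mask must equal subject_counts >= min_subjects")

    @property
    def n_significant(self) -> int:
        return int(self.mask.sum())

    def to_json(self, path: str | Path) -> None:
        payload = {
            "condition": self.condition,
            "min_subjects": self.min_subjects,
            "n_significant": self.n_significant,
            "grid_shape": list(self.mask.shape),
            "voxels": np.flatnonzero(self.mask.ravel()).tolist(),
            "subject_counts": self.subject_counts.ravel()[
                np.flatnonzero(self.subject_counts.ravel())
            ].tolist(),
        }
        Path(path).write_text(json.dumps(payload))


def effective_voxels(
    fold_selections: Sequence[SelectionResult],
    grid_shape: tuple[int, int, int],
    min_folds: int = DEFAULT_MIN_FOLDS,
    subject_id: str = "sub-01",
) -> EVMask:
    """Count per-voxel fold selections and threshold at ``min_folds``."""
    if len(fold_selections) != N_RUNS:
        raise ValueError(f"expected {N_RUNS} fold selections, got {len(fold_selections)}")
    conditions = {s.condition for s in fold_selections}
    if len(conditions) != 1:
        raise ValueError(f"fold selections mix conditions: {sorted(conditions)}")
    counts = np.zeros(int(np.prod(grid_shape)), dtype=int)
    for sel in fold_selections:
        counts[sel.selected_voxel_indices] += 1
    counts = counts.reshape(grid_shape)
    return EVMask(
        subject_id=subject_id,
        condition=conditions.pop(),
        mask=counts >= min_folds,
        fold_counts=counts,
        min_folds=min_folds,
    )


def significant_effective_voxels(
    ev_masks: Sequence[EVMask],
    min_subjects: int = DEFAULT_MIN_SUBJECTS,
) -> SEVMask:
    """Count per-voxel EV subjects and threshold at ``min_subjects``."""
    if len(ev_masks) < min_subjects:
        raise ValueError(
            f"need at least {min_subjects} subjects, got {len(ev_masks)}"
        )
    shapes = {m.mask.shape for m in ev_masks}
    if len(shapes) != 1:
        raise ValueError(f"EV masks have mismatched grids: {sorted(shapes)}")
    conditions = {m.condition for m in ev_masks}
    if len(conditions) != 1:
        raise ValueError(f"EV masks mix conditions: {sorted(conditions)}")
    counts = np.sum([m.mask.astype(int) for m in ev_masks], axis=0)
    return SEVMask(
        condition=conditions.pop(),
        mask=counts >= min_subjects,
        subject_counts=counts,
        min_subjects=min_subjects,
    )


def binomial_tail(n_subjects: int, p_success: float, k_min: int) -> float:
    """Exact upper tail P(X >= k_min) for X ~ Binomial(n_subjects, p).

    Computed as the finite sum of C(n, k) p^k (1-p)^(n-k); monotone
    increasing in ``p_success``.
    """
    if not (0.0 <= p_success <= 1.0):
        raise ValueError("p_success must lie in [0, 1]")
    if not (0 <= k_min <= n_subjects):
        raise ValueError("k_min must lie in [0, n_subjects]")
    if k_min == 0:
        return 1.0
    return float(
        sum(
            comb(n_subjects, k) * p_success**k * (1.0 - p_success) ** (n_subjects - k)
            for k in range(k_min, n_subjects + 1)
        )
    )


def recovery_scores(
    predicted_mask: np.ndarray, truth_voxels: Sequence[int]
) -> dict[str, float]:
    """Sensitivity and precision of a voxel mask against planted ground truth."""
    pred = np.flatnonzero(np.asarray(predicted_mask).ravel())
    truth = set(int(v) for v in truth_voxels)
    hit = len(truth & set(pred.tolist()))
    sensitivity = hit / len(truth) if truth else float("nan")
    precision = hit / len(pred) if len(pred) else float("nan")
    return {"sensitivity": sensitivity, "precision": precision, "n_predicted": float(len(pred))}
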