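"""Leave-one-run-out SVM decoding and the group test against chance.

Each of the 8 runs serves once as the test set; voxel selection and
feature standardization are computed from the 7 training runs only, a
linear SVM is trained on the selected voxels, and accuracy is scored on
the held-out run's included locations.  Subject mean accuracies are then
tested against chance (0.5) with a one-sided one-sample t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from soundmvpa.geometry import ConditionLabeling
from soundmvpa.glm import ResponseImage
from soundmvpa.rng import substream
from soundmvpa.selection import (
    DEFAULT_ALPHA,
    DEFAULT_N_PERM,
    assemble_features,
    run_fold_selection,
    standardize_features,
)
from soundmvpa.synth import N_RUNS

__all__ = [
    "DecodingResult",
    "GroupResult",
    "loro_cv",
    "loro_cv_with_selections",
    "group_accuracy_test",
]


@dataclass(frozen=True)
class DecodingResult:
    subject_id: str
    condition: str
    fold_accuracies: tuple[float, ...]
    n_test_per_fold: tuple[int, ...]
    selection_flags: tuple[bool, ...]  # True where the fold fell back to full ROI
    balanced_fold_accuracies: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.fold_accuracies) != N_RUNS:
            raise ValueError(f"expected {N_RUNS} folds")
        if any(not (0.0 <= a <= 1.0) for a in self.fold_accuracies):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def mean_balanced_accuracy(self) -> float:
        return float(np.mean(self.balanced_fold_accuracies))

    def to_json_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "condition": self.condition,
            "fold_accuracies": list(self.fold_accuracies),
            "mean_accuracy": self.mean_accuracy,
            "balanced_fold_accuracies": list(self.balanced_fold_accuracies),
            "mean_balanced_accuracy": self.mean_balanced_accuracy,
            "n_test_per_fold": list(self.n_test_per_fold),
            "selection_flags": list(self.selection_flags),
        }


@dataclass(frozen=True)
class GroupResult:
    condition: str
    subject_accuracies: tuple[float, ...]
    chance: float
    t_statistic: float
    df: int
    p_value: float
    test_name: str = "one-sample t-test (one-sided, greater)"
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")

    @property
    def group_mean(self) -> float:
        return float(np.mean(self.subject_accuracies))

    def to_json_dict(self) -> dict:
        return {
            "condition": self.condition,
            "subject_accuracies": list(self.subject_accuracies),
            "group_mean": self.group_mean,
            "chance": self.chance,
            "t_statistic": self.t_statistic,
            "df": self.df,
            "p_value": self.p_value,
            "test_name": self.test_name,
            "degenerate": self.degenerate,
        }


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    accs = [np.mean(y_pred[y_true == c] == c) for c in np.unique(y_true)]
    return float(np.mean(accs))


def loro_cv_with_selections(
    responses: list[ResponseImage],
    labeling: ConditionLabeling,
    roi_mask: np.ndarray,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = DEFAULT_ALPHA,
    C: float = 1.0,
    standardize: bool = True,
    seed: int = 0,
    subject_id: str = "sub-01",
) -> tuple[DecodingResult, list]:
    """Leave-one-run-out decoding of one condition for one subject.

    Voxel selection (permutation null at ``alpha``) and standardization
    statistics are derived from the training runs of each fold only.
    Returns the decoding result plus the per-fold selections (needed for
    the effective-voxel conjunction downstream).
    """
    run_ids = sorted(r.run_id for r in responses)
    if len(run_ids) != N_RUNS or len(set(run_ids)) != N_RUNS:
        raise ValueError(f"exactly {N_RUNS} distinct runs required, got {run_ids}")

    fold_accs, fold_bal, fold_n, flags, selections = [], [], [], [], []
    for fold_id, test_run in enumerate(run_ids):
        train_runs = [r for r in run_ids if r != test_run]
        ft_train = assemble_features(responses, labeling, roi_mask, runs=train_runs)
        sel = run_fold_selection(
            ft_train,
            fold_id=fold_id,
            n_perm=n_perm,
            alpha=alpha,
            seed=substream(seed, "selection", fold_id),
            C=C,
            standardize=standardize,
        )

        X_train = ft_train.features
        mean = sd = None
        if standardize:
            X_train, mean, sd = standardize_features(X_train)
        cols = sel.selected
        clf = SVC(kernel="linear", C=C)
        clf.fit(X_train[:, cols], ft_train.labels)

        ft_test = assemble_features(responses, labeling, roi_mask, runs=[test_run])
        X_test = ft_test.features
        if standardize:
            X_test, _, _ = standardize_features(X_test, mean, sd)
        y_pred = clf.predict(X_test[:, cols])
        fold_accs.append(float(np.mean(y_pred == ft_test.labels)))
        fold_bal.append(_balanced_accuracy(ft_test.labels, y_pred))
        fold_n.append(ft_test.n_rows)
        flags.append(sel.fallback)
        selections.append(sel)

    result = DecodingResult(
        subject_id=subject_id,
        condition=labeling.condition,
        fold_accuracies=tuple(fold_accs),
        n_test_per_fold=tuple(fold_n),
        selection_flags=tuple(flags),
        balanced_fold_accuracies=tuple(fold_bal),
    )
    return result, selections


def loro_cv(
    responses: list[ResponseImage],
    labeling: ConditionLabeling,
    roi_mask: np.ndarray,
    **kwargs,
) -> DecodingResult:
    """As :func:`loro_cv_with_selections`, returning only the result."""
    result, _ = loro_cv_with_selections(responses, labeling, roi_mask, **kwargs)
    return result


def group_accuracy_test(
    accuracies: list[float] | np.ndarray,
    chance: float = 0.5,
    condition: str = "",
) -> GroupResult:
    """One-sided one-sample t-test of subject accuracies against chance."""
    acc = np.asarray(accuracies, dtype=float)
    if acc.size < 2:
        raise ValueError("group test needs at least 2 subjects")
    if acc.max() == acc.min():
        # no variance: the t statistic is undefined unless centred on chance
        if acc[0] == chance:
            t_stat, p, degen = 0.0, 0.5, False
        else:
            t_stat = np.inf if acc[0] > chance else -np.inf
            p = 0.0 if acc[0] > chance else 1.0
            degen = True
        return GroupResult(
            condition=condition,
            subject_accuracies=tuple(acc.tolist()),
            chance=chance,
            t_statistic=float(t_stat),
            df=acc.size - 1,
            p_value=float(p),
            degenerate=degen,
        )
    res = stats.ttest_1samp(acc, popmean=chance, alternative="greater")
    return GroupResult(
        condition=condition,
        subject_accuracies=tuple(acc.tolist()),
        chance=chance,
        t_statistic=float(res.statistic),
        df=acc.size - 1,
        p_value=float(res.pvalue),
    )
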