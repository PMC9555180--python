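"""RBF-kernel SVM classification of patients vs controls from FC features.

Protocol: features are min-max scaled to [-1, +1] using training subjects
only; an RBF support-vector classifier is evaluated with leave-one-out
cross-validation; cost C and kernel width gamma come from a powers-of-two
grid search.  Two grid-search designs are exposed:

* ``nested=True`` (default, leak-free): (C, gamma) is re-selected inside
  every leave-one-out fold via an inner stratified k-fold on the training
  subjects.
* ``nested=False``: (C, gamma) is selected once by leave-one-out accuracy
  over the whole sample and then used in every fold.  This reproduces the
  common global-grid design of the clinical classification literature but
  lets the held-out subject influence parameter choice; the nested mode is
  the honest performance estimate.

Significance of the observed accuracy is assessed by a label-permutation
test that repeats the full procedure per permutation.  Confound-only
baselines (age, sex, education, head motion) run the identical protocol on
a single nuisance column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

DEFAULT_C_GRID = tuple(2.0 ** k for k in range(-5, 16, 2))       # 2^-5 .. 2^15
DEFAULT_GAMMA_GRID = tuple(2.0 ** k for k in range(-15, 4, 2))   # 2^-15 .. 2^3
DEFAULT_CONFOUNDS = ("age", "mean_fd", "sex", "education_years")

PATIENT = 1
CONTROL = -1


@dataclass
class ClassificationResult:
    accuracy: float
    sensitivity: float
    specificity: float
    C: float
    gamma: float
    predictions: np.ndarray = field(repr=False)
    permutation_p: float | None = None


def classification_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) with patients coded +1."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    correct = y_true == y_pred
    acc = correct.mean()
    sens = correct[y_true == PATIENT].mean()
    spec = correct[y_true == CONTROL].mean()
    return float(acc), float(sens), float(spec)


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if not set(np.unique(y)) <= {PATIENT, CONTROL}:
        raise ValueError("labels must be +1 (patient) / -1 (control)")
    return y


def _minmax_bounds(train: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return train.min(axis=0), train.max(axis=0)


def _minmax_apply(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = np.where(hi > lo, hi - lo, 1.0)
    # test-fold values outside the training range pass through unclipped
    return 2.0 * (x - lo) / span - 1.0


def _fit_predict(train_X, train_y, test_X, C, gamma):
    clf = SVC(C=C, gamma=gamma, kernel="rbf")
    clf.fit(train_X, train_y)
    return clf.predict(test_X)


def _grid_search(X: np.ndarray, y: np.ndarray, C_grid, gamma_grid,
                 n_folds: int, loo: bool = False) -> tuple[float, float]:
    """Best (C, gamma) by CV accuracy; ties -> smallest C, then smallest gamma."""
    n = len(y)
    if loo:
        splits = [(np.delete(np.arange(n), i), np.array([i])) for i in range(n)]
    else:
        class_min = min((y == PATIENT).sum(), (y == CONTROL).sum())
        k = max(2, min(n_folds, class_min))
        skf = StratifiedKFold(n_splits=k, shuffle=False)
        splits = list(skf.split(X, y))
    fold_data = []
    for tr, te in splits:
        if len(np.unique(y[tr])) < 2:
            raise ValueError("single-class training fold in grid search")
        lo, hi = _minmax_bounds(X[tr])
        fold_data.append((_minmax_apply(X[tr], lo, hi), y[tr],
                          _minmax_apply(X[te], lo, hi), y[te]))
    best = (-1.0, None, None)
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            correct = 0
            for trX, trY, teX, teY in fold_data:
                correct += int((_fit_predict(trX, trY, teX, C, gamma) == teY).sum())
            acc = correct / n
            if acc > best[0]:
                best = (acc, C, gamma)
    return best[1], best[2]


def loocv_rbf_svm(X: np.ndarray, y: np.ndarray,
                  C_grid=DEFAULT_C_GRID, gamma_grid=DEFAULT_GAMMA_GRID,
                  nested: bool = True, inner_folds: int = 5) -> ClassificationResult:
    """Leave-one-out RBF-SVM classification with grid-searched (C, gamma)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = _check_labels(y)
    n = len(y)
    if n < 6:
        raise ValueError("need at least 6 subjects for LOOCV")
    if len(C_grid) == 0 or len(gamma_grid) == 0:
        raise ValueError("parameter grids must be non-empty")

    chosen: list[tuple[float, float]] = []
    if not nested:
        global_C, global_gamma = _grid_search(X, y, C_grid, gamma_grid,
                                              n_folds=0, loo=True)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        tr = np.delete(np.arange(n), i)
        if len(np.unique(y[tr])) < 2:
            raise ValueError("single-class training fold")
        if nested:
            C, gamma = _grid_search(X[tr], y[tr], C_grid, gamma_grid,
                                    n_folds=inner_folds)
        else:
            C, gamma = global_C, global_gamma
        chosen.append((C, gamma))
        lo, hi = _minmax_bounds(X[tr])
        preds[i] = _fit_predict(_minmax_apply(X[tr], lo, hi), y[tr],
                                _minmax_apply(X[i:i + 1], lo, hi), C, gamma)[0]

    acc, sens, spec = classification_metrics(y, preds)
    # report the modal parameter pair across folds (unique in non-nested mode)
    pairs, counts = np.unique(np.array(chosen), axis=0, return_counts=True)
    mode_C, mode_gamma = pairs[np.argmax(counts)]
    return ClassificationResult(accuracy=acc, sensitivity=sens, specificity=spec,
                                C=float(mode_C), gamma=float(mode_gamma),
                                predictions=preds)


def permutation_test(X: np.ndarray, y: np.ndarray, n_permutations: int = 1000,
                     seed: int = 0, observed: ClassificationResult | None = None,
                     **loocv_kwargs) -> tuple[float, np.ndarray]:
    """Permutation p for the LOOCV accuracy: labels shuffled, full rerun.

    p = (1 + #{permutation accuracy >= observed}) / (1 + n_permutations),
    never zero by construction.
    """
    if n_permutations < 19:
        raise ValueError("need at least 19 permutations")
    y = _check_labels(y)
    if observed is None:
        observed = loocv_rbf_svm(X, y, **loocv_kwargs)
    rng = np.random.default_rng(seed)
    perm_acc = np.empty(n_permutations)
    for b in range(n_permutations):
        perm_acc[b] = loocv_rbf_svm(X, rng.permutation(y), **loocv_kwargs).accuracy
    p = (1.0 + (perm_acc >= observed.accuracy).sum()) / (1.0 + n_permutations)
    return float(p), perm_acc


def extract_region_features(maps: np.ndarray, cluster_voxels: np.ndarray,
                            mode: str = "cluster_mean") -> np.ndarray:
    """Per-subject features from one cluster of an FC-strength map stack.

    ``maps`` is subjects x V; ``cluster_voxels`` indexes in-mask voxels.
    ``cluster_mean`` yields one column (the cluster average), ``voxel_vector``
    keeps every cluster voxel as a feature.
    """
    maps = np.asarray(maps, dtype=float)
    cluster_voxels = np.asarray(cluster_voxels, dtype=int)
    if cluster_voxels.size == 0:
        raise ValueError("empty cluster")
    sub = maps[:, cluster_voxels]
    if mode == "cluster_mean":
        return sub.mean(axis=1, keepdims=True)
    if mode == "voxel_vector":
        return sub
    raise ValueError("mode must be 'cluster_mean' or 'voxel_vector'")


def confound_baselines(subjects: pd.DataFrame, columns=DEFAULT_CONFOUNDS,
                       patient_label: str = "patient",
                       **loocv_kwargs) -> dict[str, ClassificationResult]:
    """Run the identical LOOCV protocol on each scalar confound column."""
    y = np.where(subjects["group"].to_numpy() == patient_label, PATIENT, CONTROL)
    out = {}
    for col in columns:
        if col not in subjects.columns:
            raise ValueError(f"missing confound column {col!r}")
        vals = subjects[col]
        if vals.dtype == object:
            vals = vals.map({"M": 1.0, "F": 0.0})
        out[col] = loocv_rbf_svm(vals.to_numpy(dtype=float)[:, None], y, **loocv_kwargs)
    return out
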