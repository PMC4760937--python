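"""Per-channel SVM training, sum-rule fusion and one-vs-all AUC.

Each feature channel trains its own support vector machine; the kernel
(linear or RBF) and hyperparameters are selected by 5-fold
cross-validation on the training rows, scored by mean one-vs-all AUC.
Per-class margins are mapped through a softmax to row-stochastic score
matrices, which makes channels commensurate before the sum rule adds
them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from sklearn.calibration import CalibratedClassifierCV
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

#: model-selection grid; linear & small C first so ties break toward
#: the simpler model
SVM_GRID: list[dict] = (
    [{"kernel": "linear", "C": c} for c in (0.1, 1.0, 10.0, 100.0)]
    + [{"kernel": "rbf", "C": c, "gamma": g}
       for c in (0.1, 1.0, 10.0, 100.0)
       for g in [2.0 ** e for e in range(-6, 3)]]
)


@dataclass
class TrainedChannel:
    tag: str
    scaler: StandardScaler
    model: object          # calibrated classifier with predict_proba
    classes: tuple


def _softmax(margins: np.ndarray) -> np.ndarray:
    z = margins - margins.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _margins(model: SVC, x: np.ndarray) -> np.ndarray:
    f = model.decision_function(x)
    if f.ndim == 1:                         # binary: (-f, +f) columns
        f = np.column_stack([-f, f])
    return f


def auc_one_vs_all(scores: np.ndarray, labels: np.ndarray,
                   classes=None) -> tuple[float, np.ndarray]:
    """Mean and per-class one-vs-all AUC, in percent.

    Per class, the AUC of that class's score column against binary class
    membership, computed as the Mann-Whitney rank statistic (ties count
    one half).  Classes without positives (or negatives) are skipped with
    a warning and the mean taken over the rest.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if classes is None:
        classes = np.unique(labels)
    aucs = []
    for k, cls in enumerate(classes):
        pos = labels == cls
        n_pos, n_neg = int(pos.sum()), int((~pos).sum())
        if n_pos == 0 or n_neg == 0:
            warnings.warn(f"class {cls!r} has no positives or no negatives; "
                          "skipped in the AUC mean", stacklevel=2)
            aucs.append(np.nan)
            continue
        ranks = rankdata(scores[:, k])
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        aucs.append(100.0 * auc)
    per_class = np.array(aucs)
    return float(np.nanmean(per_class)), per_class


def train_channel(features: np.ndarray, labels: np.ndarray, seed: int = 0,
                  tag: str = "", cv: int = 5,
                  grid: list[dict] | None = None) -> TrainedChannel:
    """Fit one channel's SVM with inner-CV model selection.

    The grid spans {linear, RBF} x C in {0.1, 1, 10, 100} x (RBF only)
    gamma in 2^-6..2^2, scored by mean one-vs-all AUC under stratified
    5-fold CV on the training rows; ties go to the earlier grid entry
    (linear, then smallest C).  The winner is refit on all rows.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels)
    if np.isnan(x).any():
        raise ValueError("features contain NaN")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train a channel")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 training rows "
                         "for inner cross-validation")
    grid = grid if grid is not None else SVM_GRID
    scaler = StandardScaler().fit(x)
    xs = scaler.transform(x)
    best_auc, best_params = -np.inf, grid[0]
    if len(grid) > 1:
        n_splits = int(min(cv, counts.min()))
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                              random_state=seed)
        splits = list(skf.split(xs, y))
        for params in grid:
            fold_aucs = []
            for tr, te in splits:
                model = SVC(decision_function_shape="ovr", **params)
                model.fit(xs[tr], y[tr])
                scores = _softmax(_score_matrix_for(model, xs[te], classes))
                fold_aucs.append(auc_one_vs_all(scores, y[te], classes)[0])
            mean_auc = float(np.mean(fold_aucs))
            if mean_auc > best_auc:
                best_auc, best_params = mean_auc, params
    # Refit on all rows with sigmoid (Platt) calibration so that scores
    # from models trained in different folds live on one probability
    # scale; without it, pooling test scores across folds is meaningless.
    calib_cv = StratifiedKFold(n_splits=int(min(cv, counts.min())),
                               shuffle=True, random_state=seed)
    model = CalibratedClassifierCV(
        SVC(decision_function_shape="ovr", **best_params),
        method="sigmoid", ensemble=False, cv=calib_cv)
    model.fit(xs, y)
    return TrainedChannel(tag, scaler, model, tuple(classes))


def _score_matrix_for(model: SVC, x: np.ndarray, classes) -> np.ndarray:
    """Margins of ``model`` expanded to the full class-column order."""
    f = _margins(model, x)
    cols = list(model.classes_)
    out = np.full((len(x), len(classes)), -np.inf)
    for j, cls in enumerate(classes):
        if cls in cols:
            out[:, j] = f[:, cols.index(cls)]
    out[~np.isfinite(out)] = np.nanmin(f) - 1.0
    return out


def channel_scores(channel: TrainedChannel, features: np.ndarray) -> np.ndarray:
    """Row-stochastic per-class scores for new samples."""
    x = np.asarray(features, dtype=np.float64)
    if x.shape[1] != channel.scaler.mean_.shape[0]:
        raise ValueError(
            f"feature length {x.shape[1]} does not match training "
            f"({channel.scaler.mean_.shape[0]})")
    proba = channel.model.predict_proba(channel.scaler.transform(x))
    # column order of predict_proba follows model.classes_, which equals
    # np.unique(labels) = channel.classes
    return proba / proba.sum(axis=1, keepdims=True)


def sum_rule(matrices: list[np.ndarray]) -> np.ndarray:
    """Sum-rule fusion: elementwise sum of score matrices, row-renormalized."""
    if not matrices:
        raise ValueError("no score matrices to fuse")
    shape = matrices[0].shape
    if any(m.shape != shape for m in matrices):
        raise ValueError("score matrices differ in shape or class order")
    total = np.sum(matrices, axis=0)
    return total / total.sum(axis=1, keepdims=True)
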