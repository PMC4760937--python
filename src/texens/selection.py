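"""Sequential forward floating selection (SFFS) of ensemble channels.

Channels are selected to maximize the one-vs-all AUC of the sum-rule
ensemble under an internal (group-aware) 10-fold cross-validation of the
training data.  Each channel's out-of-fold score matrix is precomputed
once, so evaluating any candidate subset reduces to summing matrices and
ranking — which also makes the exhaustive-search oracle cheap at test
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .classify import _score_matrix_for, _softmax, auc_one_vs_all


@dataclass
class SffsState:
    selected: tuple[int, ...]
    objective: float
    history: list[tuple[str, int, float]] = field(default_factory=list)


def _group_folds(groups: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold index per row; rows sharing a group id share a fold."""
    uniq = np.array(sorted(set(groups)))
    n_folds = min(n_folds, len(uniq))
    order = np.random.default_rng(seed).permutation(len(uniq))
    fold_of = {uniq[idx]: i % n_folds for i, idx in enumerate(order)}
    return np.array([fold_of[g] for g in groups]), n_folds


def oof_score_matrices(channel_features: list[np.ndarray], labels: np.ndarray,
                       groups: np.ndarray | None = None, folds: int = 10,
                       seed: int = 0, svm_params: dict | None = None,
                       ) -> list[np.ndarray]:
    """Out-of-fold score matrix per channel under one shared fold plan.

    A fixed SVM configuration (default: linear, C = 1) is used inside the
    selector; the full kernel/C grid search belongs to the outer
    per-channel training, not to the selection objective.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("SFFS needs at least 2 classes")
    if groups is None:
        groups = np.arange(len(labels))
    row_folds, n_folds = _group_folds(np.asarray(groups), folds, seed)
    params = svm_params or {"kernel": "linear", "C": 1.0}
    out = []
    for feats in channel_features:
        x = np.asarray(feats, dtype=np.float64)
        scores = np.zeros((len(labels), len(classes)))
        for f in range(n_folds):
            te = row_folds == f
            tr = ~te
            if len(np.unique(labels[tr])) < 2:
                scores[te] = 1.0 / len(classes)
                continue
            scaler = StandardScaler().fit(x[tr])
            model = SVC(decision_function_shape="ovr", **params)
            model.fit(scaler.transform(x[tr]), labels[tr])
            scores[te] = _softmax(_score_matrix_for(
                model, scaler.transform(x[te]), classes))
        out.append(scores)
    return out


def subset_objective(oof_scores: list[np.ndarray], labels: np.ndarray,
                     subset) -> float:
    """Internal-CV AUC of the sum-rule ensemble over a channel subset."""
    total = np.sum([oof_scores[i] for i in subset], axis=0)
    return auc_one_vs_all(total, labels)[0]


def sffs_select(channel_features: list[np.ndarray], labels: np.ndarray,
                groups: np.ndarray | None = None, folds: int = 10,
                max_size: int = 10, seed: int = 0,
                svm_params: dict | None = None) -> SffsState:
    """Select a channel subset by sequential forward floating selection.

    Forward steps add the channel that most increases the objective
    (ties: lowest index); after each accepted addition, floating
    backward steps remove any channel whose removal strictly increases
    the objective.  The search stops at ``max_size`` channels or when no
    addition improves the objective, so the accepted-objective sequence
    is non-decreasing.
    """
    if len(channel_features) < 2:
        raise ValueError("SFFS needs at least 2 candidate channels")
    oof = oof_score_matrices(channel_features, labels, groups, folds, seed,
                             svm_params)
    n = len(oof)
    selected: list[int] = []
    current = -np.inf
    history: list[tuple[str, int, float]] = []
    while len(selected) < max_size:
        candidates = [j for j in range(n) if j not in selected]
        if not candidates:
            break
        objs = [subset_objective(oof, labels, selected + [j])
                for j in candidates]
        best = int(np.argmax(objs))      # first max -> lowest channel index
        if objs[best] <= current:
            break
        selected.append(candidates[best])
        current = objs[best]
        history.append(("add", candidates[best], current))
        # floating backward steps
        improved = True
        while improved and len(selected) > 2:
            improved = False
            drop_objs = [subset_objective(
                oof, labels, [c for c in selected if c != j])
                for j in selected]
            k = int(np.argmax(drop_objs))
            if drop_objs[k] > current:
                removed = selected.pop(k)
                current = drop_objs[k]
                history.append(("remove", removed, current))
                improved = True
    return SffsState(tuple(selected), current, history)
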