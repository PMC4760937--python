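"""Cross-validation protocols and the end-to-end experiment runner.

Folding is performed at *image level*: all subwindows sharing a
parent_id land in the same fold, so a classifier is never tested on
tiles of an acquisition it trained on.  Supported protocols:

* ``kfold_image(k)``      — k folds over parent images (default k=10);
* ``leave_one_image_out`` — one fold per parent image;
* ``kfold_plain(k)``      — k folds over rows, ignoring parentage.

The runner extracts every channel of the requested ensemble for every
image (cached per image), trains one SVM per channel inside each fold,
fuses the test scores by sum rule, and reports pooled and per-fold
one-vs-all AUC in percent.
"""

from __future__ import annotations

import logging
import re
import time
from dataclasses import dataclass, field

import numpy as np

from .classify import auc_one_vs_all, channel_scores, sum_rule, train_channel
from .ensembles import extract_channels, load_rgb, parse_config
from .imgio import DatasetManifest, load_gray
from .quinary import CIRCLE_ONLY

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldPlan:
    protocol: str
    row_folds: np.ndarray          # fold index per manifest row
    n_folds: int
    seed: int

    def split(self, f: int) -> tuple[np.ndarray, np.ndarray]:
        te = self.row_folds == f
        return ~te, te


def _parse_protocol(protocol: str) -> tuple[str, int | None]:
    protocol = protocol.strip()
    if protocol in ("leave_one_image_out", "loio"):
        return "leave_one_image_out", None
    m = re.match(r"^(kfold_image|kfold_plain)\((\d+)\)$", protocol)
    if m:
        return m.group(1), int(m.group(2))
    raise ValueError(
        f"unknown protocol {protocol!r}; use 'kfold_image(k)', "
        "'kfold_plain(k)' or 'leave_one_image_out'")


def make_folds(manifest: DatasetManifest, protocol: str, seed: int = 0,
               labels: np.ndarray | None = None) -> FoldPlan:
    """Build a fold plan; image-level protocols never split a parent_id.

    ``kfold_plain`` stratifies by class when ``labels`` are provided (the
    usual convention for row-level classification CV).
    """
    kind, k = _parse_protocol(protocol)
    parents = manifest.parent_ids
    if kind == "kfold_plain":
        n = len(manifest)
        if n < k:
            raise ValueError(f"{n} rows cannot fill {k} folds")
        row_folds = np.empty(n, dtype=int)
        if labels is not None:
            from sklearn.model_selection import StratifiedKFold
            skf = StratifiedKFold(k, shuffle=True, random_state=seed)
            for f, (_, te) in enumerate(skf.split(row_folds, labels)):
                row_folds[te] = f
        else:
            order = np.random.default_rng(seed).permutation(n)
            row_folds[order] = np.arange(n) % k
        return FoldPlan(protocol, row_folds, k, seed)
    uniq = sorted(set(parents))
    if kind == "leave_one_image_out":
        fold_of = {p: i for i, p in enumerate(uniq)}
        k = len(uniq)
    else:
        if len(uniq) < k:
            raise ValueError(f"{len(uniq)} parent images cannot fill {k} "
                             "image-level folds")
        order = np.random.default_rng(seed).permutation(len(uniq))
        fold_of = {uniq[idx]: i % k for i, idx in enumerate(order)}
    row_folds = np.array([fold_of[p] for p in parents])
    return FoldPlan(protocol, row_folds, k, seed)


@dataclass
class EvalResult:
    ensemble_name: str
    protocol: str
    auc_mean: float                      # pooled over folds, percent
    per_class_auc: dict
    per_fold_auc: list[float]
    fold_auc_mean: float
    n_channels: int
    n_samples: int
    seed: int
    pooled_scores: np.ndarray = field(repr=False, default=None)
    channel_tags: list[str] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "ensemble": self.ensemble_name,
            "protocol": self.protocol,
            "auc_mean": self.auc_mean,
            "per_class_auc": {k: (None if np.isnan(v) else float(v))
                              for k, v in self.per_class_auc.items()},
            "per_fold_auc": [float(a) for a in self.per_fold_auc],
            "fold_auc_mean": self.fold_auc_mean,
            "n_channels": self.n_channels,
            "n_samples": self.n_samples,
            "seed": self.seed,
        }


def extract_dataset_features(manifest: DatasetManifest, config: str,
                             mlqp_loci=CIRCLE_ONLY,
                             ) -> tuple[list[str], dict[str, np.ndarray]]:
    """Per-channel feature matrices for every image of a manifest.

    Returns ``(tags, {tag: (n_samples, dim) matrix})``; channel tags are
    identical across images because extraction is deterministic.
    """
    needs_rgb = "COLORS" in parse_config(config)
    tags: list[str] | None = None
    rows: list[list[np.ndarray]] = []
    for path in manifest.files:
        gray = load_gray(path)
        rgb = load_rgb(path) if needs_rgb else None
        channels = extract_channels(config, gray, rgb, mlqp_loci)
        if tags is None:
            tags = [t for t, _ in channels]
        elif tags != [t for t, _ in channels]:
            raise RuntimeError("channel tags differ across images")
        rows.append([v for _, v in channels])
    feats = {tag: np.array([row[i] for row in rows], dtype=np.float64)
             for i, tag in enumerate(tags)}
    return tags, feats


def run_experiment(manifest: DatasetManifest, ensemble_config: str,
                   protocol: str = "kfold_image(10)", seed: int = 0,
                   mlqp_loci=CIRCLE_ONLY,
                   labels_override: np.ndarray | None = None,
                   svm_grid: list[dict] | None = None) -> EvalResult:
    """Run one ensemble configuration under a cross-validation protocol.

    Per fold, every channel's scaler+SVM is fitted on the training rows
    only and scored on the test rows; the channels' row-stochastic score
    matrices are fused by sum rule.  Test scores from all folds are
    pooled for the primary AUC; per-fold AUCs are also reported.
    ``labels_override`` substitutes the manifest labels (used for
    permutation-null checks).
    """
    labels = np.asarray(labels_override if labels_override is not None
                        else manifest.labels)
    classes = np.array(sorted(set(labels)))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    tags, feats = extract_dataset_features(manifest, ensemble_config,
                                           mlqp_loci)
    plan = make_folds(manifest, protocol, seed, labels=labels)
    pooled = np.zeros((len(manifest), len(classes)))
    per_fold_auc = []
    for f in range(plan.n_folds):
        t0 = time.time()
        tr, te = plan.split(f)
        if len(np.unique(labels[tr])) < 2:
            raise ValueError(f"fold {f} leaves fewer than 2 training classes")
        fold_scores = []
        for tag in tags:
            model = train_channel(feats[tag][tr], labels[tr], seed=seed,
                                  tag=tag, grid=svm_grid)
            scores = channel_scores(model, feats[tag][te])
            if model.classes != tuple(classes):
                # a class absent from this training fold scores zero
                expanded = np.zeros((scores.shape[0], len(classes)))
                for j, cls in enumerate(model.classes):
                    expanded[:, list(classes).index(cls)] = scores[:, j]
                scores = expanded
            fold_scores.append(scores)
        fused = sum_rule(fold_scores)
        pooled[te] = fused
        if len(np.unique(labels[te])) >= 2:
            per_fold_auc.append(auc_one_vs_all(fused, labels[te], classes)[0])
        logger.info("fold %d/%d: %d channels in %.1fs", f + 1, plan.n_folds,
                    len(tags), time.time() - t0)
    auc_mean, per_class = auc_one_vs_all(pooled, labels, classes)
    return EvalResult(
        ensemble_name=ensemble_config,
        protocol=protocol,
        auc_mean=auc_mean,
        per_class_auc=dict(zip([str(c) for c in classes], per_class)),
        per_fold_auc=per_fold_auc,
        fold_auc_mean=float(np.mean(per_fold_auc)) if per_fold_auc
        else float("nan"),
        n_channels=len(tags),
        n_samples=len(manifest),
        seed=seed,
        pooled_scores=pooled,
        channel_tags=tags,
    )
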