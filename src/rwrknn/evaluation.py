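"""Cross-validation over positive samples and the reported metrics.

Cross-validation follows link-prediction practice: only *positive* pairs are
folded. Under LOOCV each known association is held out in turn; under k-fold
CV the positives are shuffled once and split into near-equal parts. The
balanced negative sample is, by default, split into folds alongside the
positives so held-out positives are scored against an equally-sized disjoint
negative set; the alternative ``paper_faithful`` protocol scores held-out
positives against every unknown pair.

Features can be built once from the full association matrix (the default,
matching how the method was originally evaluated) or rebuilt per fold with
the held-out associations zeroed (``recompute_profiles=True``), which removes
the information leak from GIP profiles and functional similarity.

Pooled held-out scores yield ROC/AUC, PR/AUPR and, at a fixed score
threshold, ACC / F1 / MCC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn import metrics as _skm

from .core_data import AssociationMatrix, DiseaseDAG
from .pipeline import PipelineParams, build_features
from .predictor import build_pair_features, knn_fit_predict, sample_negatives

__all__ = [
    "CVConfig",
    "MetricReport",
    "make_folds",
    "run_cv",
    "roc_auc",
    "pr_aupr",
    "threshold_metrics",
]


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation scheme and protocol choices.

    scheme: ``"loocv"`` or ``"kfold"``; ``folds`` applies to kfold only.
    ``recompute_profiles`` rebuilds features per fold with test associations
    masked (leakage-free mode). ``protocol`` picks the test negatives:
    ``"heldout_negatives"`` (default; negatives folded alongside positives)
    or ``"paper_faithful"`` (all unknown pairs). ``threshold`` is the score
    cut for ACC/F1/MCC.
    """

    scheme: str = "kfold"
    folds: int = 5
    shuffle_seed: int = 0
    recompute_profiles: bool = False
    protocol: str = "heldout_negatives"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.scheme not in ("loocv", "kfold"):
            raise ValueError(f"scheme must be 'loocv' or 'kfold', got {self.scheme!r}")
        if self.scheme == "kfold" and self.folds < 2:
            raise ValueError(f"kfold needs folds >= 2, got {self.folds}")
        if self.protocol not in ("heldout_negatives", "paper_faithful"):
            raise ValueError(f"unknown protocol {self.protocol!r}")


@dataclass(frozen=True)
class MetricReport:
    """Pooled held-out scores with their labels and derived metrics."""

    auc: float
    aupr: float
    acc: float
    f1: float
    mcc: float
    roc_points: list[tuple[float, float]]
    pr_points: list[tuple[float, float]]
    scores: np.ndarray = field(repr=False)
    labels: np.ndarray = field(repr=False)
    fold_sizes: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "aupr": self.aupr,
            "acc": self.acc,
            "f1": self.f1,
            "mcc": self.mcc,
            "n_test": int(len(self.labels)),
            "fold_sizes": list(self.fold_sizes),
        }


def make_folds(positives: list, config: CVConfig) -> list[tuple[list, list]]:
    """Partition items into (train, test) splits.

    LOOCV yields one split per item with a singleton test set. k-fold
    shuffles once with ``shuffle_seed`` and splits into ``folds`` parts whose
    sizes differ by at most one (larger parts first).
    """
    n = len(positives)
    if config.scheme == "loocv":
        n_folds = n
    else:
        n_folds = config.folds
        if n_folds > n:
            raise ValueError(f"cannot split {n} samples into {n_folds} folds")
    rng = np.random.default_rng(config.shuffle_seed)
    order = rng.permutation(n)
    parts = np.array_split(order, n_folds)
    splits = []
    for i, part in enumerate(parts):
        test = [positives[j] for j in part]
        train_idx = np.concatenate([p for j, p in enumerate(parts) if j != i])
        train = [positives[j] for j in train_idx]
        splits.append((train, test))
    return splits


def roc_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, list[tuple[float, float]]]:
    """ROC curve and AUC (trapezoidal; tie handling equals the rank-averaged
    Mann-Whitney statistic). Requires both classes."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present in labels")
    fpr, tpr, _ = _skm.roc_curve(labels, scores)
    auc = float(_skm.roc_auc_score(labels, scores))
    return auc, list(zip(fpr.tolist(), tpr.tolist()))


def pr_aupr(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, list[tuple[float, float]]]:
    """Precision-recall curve and AUPR by step-wise (average-precision)
    summation — no interpolation. Requires at least one positive."""
    labels = np.asarray(labels)
    if not (labels == 1).any():
        raise ValueError("AUPR undefined: no positive labels")
    precision, recall, _ = _skm.precision_recall_curve(labels, scores)
    aupr = float(_skm.average_precision_score(labels, scores))
    return aupr, list(zip(recall.tolist(), precision.tolist()))


def threshold_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> tuple[float, float, float]:
    """ACC, F1 and MCC of the binarised scores (score >= threshold is a
    predicted positive). F1 and MCC are 0 when their denominator vanishes."""
    labels = np.asarray(labels)
    predicted = (np.asarray(scores) >= threshold).astype(int)
    acc = float(_skm.accuracy_score(labels, predicted))
    f1 = float(_skm.f1_score(labels, predicted, zero_division=0))
    mcc = float(_skm.matthews_corrcoef(labels, predicted))
    return acc, f1, mcc


def _unknown_pairs(assoc: AssociationMatrix) -> list[tuple[int, int]]:
    rows, cols = np.nonzero(assoc.values == 0)
    return list(zip(rows.tolist(), cols.tolist()))


def run_cv(
    assoc: AssociationMatrix,
    dags: dict[str, DiseaseDAG],
    params: PipelineParams | None = None,
    config: CVConfig | None = None,
    negative_seed: int = 0,
) -> MetricReport:
    """Cross-validate the full pipeline and return pooled metrics.

    Positives (and, in the default protocol, the balanced negatives) are
    folded; every fold trains a KNN regressor on its training positives plus
    training negatives and scores the held-out pairs. Deterministic given
    ``negative_seed`` and ``config.shuffle_seed``.
    """
    params = params or PipelineParams()
    config = config or CVConfig()
    positives = assoc.positive_pairs()
    negatives = sample_negatives(assoc, negative_seed)
    pos_splits = make_folds(positives, config)

    if config.protocol == "heldout_negatives":
        neg_splits = make_folds(negatives, config)
    else:
        unknown = _unknown_pairs(assoc)
        neg_splits = [(negatives, unknown)] * len(pos_splits)

    if not config.recompute_profiles:
        state = build_features(assoc, dags, params)

    all_scores: list[np.ndarray] = []
    all_labels: list[np.ndarray] = []
    fold_sizes: list[int] = []
    for (train_pos, test_pos), (train_neg, test_neg) in zip(pos_splits, neg_splits):
        if config.recompute_profiles:
            masked = assoc.values.copy()
            for ci, di in test_pos:
                masked[ci, di] = 0
            fold_assoc = AssociationMatrix(
                masked, assoc.circ_registry, assoc.disease_registry
            )
            state = build_features(fold_assoc, dags, params)
        train_pairs = list(train_pos) + list(train_neg)
        train_labels = [1] * len(train_pos) + [0] * len(train_neg)
        train_samples = build_pair_features(
            state.wsd, state.wsc, train_pairs, train_labels
        )
        test_pairs = list(test_pos) + list(test_neg)
        test_labels = np.array([1] * len(test_pos) + [0] * len(test_neg))
        test_samples = build_pair_features(
            state.wsd, state.wsc, test_pairs, [0] * len(test_pairs)
        )
        test_matrix = np.vstack([s.features for s in test_samples])
        scores = knn_fit_predict(train_samples, test_matrix, params.knn)
        all_scores.append(scores)
        all_labels.append(test_labels)
        fold_sizes.append(len(test_pos))

    scores = np.concatenate(all_scores)
    labels = np.concatenate(all_labels)
    auc, roc_points = roc_auc(scores, labels)
    aupr, pr_points = pr_aupr(scores, labels)
    acc, f1, mcc = threshold_metrics(scores, labels, config.threshold)
    return MetricReport(
        auc=auc,
        aupr=aupr,
        acc=acc,
        f1=f1,
        mcc=mcc,
        roc_points=roc_points,
        pr_points=pr_points,
        scores=scores,
        labels=labels,
        fold_sizes=tuple(fold_sizes),
    )
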