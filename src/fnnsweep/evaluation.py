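"""Rank-based AUC, stratified 5-fold cross-validation and the overfitting statistic.

The overfitting statistic is the relative train/test AUC gap

    percent_AUC_diff = (mean_train_AUC - mean_test_AUC) / mean_test_AUC

over the five folds; a model is flagged as overfitted when it exceeds a
threshold (5% by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .fnn import HyperParams, train, predict

OVERFIT_THRESHOLD = 0.05


class UndefinedAUCError(ValueError):
    """AUC is undefined when only one class is present."""


class StratificationError(ValueError):
    """A class has fewer members than folds."""


@dataclass
class CVSplit:
    fold_ids: np.ndarray  # length-n vector of fold ids 0..k-1
    k: int = 5

    def test_indices(self, fold: int) -> np.ndarray:
        return np.where(self.fold_ids == fold)[0]

    def train_indices(self, fold: int) -> np.ndarray:
        return np.where(self.fold_ids != fold)[0]


@dataclass
class CVResult:
    """Per-fold and mean train/test AUCs plus percent_AUC_diff for one setting."""

    fold_train_auc: list[float]
    fold_test_auc: list[float]
    mean_train_auc: float = field(init=False)
    mean_test_auc: float = field(init=False)
    percent_auc_diff: float = field(init=False)
    overfit_flag: bool = field(init=False)
    threshold: float = OVERFIT_THRESHOLD

    def __post_init__(self):
        self.mean_train_auc = float(np.mean(self.fold_train_auc))
        self.mean_test_auc = float(np.mean(self.fold_test_auc))
        self.percent_auc_diff = percent_auc_diff(self.mean_train_auc, self.mean_test_auc)
        self.overfit_flag = self.percent_auc_diff > self.threshold


def roc_auc(labels, scores) -> float:
    """Area under the ROC curve via the Mann-Whitney statistic with midranks.

    Equals the probability that a random positive outscores a random
    negative, counting ties as 1/2; O(n log n) through a single ranking.
    """
    y = np.asarray(labels).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if y.shape != s.shape:
        raise ValueError(f"labels length {y.size} != scores length {s.size}")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedAUCError("AUC undefined: labels contain a single class")
    ranks = rankdata(s)  # midranks
    rank_sum_pos = float(np.sum(ranks[y == 1]))
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> CVSplit:
    """Seeded within-class shuffle + round-robin fold assignment.

    Guarantees each fold's positive and negative counts are within +-1 of
    n_class/k, mirroring a split where each fraction of the cohort is
    accurately represented.
    """
    y = np.asarray(labels).ravel()
    rng = np.random.default_rng(seed)
    fold_ids = np.full(y.shape[0], -1, dtype=int)
    for cls in np.unique(y):
        idx = np.where(y == cls)[0]
        if idx.size < k:
            raise StratificationError(
                f"class {cls} has {idx.size} members, fewer than k={k}")
        idx = rng.permutation(idx)
        fold_ids[idx] = np.arange(idx.size) % k
    return CVSplit(fold_ids, k)


def percent_auc_diff(mean_train_auc: float, mean_test_auc: float) -> float:
    """(mean_train_AUC - mean_test_AUC) / mean_test_AUC; may be negative."""
    if mean_test_auc <= 0:
        raise ValueError(f"mean_test_AUC must be positive, got {mean_test_auc}")
    return (mean_train_auc - mean_test_auc) / mean_test_auc


def fold_seed(seed: int, fold: int) -> int:
    """Deterministic per-fold sub-seed: seed*1000 + fold index."""
    return seed * 1000 + fold


def evaluate_cv(dataset, hp: HyperParams, seed: int, k: int = 5,
                threshold: float = OVERFIT_THRESHOLD,
                trainer=None) -> CVResult:
    """Stratified k-fold CV of one hyperparameter setting.

    Trains one network per held-out fold (fold sub-seeds derived from
    ``seed``); the train AUC of a fold is computed on the concatenated k-1
    training folds after training completes.  ``trainer`` may override the
    default train/predict pair (signature (X_tr, y_tr, X_ev, hp, sub_seed)
    -> scores for X_ev) — used for stubbing in tests.
    """
    X, y = dataset.features, dataset.labels
    split = stratified_kfold(y, k=k, seed=seed)
    fold_train, fold_test = [], []
    for fold in range(k):
        tr, te = split.train_indices(fold), split.test_indices(fold)
        sub = fold_seed(seed, fold)
        try:
            if trainer is not None:
                s_tr = trainer(X[tr], y[tr], X[tr], hp, sub)
                s_te = trainer(X[tr], y[tr], X[te], hp, sub)
            else:
                params, _ = train(X[tr], y[tr], hp, sub)
                s_tr = predict(params, X[tr], hp)
                s_te = predict(params, X[te], hp)
        except ArithmeticError as e:
            raise type(e)(f"fold {fold}: {e}") from None
        fold_train.append(roc_auc(y[tr], s_tr))
        fold_test.append(roc_auc(y[te], s_te))
    return CVResult(fold_train, fold_test, threshold=threshold)
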