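"""Training and evaluation of the two xenomiR classifiers.

The protocol: a random 15% of the positives (and an equal number of
negatives) is held out as the test set; the remaining training positives
are oversampled with replacement — every positive at least once — until
they match the training-negative count; a random forest (501 trees, 6
candidate features per split) is trained on the 105 numeric sequence
features and the convolutional network on the 72-bit one-hot encodings.
Cross-validation is stratified and oversampling happens strictly inside
each fold, after the validation fold is removed, so no validation sample
is ever duplicated into training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.ensemble._forest import _generate_unsampled_indices
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .cnn import CNNClassifier, CNNConfig
from .datasets import LabeledDataset
from .features import MODEL_FEATURE_NAMES, encode_records, feature_matrix


@dataclass
class RFConfig:
    """Random-forest hyperparameters (501 trees, 6 candidates per split)."""

    n_trees: int = 501
    candidates_per_split: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 1 <= self.candidates_per_split <= len(MODEL_FEATURE_NAMES):
            raise ValueError("candidates_per_split out of range")


@dataclass(frozen=True)
class TrainTestSplit:
    """Id lists of the stratified hold-out split."""

    train_pos: list[str]
    train_neg: list[str]
    test_pos: list[str]
    test_neg: list[str]
    seed: int


@dataclass(frozen=True)
class EvalMetrics:
    """Confusion counts plus SN/SP/ACC/MCC/AUC and the ROC polyline."""

    tp: int
    fn: int
    tn: int
    fp: int
    sn: float
    sp: float
    acc: float
    mcc: float
    auc: float
    roc: list[tuple[float, float]]

    def as_dict(self) -> dict[str, float]:
        return {"sn": self.sn, "sp": self.sp, "acc": self.acc,
                "mcc": self.mcc, "auc": self.auc}


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_train_test(dataset: LabeledDataset, test_pos_frac: float = 0.15,
                     seed: int = 0) -> TrainTestSplit:
    """Hold out round(frac*P) positives and the same number of negatives.

    Samples are drawn uniformly without replacement; everything else forms
    the training set.
    """
    if not 0 < test_pos_frac < 1:
        raise ValueError("test_pos_frac must be in (0, 1)")
    pos_ids = [r.id for r in dataset.positives]
    neg_ids = [r.id for r in dataset.negatives]
    n_test = _round_half_up(test_pos_frac * len(pos_ids))
    if n_test < 1 or len(pos_ids) < 2:
        raise ValueError("too few positives to split")
    if len(neg_ids) < n_test:
        raise ValueError("fewer negatives than the test size")
    rng = np.random.default_rng(seed)
    test_pos = sorted(rng.choice(pos_ids, size=n_test, replace=False))
    test_neg = sorted(rng.choice(neg_ids, size=n_test, replace=False))
    return TrainTestSplit(
        train_pos=[i for i in pos_ids if i not in set(test_pos)],
        train_neg=[i for i in neg_ids if i not in set(test_neg)],
        test_pos=list(test_pos), test_neg=list(test_neg), seed=seed,
    )


def oversample_positives(train_pos_ids: list[str], n_target: int,
                         seed: int = 0) -> list[str]:
    """Extend the positive ids to ``n_target`` by sampling with replacement.

    Every input id appears at least once: the multiset is one copy of each
    id plus ``n_target - P`` uniform draws.
    """
    p = len(train_pos_ids)
    if p < 1:
        raise ValueError("no positive ids to oversample")
    if n_target < p:
        raise ValueError(f"n_target {n_target} < number of positives {p}")
    rng = np.random.default_rng(seed)
    extra = list(rng.choice(train_pos_ids, size=n_target - p, replace=True))
    return list(train_pos_ids) + extra


def train_random_forest(features: pd.DataFrame | np.ndarray,
                        labels: np.ndarray,
                        config: RFConfig | None = None
                        ) -> RandomForestClassifier:
    """Fit the Gini random forest on the 105-feature schema."""
    config = config or RFConfig()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    if X.shape[1] != len(MODEL_FEATURE_NAMES):
        raise ValueError(
            f"expected {len(MODEL_FEATURE_NAMES)} features, got {X.shape[1]}")
    if len(np.unique(y)) < 2:
        raise ValueError("labels contain a single class")
    model = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.candidates_per_split,
        criterion="gini",
        random_state=config.seed,
        n_jobs=1,
    )
    model.fit(X, y)
    return model


def train_cnn(encoded: np.ndarray, labels: np.ndarray,
              config: CNNConfig | None = None) -> CNNClassifier:
    """Fit the convolutional classifier on 72-bit one-hot encodings."""
    model = CNNClassifier(config)
    model.fit(encoded, np.asarray(labels, dtype=int))
    return model


def metrics_from_confusion(tp: int, fn: int, tn: int, fp: int,
                           auc: float = float("nan"),
                           roc: list | None = None) -> EvalMetrics:
    """SN/SP/ACC/MCC from confusion counts (MCC = 0 on zero denominator)."""
    total = tp + fn + tn + fp
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / total if total else 0.0
    denom = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    return EvalMetrics(tp, fn, tn, fp, sn, sp, acc, mcc, auc, roc or [])


def evaluate(scores: np.ndarray, labels: np.ndarray,
             threshold: float = 0.5) -> EvalMetrics:
    """Threshold scores at 0.5 and report SN/SP/ACC/MCC/AUC + ROC points.

    AUC is the rank (Mann-Whitney) statistic; ROC points are
    (1 - SP, SN) over all score thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
    calls = scores >= threshold
    tp = int(np.sum(calls & (labels == 1)))
    fn = int(np.sum(~calls & (labels == 1)))
    tn = int(np.sum(~calls & (labels == 0)))
    fp = int(np.sum(calls & (labels == 0)))
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, _ = roc_curve(labels, scores)
    return metrics_from_confusion(tp, fn, tn, fp, auc,
                                  list(zip(fpr.tolist(), tpr.tolist())))


@dataclass
class CVResult:
    """Per-fold metrics for one model plus their scalar means."""

    folds: list[EvalMetrics]

    @property
    def mean(self) -> dict[str, float]:
        keys = ("sn", "sp", "acc", "mcc", "auc")
        return {k: float(np.mean([getattr(f, k) for f in self.folds]))
                for k in keys}


def oversampled_folds(y: np.ndarray, folds: int, seed: int = 0):
    """Yield (balanced_train_indices, validation_indices) per CV fold.

    Folds are stratified by class; the validation fold is removed first
    and only then are the fold's training positives oversampled (every
    one kept, extras drawn with replacement) to the training-negative
    count.  Validation indices therefore never occur in the balanced
    training multiset.
    """
    y = np.asarray(y, dtype=int)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > min(np.bincount(y)):
        raise ValueError("more folds than members of the smaller class")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for fold_i, (train_idx, val_idx) in enumerate(
            skf.split(np.zeros((len(y), 1)), y)):
        train_pos = train_idx[y[train_idx] == 1]
        train_neg = train_idx[y[train_idx] == 0]
        rng = np.random.default_rng(seed + 1000 * (fold_i + 1))
        extra = rng.choice(train_pos, size=len(train_neg) - len(train_pos),
                           replace=True)
        yield np.concatenate([train_pos, extra, train_neg]), val_idx


def cross_validate(dataset: LabeledDataset, folds: int = 5,
                   rf: RFConfig | None = None,
                   cnn: CNNConfig | None = None,
                   seed: int = 0) -> dict[str, CVResult]:
    """Stratified k-fold CV with oversampling confined to training folds.

    Within each fold the validation part is removed first and only then
    are the training positives oversampled to the training-negative
    count, so validation samples are never duplicated into training.
    """
    rf = rf or RFConfig(seed=seed)
    cnn = cnn or CNNConfig(seed=seed)
    records = dataset.all_records
    y = np.array([1 if r.label == "positive" else 0 for r in records])
    X_feat = feature_matrix(records).to_numpy()
    X_enc = encode_records(records)
    results: dict[str, list[EvalMetrics]] = {"rf": [], "cnn": []}
    for fold_i, (balanced, val_idx) in enumerate(
            oversampled_folds(y, folds, seed)):
        assert not set(balanced) & set(val_idx)
        yb = y[balanced]
        rf_model = train_random_forest(
            X_feat[balanced], yb,
            RFConfig(rf.n_trees, rf.candidates_per_split,
                     seed=rf.seed + fold_i))
        cnn_cfg = CNNConfig(cnn.conv_channels, cnn.conv_kernels,
                            cnn.dense_units, cnn.dropout_rate, cnn.l2_lambda,
                            cnn.epochs, cnn.batch_size, cnn.learning_rate,
                            seed=cnn.seed + fold_i)
        cnn_model = train_cnn(X_enc[balanced], yb, cnn_cfg)
        results["rf"].append(
            evaluate(rf_model.predict_proba(X_feat[val_idx])[:, 1], y[val_idx]))
        results["cnn"].append(
            evaluate(cnn_model.decision_scores(X_enc[val_idx]), y[val_idx]))
    return {name: CVResult(f) for name, f in results.items()}


@dataclass
class ImportanceTable:
    """Random-forest feature importances under both criteria.

    ``table`` has columns mean_decrease_accuracy, mean_decrease_gini,
    top10_accuracy, top10_gini, indexed by feature name.  The top-10% sets
    each contain ceil(0.10 * n_features) features.
    """

    table: pd.DataFrame

    def top_features(self, criterion: str = "gini") -> list[str]:
        flag = f"top10_{criterion}"
        sub = self.table[self.table[flag]]
        col = ("mean_decrease_gini" if criterion == "gini"
               else "mean_decrease_accuracy")
        return list(sub.sort_values(col, ascending=False).index)


def _oob_indices(model: RandomForestClassifier, n: int):
    for tree in model.estimators_:
        yield _generate_unsampled_indices(tree.random_state, n, n, None)


def rf_importance(model: RandomForestClassifier,
                  features: pd.DataFrame | np.ndarray,
                  labels: np.ndarray,
                  n_repeats: int = 10, seed: int = 0) -> ImportanceTable:
    """Mean decrease Gini and out-of-bag permutation (accuracy) importance.

    Mean decrease accuracy: for each tree, accuracy on its out-of-bag
    samples minus accuracy after permuting one feature within those
    samples, averaged over trees and ``n_repeats`` permutations.
    """
    if not hasattr(model, "estimators_"):
        raise ValueError("model is not a trained random forest")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    names = (list(features.columns) if isinstance(features, pd.DataFrame)
             else list(MODEL_FEATURE_NAMES))
    n, p = X.shape
    gini = model.feature_importances_
    rng = np.random.default_rng(seed)
    drops = np.zeros(p)
    counts = 0
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    for tree, oob in zip(model.estimators_, _oob_indices(model, n)):
        if len(oob) == 0:
            continue
        Xo = np.ascontiguousarray(X32[oob])
        yo = y[oob]
        # check_input=False skips sklearn validation in the hot loop
        base = np.mean(tree.predict(Xo, check_input=False) == yo)
        counts += 1
        for j in range(p):
            orig = Xo[:, j].copy()
            drop_j = 0.0
            for _ in range(n_repeats):
                Xo[:, j] = orig[rng.permutation(len(oob))]
                drop_j += base - np.mean(
                    tree.predict(Xo, check_input=False) == yo)
            Xo[:, j] = orig
            drops[j] += drop_j / n_repeats
    mda = drops / max(counts, 1)
    k = math.ceil(0.10 * p)
    top_gini = set(np.argsort(gini)[::-1][:k])
    top_mda = set(np.argsort(mda)[::-1][:k])
    table = pd.DataFrame({
        "mean_decrease_accuracy": mda,
        "mean_decrease_gini": gini,
        "top10_accuracy": [i in top_mda for i in range(p)],
        "top10_gini": [i in top_gini for i in range(p)],
    }, index=names)
    return ImportanceTable(table)
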