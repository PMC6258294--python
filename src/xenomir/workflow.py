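"""End-to-end orchestration of the two analysis runs.

``run_statistics`` produces the descriptive report bundle (feature
matrix, per-feature screen, positional composition, LD1 scores and
compactness test, optional family summary).  ``run_full`` runs the
modelling pipeline: hold-out split -> oversampling -> RF + CNN training
-> held-out evaluation -> stratified cross-validation -> RF importance ->
consensus prediction on the unlabeled pool.  Every run writes a manifest
recording the seed and input content hashes so reruns are reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import (CVResult, EvalMetrics, RFConfig, cross_validate,
                       evaluate, oversample_positives, rf_importance,
                       split_train_test, train_cnn, train_random_forest)
from .cnn import CNNConfig
from .consensus import predict_consensus, venn_counts
from .datasets import LabeledDataset, MiRNARecord, deduplicate, read_fasta, \
    read_sequence_table
from .features import encode_records, feature_matrix, feature_table
from .group_stats import (compare_feature_groups, comparison_table,
                          family_summary, lda_ld1, position_composition)
from .synthetic import SyntheticConfig, generate_dataset


@dataclass
class RunConfig:
    """One run: either real input paths or a synthetic recipe, never both."""

    positives_path: str | None = None
    negatives_path: str | None = None
    pool_path: str | None = None
    synthetic: SyntheticConfig | None = None
    test_pos_frac: float = 0.15
    folds: int = 5
    rf: RFConfig = field(default_factory=RFConfig)
    cnn: CNNConfig = field(default_factory=CNNConfig)
    alpha: float = 0.01
    threshold: float = 0.5
    out_dir: str = "xenomir-out"
    seed: int = 0

    def __post_init__(self) -> None:
        real = self.positives_path is not None
        if real == (self.synthetic is not None):
            raise ValueError(
                "exactly one of (real input paths, synthetic config) "
                "must be given")


def _read_any(path: str, label: str) -> list[MiRNARecord]:
    p = Path(path)
    if p.suffix.lower() in (".fa", ".fasta"):
        records, rejected = read_fasta(p, label)
        if rejected:
            raise ValueError(f"{path}: invalid records {rejected[:5]}")
        return records
    return read_sequence_table(p, label)


def load_inputs(config: RunConfig
                ) -> tuple[LabeledDataset, list[MiRNARecord], dict[str, bool]]:
    """Resolve the run inputs to (labeled dataset, pool, truth-or-empty)."""
    if config.synthetic is not None:
        return generate_dataset(config.synthetic)
    positives = deduplicate(_read_any(config.positives_path, "positive"))
    negatives = deduplicate(_read_any(config.negatives_path, "negative"))
    if not positives or not negatives:
        raise ValueError("empty positive or negative input")
    dataset = LabeledDataset(positives, negatives)
    pool: list[MiRNARecord] = []
    if config.pool_path:
        from .datasets import filter_unlabeled_pool
        pool = filter_unlabeled_pool(_read_any(config.pool_path, "unlabeled"),
                                     dataset)
    return dataset, pool, {}


def _hash_records(records: list[MiRNARecord]) -> str:
    h = hashlib.sha256()
    for r in records:
        h.update(f"{r.id}\t{r.sequence}\n".encode())
    return h.hexdigest()


def _manifest(config: RunConfig, dataset: LabeledDataset,
              pool: list[MiRNARecord]) -> dict:
    return {
        "xenomir_version": __version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "n_positives": len(dataset.positives),
        "n_negatives": len(dataset.negatives),
        "n_pool": len(pool),
        "hash_positives": _hash_records(dataset.positives),
        "hash_negatives": _hash_records(dataset.negatives),
        "hash_pool": _hash_records(pool),
        "synthetic": config.synthetic is not None,
    }


def run_statistics(config: RunConfig) -> dict:
    """Descriptive statistics bundle; returns the in-memory results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, pool, _ = load_inputs(config)
    pos_X = feature_matrix(dataset.positives)
    neg_X = feature_matrix(dataset.negatives)
    comparisons = compare_feature_groups(pos_X, neg_X, alpha=config.alpha)
    lda = lda_ld1(pos_X, neg_X)
    comp_pos = position_composition(dataset.positives)
    comp_neg = position_composition(dataset.negatives)

    feature_table(dataset.all_records).to_csv(out / "feature_table.csv")
    comparison_table(comparisons).to_csv(out / "feature_comparison.csv",
                                         index=False)
    comp_pos.to_frame().to_csv(out / "position_composition_pos.csv")
    comp_neg.to_frame().to_csv(out / "position_composition_neg.csv")
    pd.DataFrame({
        "ld1": np.concatenate([lda.ld1_pos, lda.ld1_neg]),
        "group": ["positive"] * len(lda.ld1_pos)
        + ["negative"] * len(lda.ld1_neg),
    }).to_csv(out / "ld1_scores.csv", index=False)
    manifest = _manifest(config, dataset, pool)
    manifest["n_significant"] = sum(c.significant for c in comparisons)
    manifest["compactness_t"] = lda.compactness_t
    manifest["compactness_p"] = lda.compactness_p
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"dataset": dataset, "comparisons": comparisons, "lda": lda,
            "composition": {"positive": comp_pos, "negative": comp_neg},
            "manifest": manifest}


def run_family_summary(records: list[MiRNARecord],
                       family_map: dict[str, int], out_dir: str) -> pd.DataFrame:
    df = family_summary(records, family_map)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df.to_csv(out / "family_summary.csv", index=False)
    return df


def run_full(config: RunConfig) -> dict:
    """The modelling run; returns models, metrics and consensus calls."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, pool, truth = load_inputs(config)

    records = {r.id: r for r in dataset.all_records}
    split = split_train_test(dataset, config.test_pos_frac, seed=config.seed)
    train_ids = oversample_positives(
        split.train_pos, len(split.train_neg), seed=config.seed
    ) + split.train_neg
    train_recs = [records[i] for i in train_ids]
    y_train = np.array([1 if r.label == "positive" else 0
                        for r in train_recs])
    test_recs = [records[i] for i in split.test_pos + split.test_neg]
    y_test = np.array([1 if r.label == "positive" else 0 for r in test_recs])

    rf_cfg = RFConfig(config.rf.n_trees, config.rf.candidates_per_split,
                      seed=config.seed)
    cnn_cfg = CNNConfig(config.cnn.conv_channels, config.cnn.conv_kernels,
                        config.cnn.dense_units, config.cnn.dropout_rate,
                        config.cnn.l2_lambda, config.cnn.epochs,
                        config.cnn.batch_size, config.cnn.learning_rate,
                        seed=config.seed)
    X_train = feature_matrix(train_recs)
    rf_model = train_random_forest(X_train, y_train, rf_cfg)
    cnn_model = train_cnn(encode_records(train_recs), y_train, cnn_cfg)

    X_test = feature_matrix(test_recs)
    rf_test = evaluate(rf_model.predict_proba(X_test.to_numpy())[:, 1],
                       y_test, config.threshold)
    cnn_test = evaluate(cnn_model.decision_scores(encode_records(test_recs)),
                        y_test, config.threshold)
    cv = cross_validate(dataset, folds=config.folds, rf=rf_cfg, cnn=cnn_cfg,
                        seed=config.seed)
    importance = rf_importance(rf_model, X_train, y_train, seed=config.seed)

    consensus = None
    if pool:
        consensus = predict_consensus(rf_model, cnn_model, pool,
                                      threshold=config.threshold)
        consensus.to_csv(out / "consensus_predictions.csv", index=False)

    rows = []
    for name, metrics in (("RF", rf_test), ("1D-CNN", cnn_test)):
        rows.append(("test", name, *metrics.as_dict().values()))
    for name, key in (("RF", "rf"), ("1D-CNN", "cnn")):
        rows.append(("cv-mean", name, *cv[key].mean.values()))
    metrics_df = pd.DataFrame(
        rows, columns=["set", "model", "sn", "sp", "acc", "mcc", "auc"])
    metrics_df.to_csv(out / "metrics.csv", index=False)
    importance.table.to_csv(out / "rf_importance.csv")
    pd.DataFrame(rf_test.roc, columns=["fpr", "tpr"]).to_csv(
        out / "roc_rf_test.csv", index=False)
    pd.DataFrame(cnn_test.roc, columns=["fpr", "tpr"]).to_csv(
        out / "roc_cnn_test.csv", index=False)

    manifest = _manifest(config, dataset, pool)
    manifest["split"] = {
        "train_pos": len(split.train_pos), "train_neg": len(split.train_neg),
        "test_pos": len(split.test_pos), "test_neg": len(split.test_neg),
    }
    manifest["test_metrics"] = {"rf": rf_test.as_dict(),
                                "cnn": cnn_test.as_dict()}
    manifest["cv_mean"] = {"rf": cv["rf"].mean, "cnn": cv["cnn"].mean}
    if consensus is not None:
        manifest["consensus"] = venn_counts(consensus)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return {"dataset": dataset, "pool": pool, "truth": truth, "split": split,
            "rf_model": rf_model, "cnn_model": cnn_model,
            "rf_test": rf_test, "cnn_test": cnn_test, "cv": cv,
            "importance": importance, "consensus": consensus,
            "manifest": manifest}
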