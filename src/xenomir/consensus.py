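"""Consensus nomination of candidate xenomiRs from an unlabeled pool.

Both trained models score every pool sequence; a candidate is nominated
only when the random forest and the convolutional network both call it
positive (set intersection — the conservative rule).
"""

from __future__ import annotations

import pandas as pd

from .datasets import MiRNARecord
from .features import encode_records, feature_matrix


def predict_consensus(rf_model, cnn_model, pool: list[MiRNARecord],
                      threshold: float = 0.5,
                      rf_threshold: float | None = None,
                      cnn_threshold: float | None = None) -> pd.DataFrame:
    """Score the pool with both models and intersect their positive calls.

    Returns a DataFrame with one row per pool record: id, sequence,
    rf_score, cnn_score, rf_call, cnn_call, consensus_call.  Per-model
    thresholds default to the shared ``threshold`` (0.5).
    """
    if not pool:
        raise ValueError("empty unlabeled pool")
    rf_thr = threshold if rf_threshold is None else rf_threshold
    cnn_thr = threshold if cnn_threshold is None else cnn_threshold
    X = feature_matrix(pool)
    rf_scores = rf_model.predict_proba(X.to_numpy())[:, 1]
    cnn_scores = cnn_model.decision_scores(encode_records(pool))
    df = pd.DataFrame({
        "id": [r.id for r in pool],
        "sequence": [r.sequence for r in pool],
        "rf_score": rf_scores,
        "cnn_score": cnn_scores,
    })
    df["rf_call"] = df["rf_score"] >= rf_thr
    df["cnn_call"] = df["cnn_score"] >= cnn_thr
    df["consensus_call"] = df["rf_call"] & df["cnn_call"]
    return df


def venn_counts(result: pd.DataFrame) -> dict[str, int]:
    """rf-only / cnn-only / both counts of the positive-call sets."""
    both = int(result["consensus_call"].sum())
    return {
        "rf_only": int(result["rf_call"].sum()) - both,
        "cnn_only": int(result["cnn_call"].sum()) - both,
        "both": both,
    }
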