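"""Group-wise statistics: feature screening, positional composition,
linear-discriminant separability and family summaries.

The feature screen runs a two-sided Wilcoxon rank-sum test per model
feature and controls the false discovery rate with Benjamini-Hochberg;
features with FDR below alpha (default 0.01) are flagged significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import MiRNARecord
from .features import N_POSITIONS, NUCLEOTIDES

#: group-size bound below which the exact rank-sum distribution is used
_EXACT_MAX_N = 25


@dataclass(frozen=True)
class FeatureComparison:
    """One row of the per-feature screening table."""

    feature: str
    p_value: float
    fdr: float
    mean_pos: float
    mean_neg: float
    significant: bool


@dataclass(frozen=True)
class PositionComposition:
    """Per-position nucleotide percentages for one sequence group.

    ``percent`` is a (24, 4) array (positions x ACGU) summing to 100 per
    row where ``counts`` (the per-position denominator: number of
    sequences at least that long) is nonzero; rows with zero denominator
    are NaN.
    """

    percent: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.percent, columns=list(NUCLEOTIDES),
                          index=pd.RangeIndex(1, N_POSITIONS + 1,
                                              name="position"))
        df["n"] = self.counts
        return df


@dataclass(frozen=True)
class LdaResult:
    """LD1 projections of both groups plus the compactness test."""

    ld1_pos: np.ndarray
    ld1_neg: np.ndarray
    compactness_t: float
    compactness_p: float


def position_composition(group: list[MiRNARecord]) -> PositionComposition:
    """Percentage of each nucleotide at positions 1..24 of a group."""
    if not group:
        raise ValueError("empty group")
    counts = np.zeros((N_POSITIONS, 4))
    idx = {nt: j for j, nt in enumerate(NUCLEOTIDES)}
    for rec in group:
        for i, nt in enumerate(rec.sequence[:N_POSITIONS]):
            counts[i, idx[nt]] += 1
    denom = counts.sum(axis=1)
    with np.errstate(invalid="ignore"):
        percent = np.where(denom[:, None] > 0,
                           100.0 * counts / np.where(denom[:, None] > 0,
                                                     denom[:, None], 1.0),
                           np.nan)
    return PositionComposition(percent, denom.astype(int))


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact distribution when both samples have <= 25 observations and no
    cross-sample ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    exact_ok = (len(x) <= _EXACT_MAX_N and len(y) <= _EXACT_MAX_N
                and len(np.unique(np.concatenate([x, y]))) == len(x) + len(y))
    method = "exact" if exact_ok else "asymptotic"
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method=method,
                                    use_continuity=True).pvalue)


def compare_feature_groups(pos_features: pd.DataFrame,
                           neg_features: pd.DataFrame,
                           alpha: float = 0.01) -> list[FeatureComparison]:
    """Per-feature Wilcoxon rank-sum screen with BH-FDR control.

    Both inputs must share the 105-feature model schema; the result is
    sorted by feature name.
    """
    if list(pos_features.columns) != list(neg_features.columns):
        raise ValueError("feature schemas differ between groups")
    if len(pos_features) < 2 or len(neg_features) < 2:
        raise ValueError("each group needs at least 2 samples")
    names = list(pos_features.columns)
    pvals = np.array([
        rank_sum_test(pos_features[c].to_numpy(), neg_features[c].to_numpy())
        for c in names
    ])
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    rows = [
        FeatureComparison(c, float(p), float(q),
                          float(pos_features[c].mean()),
                          float(neg_features[c].mean()),
                          bool(q < alpha))
        for c, p, q in zip(names, pvals, fdrs)
    ]
    return sorted(rows, key=lambda r: r.feature)


def comparison_table(rows: list[FeatureComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.feature, r.p_value, r.fdr, r.mean_pos, r.mean_neg, r.significant)
         for r in rows],
        columns=["feature", "p_value", "fdr", "mean_pos", "mean_neg",
                 "significant"],
    )


def _fisher_direction(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Fisher discriminant direction with a ridge-stabilized scatter.

    Features are standardized first; the within-class scatter of k-mer
    frequency features is rank-deficient (each k-mer family sums to 1), so
    a ridge term lambda = 1e-6 * trace(Sw)/p is added.
    """
    X = np.vstack([pos, neg])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    posz, negz = (pos - mu) / sd, (neg - mu) / sd
    d_pos = posz - posz.mean(axis=0)
    d_neg = negz - negz.mean(axis=0)
    sw = d_pos.T @ d_pos + d_neg.T @ d_neg
    p = sw.shape[0]
    lam = 1e-6 * np.trace(sw) / p
    sw_reg = sw + lam * np.eye(p)
    try:
        w = np.linalg.solve(sw_reg, posz.mean(axis=0) - negz.mean(axis=0))
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise np.linalg.LinAlgError(
            "within-class scatter singular after regularization") from exc
    # unit-norm direction: LD1 scale-free for plots; the compactness test
    # is invariant to this scaling.  Identical group means leave w = 0.
    norm = np.linalg.norm(w)
    return (w / norm if norm > 0 else w), mu, sd


def lda_ld1(pos_features: pd.DataFrame | np.ndarray,
            neg_features: pd.DataFrame | np.ndarray) -> LdaResult:
    """Project both groups onto the (single) Fisher discriminant axis.

    Orientation is fixed so mean(LD1 positives) > mean(LD1 negatives).
    The compactness test on within-group pairwise LD1 distances is run as
    part of the result; see :func:`ld1_compactness_test`.
    """
    pos = np.asarray(pos_features, dtype=float)
    neg = np.asarray(neg_features, dtype=float)
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("each group needs at least 2 samples")
    w, mu, sd = _fisher_direction(pos, neg)
    ld1_pos = ((pos - mu) / sd) @ w
    ld1_neg = ((neg - mu) / sd) @ w
    if ld1_pos.mean() < ld1_neg.mean():
        ld1_pos, ld1_neg = -ld1_pos, -ld1_neg
    t, p = _compactness(ld1_pos, ld1_neg)
    return LdaResult(ld1_pos, ld1_neg, t, p)


def _pairwise_distances(scores: np.ndarray) -> np.ndarray:
    s = np.asarray(scores, dtype=float)
    i, j = np.triu_indices(len(s), k=1)
    return np.abs(s[i] - s[j])


def _compactness(ld1_pos: np.ndarray, ld1_neg: np.ndarray):
    d_pos = _pairwise_distances(ld1_pos)
    d_neg = _pairwise_distances(ld1_neg)
    t, p = stats.ttest_ind(d_pos, d_neg, equal_var=False)
    return float(t), float(p)


def ld1_compactness_test(result: LdaResult) -> tuple[float, float]:
    """Welch t-test comparing within-group pairwise LD1 distances.

    A negative t statistic means the positive group is the more compact
    one (smaller mean pairwise distance).
    """
    if len(result.ld1_pos) < 2 or len(result.ld1_neg) < 2:
        raise ValueError("each group needs at least 2 LD1 scores")
    return _compactness(result.ld1_pos, result.ld1_neg)


def family_summary(records: list[MiRNARecord],
                   family_map: dict[str, int]) -> pd.DataFrame:
    """Per-family mapped counts and fractions (of total family size).

    ``family_map`` gives the number of members of each family in the
    reference registry; every family carried by a record must be present.
    """
    fams = [r.family for r in records if r.family is not None]
    missing = sorted({f for f in fams if f not in family_map})
    if missing:
        raise KeyError(f"families missing from map: {missing}")
    counts = pd.Series(fams, dtype=object).value_counts() if fams \
        else pd.Series(dtype=int)
    rows = [
        (fam, int(n), int(family_map[fam]), 100.0 * n / family_map[fam])
        for fam, n in counts.items()
    ]
    df = pd.DataFrame(rows, columns=["family", "n_mapped", "family_size",
                                     "percent_mapped"])
    return df.sort_values(["n_mapped", "family"],
                          ascending=[False, True]).reset_index(drop=True)
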