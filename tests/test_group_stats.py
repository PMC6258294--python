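from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from xenomir.datasets import MiRNARecord
from xenomir.features import MODEL_FEATURE_NAMES
from xenomir.group_stats import (LdaResult, compare_feature_groups,
                                 family_summary, ld1_compactness_test,
                                 lda_ld1, position_composition,
                                 rank_sum_test)


def rec(id_, seq, label="positive"):
    return MiRNARecord(id_, seq, label)


class TestPositionComposition:
    def test_two_sequences_hand_counted(self):
        group = [rec("a", "AA" + "G" * 13), rec("b", "AU" + "G" * 13)]
        comp = position_composition(group)
        frame = comp.to_frame()
        assert frame.loc[1, "A"] == 100.0
        assert frame.loc[2, "A"] == 50.0
        assert frame.loc[2, "U"] == 50.0

    def test_positions_beyond_length_have_zero_denominator(self):
        comp = position_composition([rec("a", "A" * 16)])
        assert comp.counts[15] == 1
        assert comp.counts[16] == 0
        assert np.isnan(comp.percent[16]).all()

    def test_three_sequences_hand_counted(self):
        group = [rec("a", "ACG" + "A" * 12), rec("b", "ACG" + "A" * 12 + "U"),
                 rec("c", "AUG" + "A" * 12)]
        frame = position_composition(group).to_frame()
        assert frame.loc[2, "C"] == pytest.approx(200 / 3)
        assert frame.loc[2, "U"] == pytest.approx(100 / 3)

    def test_rows_sum_to_100_where_defined(self):
        rng = np.random.default_rng(0)
        group = [rec(f"r{i}", "".join(rng.choice(list("ACGU"),
                                                 size=rng.integers(15, 25))))
                 for i in range(30)]
        comp = position_composition(group)
        defined = comp.counts > 0
        assert np.allclose(comp.percent[defined].sum(axis=1), 100.0)

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            position_composition([])


def exact_rank_sum_p(x, y):
    """Enumerate all group assignments of the pooled sample (tie-free)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n = len(x)
    w_obs = ranks[:n].sum()
    mid = n * (len(pooled) + 1) / 2
    hits = total = 0
    for subset in combinations(range(len(pooled)), n):
        w = ranks[list(subset)].sum()
        total += 1
        if abs(w - mid) >= abs(w_obs - mid) - 1e-9:
            hits += 1
    return hits / total


class TestRankSum:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exact_enumeration_small_groups(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(3, 9, size=2)
        x = rng.normal(size=n)
        y = rng.normal(loc=rng.uniform(0, 1.5), size=m)
        assert rank_sum_test(x, y) == pytest.approx(exact_rank_sum_p(x, y))

    def test_large_groups_use_tie_corrected_normal(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 5, size=60).astype(float)
        y = rng.integers(1, 6, size=80).astype(float)
        expect = stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method="asymptotic",
                                    use_continuity=True).pvalue
        assert rank_sum_test(x, y) == pytest.approx(float(expect))


class TestBenjaminiHochberg:
    def test_matches_hand_computation(self):
        # raw p * m/rank, then cumulative minimum from the largest rank
        pvals = [0.001, 0.008, 0.039, 0.041, 0.042]
        expected = [0.005, 0.02, 0.042, 0.042, 0.042]
        _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
        assert np.allclose(fdr, expected)

    def test_monotone_and_above_p(self):
        rng = np.random.default_rng(2)
        pvals = np.sort(rng.uniform(size=40))
        _, fdr, _, _ = multipletests(pvals, method="fdr_bh")
        assert np.all(fdr >= pvals)
        assert np.all(np.diff(fdr) >= -1e-12)


def _feature_frame(values: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(values, columns=MODEL_FEATURE_NAMES)


class TestCompareFeatureGroups:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(3)
        base = rng.random((10, 105))
        rows = compare_feature_groups(_feature_frame(base),
                                      _feature_frame(base.copy()))
        assert len(rows) == 105
        assert all(r.p_value == pytest.approx(1.0) for r in rows)
        assert not any(r.significant for r in rows)

    def test_single_planted_feature_hits_exact_extreme_tail(self):
        rng = np.random.default_rng(4)
        base = rng.random(105)
        pos = np.tile(base, (20, 1))
        neg = np.tile(base, (20, 1))
        jitter = np.linspace(0, 1e-6, 20)
        j = MODEL_FEATURE_NAMES.index("CAG")
        pos[:, j] = 1.0 + jitter     # fully separated, tie-free
        neg[:, j] = 0.0 + jitter
        rows = compare_feature_groups(_feature_frame(pos),
                                      _feature_frame(neg))
        by_name = {r.feature: r for r in rows}
        assert by_name["CAG"].p_value == pytest.approx(2 / comb(40, 20))
        assert [r.feature for r in rows if r.significant] == ["CAG"]
        assert by_name["CAG"].mean_pos > by_name["CAG"].mean_neg

    def test_schema_mismatch_is_an_error(self):
        a = _feature_frame(np.random.default_rng(0).random((5, 105)))
        b = a.rename(columns={"CAG": "GAC"})
        with pytest.raises(ValueError):
            compare_feature_groups(a, b)

    def test_sorted_by_feature_name(self):
        rng = np.random.default_rng(5)
        rows = compare_feature_groups(_feature_frame(rng.random((5, 105))),
                                      _feature_frame(rng.random((6, 105))))
        names = [r.feature for r in rows]
        assert names == sorted(names)


class TestLda:
    def _clouds(self, seed=0, n=40, p=8, delta=3.0):
        rng = np.random.default_rng(seed)
        direction = rng.normal(size=p)
        direction /= np.linalg.norm(direction)
        base = rng.normal(size=p)
        pos = base + delta * direction + 0.2 * rng.normal(size=(n, p))
        neg = base - delta * direction + 0.2 * rng.normal(size=(n, p))
        return pos, neg

    def test_separated_clouds_have_disjoint_ld1_ranges(self):
        pos, neg = self._clouds()
        res = lda_ld1(pos, neg)
        assert res.ld1_pos.min() > res.ld1_neg.max()

    def test_orientation_positive_mean_higher(self):
        pos, neg = self._clouds(seed=1)
        res = lda_ld1(pos, neg)
        assert res.ld1_pos.mean() > res.ld1_neg.mean()

    def test_label_swap_negates_scores(self):
        pos, neg = self._clouds(seed=2)
        res = lda_ld1(pos, neg)
        swapped = lda_ld1(neg, pos)
        assert np.allclose(np.sort(res.ld1_pos), np.sort(-swapped.ld1_neg))

    def test_identical_groups_equal_means(self):
        rng = np.random.default_rng(6)
        group = rng.normal(size=(30, 6))
        res = lda_ld1(group, group.copy())
        assert res.ld1_pos.mean() == pytest.approx(res.ld1_neg.mean())

    def test_agrees_with_reference_lda_projection(self):
        # independent route: sklearn's LDA on a well-conditioned problem
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        pos, neg = self._clouds(seed=3, delta=1.0)
        res = lda_ld1(pos, neg)
        X = np.vstack([pos, neg])
        y = np.r_[np.ones(len(pos)), np.zeros(len(neg))]
        ref = LinearDiscriminantAnalysis(n_components=1).fit(X, y)
        ref_scores = ref.transform(X).ravel()
        ours = np.r_[res.ld1_pos, res.ld1_neg]
        corr = abs(np.corrcoef(ours, ref_scores)[0, 1])
        assert corr > 0.999


class TestCompactness:
    def test_closed_form_three_vs_three(self):
        res = LdaResult(np.array([0.0, 0.0, 0.0]),
                        np.array([0.0, 10.0, 20.0]), 0.0, 1.0)
        t, p = ld1_compactness_test(res)
        # pos distances {0,0,0}; neg {10,20,10}: Welch t = -4, df = 2
        assert t == pytest.approx(-4.0)
        assert p == pytest.approx(2 * stats.t.sf(4.0, 2.0))

    def test_identical_score_multisets(self):
        res = LdaResult(np.array([1.0, 2.0, 3.0]),
                        np.array([1.0, 2.0, 3.0]), 0.0, 1.0)
        t, p = ld1_compactness_test(res)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_pairwise_distance_counts(self):
        from xenomir.group_stats import _pairwise_distances
        for n in (2, 5, 9):
            assert len(_pairwise_distances(np.arange(n))) == n * (n - 1) // 2

    def test_too_few_scores_is_an_error(self):
        res = LdaResult(np.array([0.0]), np.array([1.0, 2.0]), 0.0, 1.0)
        with pytest.raises(ValueError):
            ld1_compactness_test(res)


class TestFamilySummary:
    def test_fig1_style_fraction(self):
        records = [MiRNARecord(f"m{i}", "ACGU" * 5, "positive",
                               family="mir168") for i in range(7)]
        df = family_summary(records, {"mir168": 17})
        assert df.loc[0, "n_mapped"] == 7
        assert round(df.loc[0, "percent_mapped"], 1) == 41.2

    def test_empty_records(self):
        assert family_summary([], {"mir168": 17}).empty

    def test_full_family(self):
        records = [MiRNARecord(f"m{i}", "ACGU" * 5, "positive", family="f")
                   for i in range(3)]
        df = family_summary(records, {"f": 3})
        assert df.loc[0, "percent_mapped"] == 100.0

    def test_missing_family_is_an_error(self):
        records = [MiRNARecord("m", "ACGU" * 5, "positive", family="f")]
        with pytest.raises(KeyError):
            family_summary(records, {"g": 3})
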