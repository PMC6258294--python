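"""Screen all 105 model features for group differences.

Runs the two-sided Wilcoxon rank-sum test per feature with
Benjamini-Hochberg FDR control (alpha = 0.01), the analysis that
produces the study's table of significantly different sequence features.
"""

from xenomir import (compare_feature_groups, feature_matrix,
                     generate_dataset, lda_ld1, table1_like_config)

dataset, _, _ = generate_dataset(table1_like_config(seed=1))
pos_X = feature_matrix(dataset.positives)
neg_X = feature_matrix(dataset.negatives)

rows = compare_feature_groups(pos_X, neg_X, alpha=0.01)
significant = [r for r in rows if r.significant]
print(f"{len(significant)} of {len(rows)} features significant at FDR<0.01")
print(f"{'feature':>12} {'p':>10} {'fdr':>10} {'mean+':>8} {'mean-':>8}")
for r in sorted(significant, key=lambda r: r.fdr)[:10]:
    print(f"{r.feature:>12} {r.p_value:10.2e} {r.fdr:10.2e} "
          f"{r.mean_pos:8.4f} {r.mean_neg:8.4f}")

# LD1 separability: project both groups on the Fisher discriminant and
# compare within-group pairwise distances (compactness).
lda = lda_ld1(pos_X, neg_X)
print(f"\nLD1 means: positives {lda.ld1_pos.mean():.2f}, "
      f"negatives {lda.ld1_neg.mean():.2f}")
print(f"compactness Welch t = {lda.compactness_t:.1f}, "
      f"p = {lda.compactness_p:.2e}")
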