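"""Biclustering a noisy gene expression matrix with rectangular BMF.

Plants 10 non-overlapping constant biclusters in a 100 x 50 expression
matrix, adds Gaussian noise, thresholds the matrix at half the signal
level, and factorizes it with row and column clusters untied.  The match
score (best Jaccard overlap of gene sets, averaged) measures how well the
found biclusters represent the truth (relevance) and how well each true
bicluster is recovered (recovery).
"""

from bmfcluster import (
    FitConfig,
    binarize_expression,
    fit_multi,
    generate_expression_biclusters,
    match_score,
    model_to_biclusters,
)

for noise_sd in (0.0, 0.1, 0.25):
    expr, truth = generate_expression_biclusters(
        n_genes=100, n_conds=50, k=10, signal=1.0, noise_sd=noise_sd, seed=0
    )
    x = binarize_expression(expr, signal=1.0)
    model, _ = fit_multi(x, FitConfig(m_init=30, restarts=30, seed=0, symmetric=False))
    found = model_to_biclusters(model)
    relevance = match_score(found, truth)
    recovery = match_score(truth, found)
    print(f"noise_sd={noise_sd:.2f}: {len(found)} biclusters found, "
          f"relevance={relevance:.3f}, recovery={recovery:.3f}")
print()
print("Scores of 1.0 mean every found bicluster's gene set exactly matches "
      "a planted one and vice versa; robustness shows as the scores staying "
      "high while the noise standard deviation grows.")
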