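"""Phase-randomization surrogate test: CAP structure vanishes under the null.

Surrogates keep every component's amplitude spectrum (mean, variance,
autocorrelation) but randomize phases independently per component,
destroying cross-component coactivation. Clustering surrogates at the
original k yields weak centroids; the RMS-centroid structure score
quantifies the gap.
"""

import numpy as np

import capdyn as cd
from capdyn.preprocess import trim_scan, zscore

cohort = cd.simulate_cohort(cd.CohortConfig(rng_seed=1))
proc = [zscore(trim_scan(ts)) for ts in cohort.subjects]
selected = [cd.select_top_frames(ts.seed_series, 0.20, ts.subject_id) for ts in proc]
pooled = cd.pool_frames(proc, selected)
solution = cd.kmeans_cluster(pooled, 5, n_init=50, rng_seed=1)

result = cd.surrogate_cap_analysis(
    proc, solution, fraction=0.20, n_realizations=20, n_init=10, rng_seed=1
)
scores = np.asarray(result.surrogate_scores)
print(f"original structure score : {result.original_score:.4f}")
print(f"surrogate scores         : mean {scores.mean():.4f}, "
      f"95th pct {np.percentile(scores, 95):.4f}")
print(f"score ratio              : {result.score_ratio:.2f}")
print(f"surrogates below original: {result.percentile_of_original():.0%}")
# The original solution should exceed every surrogate score: coherent
# network coactivation is present in the data but not in the null.
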