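"""Rank the most discriminative edges and test them within sex strata.

Per training fold, the 20 smallest-p edges are tallied; edges are ranked by
cross-fold frequency (ties by best p) and the top 9 are annotated with AAL-78
region and lobe names. With the effect injected into regions 3 and 10, the
ranked edges should be incident to those regions.
"""

import numpy as np

from brainnetdx import (
    CohortConfig,
    PipelineConfig,
    edge_to_names,
    gender_edge_analysis,
    load_atlas,
    rank_cv_edges,
    run_cv,
    simulate_cohort,
)
from brainnetdx.networks import (
    apply_zscore,
    fit_zscore,
    fuse_features,
    subject_feature_blocks,
)

cohort = simulate_cohort(CohortConfig(
    base_seed=5, affected_regions=(3, 10), thickness_effect_mm=0.6, cbf_effect=8.0))
blocks = subject_feature_blocks(cohort)
cv = run_cv(cohort, PipelineConfig(n_repeats=1, base_seed=2), feature_blocks=blocks)

atlas = load_atlas()
ranking = rank_cv_edges(cv, repeat=0, top_m=20, top_k=9)
print("top discriminative edges (fold count, best p):")
for (modality, a, b), count, best_p, rank in ranking.rows:
    name_a, name_b, lobes, _ = edge_to_names((a, b), atlas, modality)
    print(f" {rank}. {name_a}-{name_b} [{lobes}, {modality}] "
          f"count={count} p={best_p:.2e}")

x_t1, x_asl, m1, m2 = blocks
fused = fuse_features(apply_zscore(x_t1, fit_zscore(x_t1)),
                      apply_zscore(x_asl, fit_zscore(x_asl)), 0.5, m1, m2)
col_of = {meta: j for j, meta in enumerate(fused.column_meta)}
labels = np.array([1 if s.group == "ASD" else -1 for s in cohort])
gdf = gender_edge_analysis(fused.matrix, labels,
                           [s.sex for s in cohort],
                           [col_of[e] for e, *_ in ranking.rows])
print("\nsex-stratified t-tests (p < 0.01 flagged significant):")
print(gdf[["edge", "p_all", "p_male", "p_female"]].to_string(index=False))
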