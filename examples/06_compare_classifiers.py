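"""Compare RVFL against ELM and SVM with the DeLong paired AUC test.

All three classifiers see identical out-of-fold score vectors on the same
subjects (pooled over a repeat), so their AUCs are correlated; DeLong's test
accounts for that correlation.
"""

from brainnetdx import (
    CohortConfig,
    PipelineConfig,
    delong_test,
    run_cv,
    simulate_cohort,
)
from brainnetdx.networks import subject_feature_blocks

cohort = simulate_cohort(CohortConfig(
    base_seed=9, affected_regions=(3, 10), thickness_effect_mm=0.05))
blocks = subject_feature_blocks(cohort)

scores = {}
for clf in ("rvfl", "elm", "svm"):
    cfg = PipelineConfig(n_repeats=1, base_seed=4, classifier=clf)
    res = run_cv(cohort, cfg, feature_blocks=blocks)
    scores[clf] = res.per_repeat[0].scores
    print(f"{clf:>4}: AUC {res.metrics_mean['AUC']:.3f}, "
          f"ACC {res.metrics_mean['ACC']:.3f}")

labels = [1 if s.group == "ASD" else -1 for s in cohort]
for other in ("elm", "svm"):
    auc_a, auc_b, z, p = delong_test(scores["rvfl"], scores[other], labels)
    print(f"DeLong RVFL vs {other.upper()}: AUC {auc_a:.3f} vs {auc_b:.3f}, "
          f"z = {z:.2f}, p = {p:.3f}")
print("small p would indicate a reliable AUC difference on these subjects")
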