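"""Cross-validate the full pipeline on a cohort with an injected group effect.

Within every training fold the pipeline z-scores the edge features, fuses the
two modalities (equal weights), filters edges by group t-test (p < 0.05),
ranks survivors with mRMR, and trains an RVFL classifier; metrics are means
over repeats of the pooled out-of-fold predictions. The injected 0.6 mm
thickness effect in six regions makes the groups clearly separable.
"""

from brainnetdx import CohortConfig, PipelineConfig, run_cv, simulate_cohort

cohort = simulate_cohort(CohortConfig(
    base_seed=3, affected_regions=(3, 10, 20, 30, 40, 50),
    thickness_effect_mm=0.6, cbf_effect=8.0))

result = run_cv(cohort, PipelineConfig(n_repeats=5, base_seed=1))

print(f"{len(cohort)} subjects, 5-fold CV x {len(result.per_repeat)} repeats")
for key in ("ACC", "SEN", "SPC", "precision", "F1", "AUC"):
    print(f"  {key:>9}: {result.metrics_mean[key]:.3f} "
          f"+/- {result.metrics_sd[key]:.3f}")
print("values near 1.0 mean the injected effect is recovered; a null cohort "
      "sits near 0.5")
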