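# brainnetdx

Multimodal individual brain-network construction and classification for
case-control neuroimaging studies — built around the setting of distinguishing
preschool-aged children with autism spectrum disorder (ASD) from typically
developing (TD) controls using T1-weighted gray-matter and arterial-spin-labeling
(ASL) cerebral-blood-flow (CBF) measurements over 78 cortical AAL regions.

It is a library first (importable API plus `examples/`), with a thin CLI for
running the pipeline from a shell. Because clinical imaging cohorts of this
kind are private, the package ships a fully specified synthetic-cohort
simulator; every statistical property of the pipeline is calibrated and
stress-tested against it.

## The model

For each subject, two R×R networks (R = 78 cortical regions) are built:

* **Gray-matter similarity network (T1).** Region *a* is summarised by its mean
  cortical thickness *u*<sub>a</sub> and across-vertex SD *∂*<sub>a</sub>; the
  edge weight is the Gaussian kernel

  f<sub>ab</sub> = exp( −(u<sub>a</sub> − u<sub>b</sub>)² / (2∂²) ),  ∂² = ∂<sub>a</sub>² + ∂<sub>b</sub>²,

  so f<sub>ab</sub> ∈ (0, 1] and only thickness *differences* matter.

* **CBF network (ASL).** Region *a* is summarised by a fixed-length vector of
  empirical quantiles of its voxel CBF distribution; the edge weight is the
  Pearson correlation of the two regions' quantile descriptors.

The strict upper triangles (R(R−1)/2 = 3003 edges each) are z-scored per column
on training data only, weighted *w*·T1 / (1−*w*)·ASL and concatenated (6006
features). Per training fold, edges are filtered by a pooled two-sample t-test
(p < 0.05), ranked by greedy mRMR (mutual-information difference criterion),
and the top k feed a **random vector functional link (RVFL)** classifier:
random hidden layer H = g(XW + b), design D = [X | H | 1], output weights
solved in closed form as ridge regression onto ±1 labels (dropping the direct
links X gives an ELM; an RBF-SVM baseline is included). Evaluation is
stratified 5-fold CV repeated 20 times (ACC/SEN/SPC/precision/F1/AUC), with
DeLong's paired test for AUC comparisons, and a discriminative-edge ranking
that tallies each fold's 20 smallest-p edges across folds and reports the top
9 with AAL region and lobe names.

## Worked example

```python
from brainnetdx import CohortConfig, PipelineConfig, run_cv, simulate_cohort

cohort = simulate_cohort(CohortConfig(
    base_seed=3, affected_regions=(3, 10, 20, 30, 40, 50),
    thickness_effect_mm=0.6, cbf_effect=8.0))
result = run_cv(cohort, PipelineConfig(n_repeats=5, base_seed=1))
print({k: round(v, 3) for k, v in result.metrics_mean.items()})
```

prints (see `examples/03_cross_validate.py`)

```
{'ACC': 1.0, 'SEN': 1.0, 'SPC': 1.0, 'precision': 1.0, 'F1': 1.0, 'AUC': 1.0}
```

— a 0.6 mm thickness shift in six regions separates the simulated groups
perfectly, while a null cohort (no injected effect) scores near chance
(ACC ≈ 0.5). Each script in `examples/` demonstrates one capability
(simulation and demographics, network construction, cross-validation, the
fusion-weight sweep, edge ranking with atlas names, classifier comparison via
DeLong) and prints a line explaining what the numbers mean.

The same pipeline runs from the shell:

```bash
brainnetdx simulate --outdir run/sim
brainnetdx cv --cohort-dir run/sim/cohort --outdir run/cv
brainnetdx rank --cv-dir run/cv --cohort-dir run/sim/cohort --outdir run/rank
```

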