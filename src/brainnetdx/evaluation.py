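"""Repeated stratified cross-validation, classification metrics, ROC/AUC and
the DeLong paired AUC comparison.

The CV protocol is leakage-free by construction: within every training fold —
and only there — the z-score normalisation is fitted, features are fused and
weighted, the t-test filter and mRMR ranking are run, and the classifier is
trained; the frozen transforms are then applied to the held-out fold. Metrics
are computed per repeat from that repeat's pooled out-of-fold predictions and
reported as mean +/- SD over repeats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ASD, SubjectRecord
from .config import PipelineConfig
from .models import RVFLConfig, rvfl_train, rvfl_predict, svm_baseline
from .networks import apply_zscore, fit_zscore, fuse_features, subject_feature_blocks
from .selection import SelectionResult, select_features

__all__ = [
    "ConfusionCounts",
    "FoldRecord",
    "RepeatResult",
    "CVResult",
    "stratified_kfold",
    "classification_metrics",
    "confusion_from_predictions",
    "roc_auc",
    "delong_test",
    "run_cv",
    "weight_sweep",
    "METRIC_KEYS",
]

METRIC_KEYS = ("ACC", "SEN", "SPC", "precision", "F1", "AUC")


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 confusion counts with ASD as the positive class."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


def classification_metrics(cm: ConfusionCounts) -> dict[str, float]:
    """ACC/SEN/SPC/precision/F1 from confusion counts; 0 on zero denominators."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")

    def ratio(num: int, den: int) -> float:
        if den == 0:
            warnings.warn(
                "zero denominator in a classification metric; reporting 0",
                UserWarning,
                stacklevel=3,
            )
            return 0.0
        return num / den

    sen = ratio(cm.tp, cm.tp + cm.fn)
    spc = ratio(cm.tn, cm.tn + cm.fp)
    prec = ratio(cm.tp, cm.tp + cm.fp)
    f1 = 2 * prec * sen / (prec + sen) if (prec + sen) > 0 else 0.0
    return {
        "ACC": (cm.tp + cm.tn) / cm.total,
        "SEN": sen,
        "SPC": spc,
        "precision": prec,
        "F1": f1,
    }


def confusion_from_predictions(
    predictions: Sequence[int], labels: Sequence[int]
) -> ConfusionCounts:
    """Confusion counts from +/-1 predictions and +/-1 true labels (+1 = ASD)."""
    pred = np.asarray(predictions)
    lab = np.asarray(labels)
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (lab == 1))),
        fn=int(np.sum((pred == -1) & (lab == 1))),
        tn=int(np.sum((pred == -1) & (lab == -1))),
        fp=int(np.sum((pred == 1) & (lab == -1))),
    )


def stratified_kfold(labels: Sequence, k: int = 5, seed: int = 0) -> np.ndarray:
    """Per-class shuffled round-robin fold assignment (deterministic in seed).

    Within each class, fold sizes differ by at most one. Returns an integer
    fold index in [0, k) per subject.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    assignment = np.full(labels.shape[0], -1, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(
                f"class {cls!r} has {idx.size} members, fewer than k={k} folds"
            )
        rng.shuffle(idx)
        assignment[idx] = np.arange(idx.size) % k
    return assignment


# ---------------------------------------------------------------------------
# ROC / AUC and the DeLong paired comparison
# ---------------------------------------------------------------------------

def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, np.ndarray]:
    """AUC as the Mann-Whitney probability (ties count 1/2) plus ROC points.

    Returns ``(auc, points)`` with points an (m, 2) array of (FPR, TPR) rows
    from all score thresholds, anchored at (0,0) and (1,1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels != 1]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size)
    order = np.argsort(-scores, kind="stable")
    tps = np.cumsum(labels[order] == 1)
    fps = np.cumsum(labels[order] != 1)
    distinct = np.r_[np.flatnonzero(np.diff(scores[order])), scores.size - 1]
    tpr = np.r_[0.0, tps[distinct] / pos.size]
    fpr = np.r_[0.0, fps[distinct] / neg.size]
    return float(auc), np.column_stack([fpr, tpr])


def _placement_values(scores: np.ndarray, pos_mask: np.ndarray):
    """Per-subject placement values (midrank form) and the AUC."""
    pos = scores[pos_mask]
    neg = scores[~pos_mask]
    m, n = pos.size, neg.size
    tz = stats.rankdata(np.concatenate([pos, neg]))
    tx = stats.rankdata(pos)
    ty = stats.rankdata(neg)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    return v10, v01, float(auc)


def delong_test(
    scores_a: Sequence[float], scores_b: Sequence[float], labels: Sequence[int]
) -> tuple[float, float, float, float]:
    """DeLong's paired comparison of two correlated AUCs on the same subjects.

    Returns ``(auc_a, auc_b, z, p)`` with a two-sided normal p-value. A zero
    variance of the AUC difference is degenerate: p = 1 if the AUCs agree,
    otherwise an error.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if not (scores_a.shape == scores_b.shape == labels.shape):
        raise ValueError("score vectors and labels must have identical shape")
    pos_mask = labels == 1
    if pos_mask.all() or not pos_mask.any():
        raise ValueError("both classes must be present")
    v10a, v01a, auc_a = _placement_values(scores_a, pos_mask)
    v10b, v01b, auc_b = _placement_values(scores_b, pos_mask)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    var = s10 / m + s01 / n
    var_diff = var[0, 0] + var[1, 1] - 2 * var[0, 1]
    if var_diff <= 0:
        if np.isclose(auc_a, auc_b):
            return auc_a, auc_b, 0.0, 1.0
        raise ValueError("degenerate DeLong comparison: zero variance, unequal AUCs")
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(p)


# ---------------------------------------------------------------------------
# Repeated cross-validation of the full pipeline
# ---------------------------------------------------------------------------

@dataclass
class FoldRecord:
    fold: int
    test_indices: np.ndarray
    selection: SelectionResult
    selected_meta: list[tuple[str, int, int]]


@dataclass
class RepeatResult:
    repeat: int
    fold_assignment: np.ndarray
    scores: np.ndarray  # out-of-fold score per subject
    predictions: np.ndarray  # out-of-fold +/-1 prediction per subject
    folds: list[FoldRecord]
    metrics: dict[str, float]


@dataclass
class CVResult:
    per_repeat: list[RepeatResult]
    metrics_mean: dict[str, float]
    metrics_sd: dict[str, float]
    pooled_scores: np.ndarray  # per-subject mean out-of-fold score over repeats
    labels: np.ndarray
    column_meta: list[tuple[str, int, int]]
    config: PipelineConfig


def _fold_seed(base_seed: int, repeat: int, fold: int) -> int:
    return int(np.random.SeedSequence([base_seed, repeat, fold]).generate_state(1)[0] % (2**31))


def _fit_predict(classifier: str, rvfl_cfg: RVFLConfig, seed: int,
                 X_tr, y_tr, X_te):
    if classifier == "svm":
        model = svm_baseline(X_tr, y_tr)
        return model.predict(X_te)
    cfg_kwargs = {**rvfl_cfg.__dict__, "seed": seed}
    if classifier == "elm":
        cfg_kwargs["direct_links"] = False
        if cfg_kwargs["n_hidden"] == 0:
            raise ValueError("ELM requires n_hidden >= 1")
    model = rvfl_train(X_tr, y_tr, RVFLConfig(**cfg_kwargs))
    return rvfl_predict(model, X_te)


def run_cv(
    subjects: Sequence[SubjectRecord],
    config: PipelineConfig | None = None,
    feature_blocks=None,
) -> CVResult:
    """Repeated stratified k-fold CV of the full pipeline on a cohort.

    ``feature_blocks`` may carry precomputed raw edge blocks (from
    :func:`brainnetdx.networks.subject_feature_blocks`) to avoid recomputing
    networks across repeated calls (e.g. the weight sweep); they are raw,
    per-subject quantities, so sharing them across folds leaks nothing.
    """
    config = config or PipelineConfig()
    y = np.array([1 if s.group == ASD else -1 for s in subjects])
    if np.unique(y).size < 2:
        raise ValueError("cohort must contain both groups")
    if feature_blocks is None:
        feature_blocks = subject_feature_blocks(subjects, q=config.q)
    x_t1, x_asl, t1_meta, asl_meta = feature_blocks
    column_meta = list(t1_meta) + list(asl_meta)
    n = len(subjects)
    per_repeat: list[RepeatResult] = []
    for r in range(config.n_repeats):
        assignment = stratified_kfold(y, k=config.k_folds, seed=config.base_seed + r)
        scores = np.zeros(n)
        preds = np.zeros(n, dtype=int)
        folds: list[FoldRecord] = []
        for f in range(config.k_folds):
            test = np.flatnonzero(assignment == f)
            train = np.flatnonzero(assignment != f)
            try:
                norm_t1 = fit_zscore(x_t1[train])
                norm_asl = fit_zscore(x_asl[train])
                fused_tr = fuse_features(
                    apply_zscore(x_t1[train], norm_t1),
                    apply_zscore(x_asl[train], norm_asl),
                    config.w_t1, t1_meta, asl_meta,
                )
                fused_te = fuse_features(
                    apply_zscore(x_t1[test], norm_t1),
                    apply_zscore(x_asl[test], norm_asl),
                    config.w_t1, t1_meta, asl_meta,
                )
                sel = select_features(
                    fused_tr.matrix, y[train],
                    alpha=config.alpha, k=config.mrmr_k, bins=config.mrmr_bins,
                )
                cols = sel.mrmr_order
                sc, lb = _fit_predict(
                    config.classifier, config.rvfl,
                    _fold_seed(config.base_seed, r, f),
                    fused_tr.matrix[:, cols], y[train], fused_te.matrix[:, cols],
                )
            except Exception as exc:
                raise type(exc)(f"repeat {r}, fold {f}: {exc}") from exc
            scores[test] = sc
            preds[test] = lb
            folds.append(FoldRecord(
                fold=f, test_indices=test, selection=sel,
                selected_meta=[column_meta[c] for c in cols],
            ))
        metrics = classification_metrics(confusion_from_predictions(preds, y))
        metrics["AUC"] = roc_auc(scores, y)[0]
        per_repeat.append(RepeatResult(
            repeat=r, fold_assignment=assignment, scores=scores,
            predictions=preds, folds=folds, metrics=metrics,
        ))
    stacked = {k: np.array([rep.metrics[k] for rep in per_repeat]) for k in METRIC_KEYS}
    return CVResult(
        per_repeat=per_repeat,
        metrics_mean={k: float(v.mean()) for k, v in stacked.items()},
        metrics_sd={k: float(v.std(ddof=1)) if v.size > 1 else 0.0 for k, v in stacked.items()},
        pooled_scores=np.mean([rep.scores for rep in per_repeat], axis=0),
        labels=y,
        column_meta=column_meta,
        config=config,
    )


def weight_sweep(
    subjects: Sequence[SubjectRecord],
    config: PipelineConfig | None = None,
    weights: Sequence[float] | None = None,
    feature_blocks=None,
) -> pd.DataFrame:
    """Sweep the T1 fusion weight (default 0.1..0.9) and record CV metrics.

    Returns a DataFrame with one row per weight (ascending) and columns
    ``w_t1``, ``auc_mean``, ``auc_sd``, ``acc_mean``, ``acc_sd``.
    """
    config = config or PipelineConfig()
    if weights is None:
        weights = np.round(np.arange(0.1, 0.95, 0.1), 10)
    if feature_blocks is None:
        feature_blocks = subject_feature_blocks(subjects, q=config.q)
    rows = []
    for w in weights:
        cfg = PipelineConfig.from_dict({**config.to_dict(), "w_t1": float(w)})
        res = run_cv(subjects, cfg, feature_blocks=feature_blocks)
        rows.append({
            "w_t1": float(w),
            "auc_mean": res.metrics_mean["AUC"],
            "auc_sd": res.metrics_sd["AUC"],
            "acc_mean": res.metrics_mean["ACC"],
            "acc_sd": res.metrics_sd["ACC"],
        })
    return pd.DataFrame(rows).sort_values("w_t1", ignore_index=True)
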