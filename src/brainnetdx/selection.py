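"""Feature selection: two-sample t-test filtering followed by mRMR ranking.

Also houses the demographic group-comparison statistics (pooled two-sample
t-test from raw values or summary statistics, Pearson chi-square on a 2x2
table) used to characterise a cohort.

The selection protocol mirrors the diagnosis pipeline: keep edge features whose
ASD-vs-TD pooled t-test has p < alpha (0.05, uncorrected), then rank survivors
with greedy minimum-redundancy-maximum-relevance (mRMR) using the MID
(mutual-information difference) criterion on equal-frequency-discretised
features, and retain the top k.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "SelectionResult",
    "DegenerateStatisticWarning",
    "ttest_two_sample",
    "ttest_from_summary",
    "chi_square_2x2",
    "ttest_filter",
    "mrmr_select",
    "select_features",
]


class DegenerateStatisticWarning(UserWarning):
    """A statistic hit a degenerate-input convention (e.g. zero pooled SD)."""


@dataclass
class SelectionResult:
    """Outcome of the t-test filter (and, optionally, the mRMR pass).

    ``surviving_indices`` are ordered by ascending p; ``mrmr_order`` is the
    greedy selection order (a subset of the survivors), of length
    ``min(k_selected, len(surviving_indices))``.
    """

    surviving_indices: np.ndarray
    p_values: np.ndarray
    mrmr_order: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    k_selected: int = 0
    fallback_used: bool = False

    def to_json(self, path: str | Path, **params) -> None:
        payload = {
            "surviving_indices": self.surviving_indices.tolist(),
            "p_values": self.p_values.tolist(),
            "mrmr_order": self.mrmr_order.tolist(),
            "k_selected": int(self.k_selected),
            "fallback_used": bool(self.fallback_used),
            "params": params,
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))


def ttest_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Student's pooled-variance two-sample t-test; returns (t, two-sided p).

    Degenerate conventions: zero pooled SD with equal means -> (0, 1); zero
    pooled SD with unequal means -> (inf-signed t, 0) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need >= 2 observations")
    sp2 = ((x.size - 1) * np.var(x, ddof=1) + (y.size - 1) * np.var(y, ddof=1)) / (
        x.size + y.size - 2
    )
    if sp2 == 0.0:
        if np.mean(x) == np.mean(y):
            return 0.0, 1.0
        warnings.warn(
            "zero pooled SD with unequal means; p set to 0 by convention",
            DegenerateStatisticWarning,
            stacklevel=2,
        )
        return float(np.sign(np.mean(x) - np.mean(y)) * np.inf), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def ttest_from_summary(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> tuple[float, float]:
    """Pooled two-sample t-test from group summary statistics (mean, SD, n)."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if s1 < 0 or s2 < 0:
        raise ValueError("SDs must be >= 0")
    if s1 == 0.0 and s2 == 0.0:
        if m1 == m2:
            return 0.0, 1.0
        warnings.warn(
            "zero pooled SD with unequal means; p set to 0 by convention",
            DegenerateStatisticWarning,
            stacklevel=2,
        )
        return float(np.sign(m1 - m2) * np.inf), 0.0
    t, p = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
    return float(t), float(p)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on [[a, b], [c, d]]."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be >= 0")
    n = table.sum()
    if n == 0:
        raise ValueError("table total must be > 0")
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("a zero marginal makes expected counts undefined")
    chi2 = n * (a * d - b * c) ** 2 / (rows[0] * rows[1] * cols[0] * cols[1])
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def _column_ttest_pvalues(features: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorised pooled two-sample t-test p-value per column."""
    g1 = features[labels == 1]
    g0 = features[labels != 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(g1, g0, axis=0, equal_var=True)
    p = np.asarray(p, dtype=float)
    # zero pooled variance: p is nan; apply the degenerate conventions
    nan = np.isnan(p)
    if nan.any():
        equal = np.isclose(g1.mean(axis=0), g0.mean(axis=0))
        p[nan & equal] = 1.0
        p[nan & ~equal] = 0.0
    return p


def ttest_filter(
    features: np.ndarray, labels: Sequence[int], alpha: float = 0.05
) -> SelectionResult:
    """Keep features whose between-group t-test has p < alpha.

    Survivors are ordered by ascending p (ties by column index). If nothing
    survives, the min(10, d) smallest-p columns are kept and the result is
    flagged (``fallback_used``).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    if min(np.sum(labels == c) for c in classes) < 2:
        raise ValueError("each class needs >= 2 members")
    y = (labels == classes.max()).astype(int)
    p = _column_ttest_pvalues(features, y)
    order = np.lexsort((np.arange(p.size), p))  # ascending p, ties by index
    surviving = order[p[order] < alpha]
    fallback = False
    if surviving.size == 0:
        surviving = order[: min(10, p.size)]
        fallback = True
        warnings.warn(
            f"no feature survived the p < {alpha} filter; keeping the "
            f"{surviving.size} smallest-p features",
            DegenerateStatisticWarning,
            stacklevel=2,
        )
    return SelectionResult(
        surviving_indices=surviving.astype(int),
        p_values=p,
        fallback_used=fallback,
    )


# ---------------------------------------------------------------------------
# mRMR (greedy MID criterion on equal-frequency-discretised features)
# ---------------------------------------------------------------------------

def _discretize(features: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency binning per column; returns int codes in [0, bins)."""
    n, d = features.shape
    codes = np.zeros((n, d), dtype=np.int64)
    qs = np.quantile(features, np.arange(1, bins) / bins, axis=0)
    for j in range(d):
        codes[:, j] = np.searchsorted(qs[:, j], features[:, j], side="left")
    return codes


def _mi_from_joint(joint: np.ndarray) -> float:
    """Mutual information (nats) from a 2-D contingency count table."""
    n = joint.sum()
    if n == 0:
        return 0.0
    pxy = joint / n
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    return float(np.sum(pxy[mask] * np.log(pxy[mask] / (px @ py)[mask])))


def _mi_columns_vs_vector(codes: np.ndarray, v: np.ndarray, levels_v: int,
                          levels_c: int) -> np.ndarray:
    """MI of each column of ``codes`` with integer vector ``v`` (vectorised)."""
    n, d = codes.shape
    flat = (codes * levels_v + v[:, None]) + np.arange(d) * (levels_c * levels_v)
    counts = np.bincount(flat.ravel(), minlength=d * levels_c * levels_v)
    counts = counts.reshape(d, levels_c, levels_v).astype(float)
    p = counts / n
    px = p.sum(axis=2, keepdims=True)
    py = p.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (px * py))
    return np.nansum(terms, axis=(1, 2))


def mrmr_select(
    features: np.ndarray,
    labels: Sequence[int],
    k: int,
    bins: int = 3,
) -> np.ndarray:
    """Greedy mRMR with the MID (difference) criterion.

    Columns are discretised into ``bins`` equal-frequency bins on the given
    rows; relevance and redundancy are discrete mutual information in nats. The
    first pick maximises I(f; y); each subsequent pick maximises
    I(f; y) - mean over selected s of I(f; s). Ties break to the lower column
    index. Deterministic; returns min(k, d) column indices in selection order.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if features.ndim != 2 or features.shape[1] < 1:
        raise ValueError("features must be 2-D with >= 1 column")
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("need exactly 2 classes")
    y = (labels == classes.max()).astype(np.int64)
    n, d = features.shape
    codes = _discretize(features, bins)
    relevance = _mi_columns_vs_vector(codes, y, 2, bins)
    k = min(k, d)
    selected: list[int] = []
    redundancy = np.zeros(d)
    available = np.ones(d, dtype=bool)
    for step in range(k):
        if step == 0:
            score = relevance.copy()
        else:
            score = relevance - redundancy / step
        score[~available] = -np.inf
        pick = int(np.argmax(score))  # first occurrence = lowest index on ties
        selected.append(pick)
        available[pick] = False
        if step < k - 1:
            redundancy += _mi_columns_vs_vector(codes, codes[:, pick], bins, bins)
    return np.array(selected, dtype=int)


def select_features(
    features: np.ndarray,
    labels: Sequence[int],
    alpha: float = 0.05,
    k: int = 20,
    bins: int = 3,
) -> SelectionResult:
    """t-test filter then mRMR ranking; the pipeline's full selection stage.

    ``mrmr_order`` indexes the original feature columns.
    """
    res = ttest_filter(features, labels, alpha=alpha)
    surv = res.surviving_indices
    order = mrmr_select(np.asarray(features, float)[:, surv], labels, k=k, bins=bins)
    res.mrmr_order = surv[order]
    res.k_selected = int(min(k, surv.size))
    return res
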