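"""Independent brute-force oracles used to cross-check the implementation.

Every function here is written from the defining formula, in the most naive
way available (explicit loops, pair enumeration, normal equations), and never
calls into :mod:`brainnetdx`.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def pooled_t_oracle(x, y):
    """Textbook pooled-variance two-sample t and two-sided p."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
    return t, p


def pearson_oracle(x, y):
    """Sum-of-products Pearson r."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    dx, dy = x - x.mean(), y - y.mean()
    return float(np.sum(dx * dy) / math.sqrt(np.sum(dx**2) * np.sum(dy**2)))


def ridge_oracle(D, y, lam):
    """Normal-equations ridge solve (D'D + lam I)^-1 D'y."""
    D = np.asarray(D, float)
    return np.linalg.inv(D.T @ D + lam * np.eye(D.shape[1])) @ D.T @ np.asarray(y, float)


def auc_pairs_oracle(scores, labels):
    """AUC by enumerating all positive-negative pairs (ties count 1/2)."""
    scores, labels = np.asarray(scores, float), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels != 1]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))


def delong_oracle(scores_a, scores_b, labels):
    """DeLong paired AUC comparison via explicit placement-value loops."""
    labels = np.asarray(labels)
    out = []
    for scores in (np.asarray(scores_a, float), np.asarray(scores_b, float)):
        pos = scores[labels == 1]
        neg = scores[labels != 1]
        m, n = len(pos), len(neg)
        v10 = np.array([np.mean([_psi(p, q) for q in neg]) for p in pos])
        v01 = np.array([np.mean([_psi(p, q) for p in pos]) for q in neg])
        out.append((v10, v01, v10.mean()))
    (v10a, v01a, auc_a), (v10b, v01b, auc_b) = out
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    var = s10 / m + s01 / n
    z = (auc_a - auc_b) / math.sqrt(var[0, 0] + var[1, 1] - 2 * var[0, 1])
    p = 2 * stats.norm.sf(abs(z))
    return auc_a, auc_b, z, p


def _psi(p, q):
    return 1.0 if p > q else (0.5 if p == q else 0.0)


def mi_oracle(u, v):
    """Discrete mutual information (nats) by direct probability summation."""
    u, v = np.asarray(u), np.asarray(v)
    n = len(u)
    mi = 0.0
    for a in np.unique(u):
        for b in np.unique(v):
            pab = np.mean((u == a) & (v == b))
            if pab > 0:
                mi += pab * math.log(pab / (np.mean(u == a) * np.mean(v == b)))
    return mi


def discretize_oracle(col, bins):
    """Equal-frequency bin codes using quantile edges (left-open search)."""
    edges = np.quantile(col, np.arange(1, bins) / bins)
    return np.array([int(np.sum(x >= edges) if x in edges else np.searchsorted(edges, x))
                     for x in col])


def mrmr_oracle(features, labels, k, bins=3):
    """Naive greedy MID mRMR re-derivation with explicit loops."""
    X = np.asarray(features, float)
    y = (np.asarray(labels) == np.max(labels)).astype(int)
    n, d = X.shape
    codes = np.empty((n, d), dtype=int)
    for j in range(d):
        edges = np.quantile(X[:, j], np.arange(1, bins) / bins)
        codes[:, j] = np.searchsorted(edges, X[:, j], side="left")
    relevance = [mi_oracle(codes[:, j], y) for j in range(d)]
    selected = []
    while len(selected) < min(k, d):
        best, best_score = None, -np.inf
        for j in range(d):
            if j in selected:
                continue
            if selected:
                red = np.mean([mi_oracle(codes[:, j], codes[:, s]) for s in selected])
            else:
                red = 0.0
            score = relevance[j] - red
            if score > best_score:  # strict: ties keep the lower index
                best, best_score = j, score
        selected.append(best)
    return selected


def mrmr_step_scores(features, labels, selected, bins=3):
    """Oracle MID scores of every candidate given an already-selected list."""
    X = np.asarray(features, float)
    y = (np.asarray(labels) == np.max(labels)).astype(int)
    n, d = X.shape
    codes = np.empty((n, d), dtype=int)
    for j in range(d):
        edges = np.quantile(X[:, j], np.arange(1, bins) / bins)
        codes[:, j] = np.searchsorted(edges, X[:, j], side="left")
    scores = np.full(d, -np.inf)
    for j in range(d):
        if j in selected:
            continue
        red = (np.mean([mi_oracle(codes[:, j], codes[:, s]) for s in selected])
               if selected else 0.0)
        scores[j] = mi_oracle(codes[:, j], y) - red
    return scores


def rank_edges_oracle(per_fold, top_m, top_k):
    """Exhaustive re-derivation of the fold-frequency edge ranking."""
    counts, best = {}, {}
    for fold in per_fold:
        top = sorted(fold, key=lambda ep: (ep[1], ep[0]))[:top_m]
        for e, p in top:
            counts[e] = counts.get(e, 0) + 1
            best[e] = min(best.get(e, np.inf), p)
    ordered = sorted(counts, key=lambda e: (-counts[e], best[e], e))
    return [(e, counts[e], best[e], i + 1) for i, e in enumerate(ordered[:top_k])]
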