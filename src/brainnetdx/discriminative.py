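"""Discriminative-edge ranking, atlas naming and the sex-stratified analysis.

The ranking procedure mirrors the cross-validated selection: within each of the
k training folds, take the ``top_m`` edges with the smallest between-group
p-values; count how often each edge appears across folds; order edges by that
fold count (descending), breaking ties by the edge's minimum p across the folds
where it appeared (ascending), then by edge identity; keep the first ``top_k``.

Region naming uses the 78-region cortical subset of the AAL atlas (AAL-90 minus
bilateral hippocampus, amygdala, caudate, putamen, pallidum and thalamus),
shipped as a versioned TSV resource with hemisphere and lobe assignments.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

from .evaluation import CVResult
from .selection import ttest_two_sample

__all__ = [
    "RegionAtlas",
    "EdgeRanking",
    "load_atlas",
    "rank_edges",
    "edge_to_names",
    "fold_pvalue_lists",
    "rank_cv_edges",
    "gender_edge_analysis",
]

EdgeKey = Hashable  # typically (modality, region_a, region_b)


@dataclass(frozen=True)
class RegionAtlas:
    """The 78 cortical AAL regions in fixed row order.

    ``names`` are Table-style display names with an L_/R_ prefix; ``lobes``
    take values in {frontal, temporal, parietal, occipital, limbic, insula}.
    """

    names: tuple[str, ...]
    lobes: tuple[str, ...]
    hemispheres: tuple[str, ...]
    aal_names: tuple[str, ...]
    aal_labels: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("region names must be unique")
        n = len(self.names)
        if not (len(self.lobes) == len(self.hemispheres) == len(self.aal_labels) == n):
            raise ValueError("atlas field lengths disagree")

    @property
    def n_regions(self) -> int:
        return len(self.names)

    def index_of(self, name: str) -> int:
        return self.names.index(name)


def load_atlas(path: str | Path | None = None) -> RegionAtlas:
    """Load the bundled AAL-78 cortical atlas (or a compatible TSV)."""
    if path is None:
        src = resources.files("brainnetdx.data") / "aal78.tsv"
        df = pd.read_csv(src.open(), sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return RegionAtlas(
        names=tuple(df["display_name"]),
        lobes=tuple(df["lobe"]),
        hemispheres=tuple(df["hemisphere"]),
        aal_names=tuple(df["aal_name"]),
        aal_labels=tuple(int(v) for v in df["aal_label"]),
    )


@dataclass
class EdgeRanking:
    """Ranked discriminative edges: (edge, fold count, best p, rank 1..k)."""

    rows: list[tuple[EdgeKey, int, float, int]]

    def to_frame(self, atlas: RegionAtlas | None = None) -> pd.DataFrame:
        recs = []
        for edge, count, best_p, rank in self.rows:
            rec = {"rank": rank, "fold_count": count, "best_p": best_p}
            if isinstance(edge, tuple) and len(edge) == 3:
                modality, a, b = edge
                rec["modality"] = modality
                if atlas is not None:
                    name_a, name_b, lobe_pair, _ = edge_to_names((a, b), atlas, modality)
                    rec["connectivity_feature"] = f"{name_a}-{name_b}"
                    rec["brain_lobe"] = lobe_pair
                else:
                    rec["connectivity_feature"] = f"({a}, {b})"
            else:
                rec["connectivity_feature"] = str(edge)
            recs.append(rec)
        return pd.DataFrame(recs)


def rank_edges(
    per_fold_pvalues: Sequence[Sequence[tuple[EdgeKey, float]]],
    top_m: int = 20,
    top_k: int = 9,
) -> EdgeRanking:
    """Cross-fold frequency ranking of small-p edges.

    ``per_fold_pvalues`` holds one (edge, p) list per fold. Per fold the
    ``top_m`` smallest-p edges are taken (ties by edge identity); edges are
    then ordered by cross-fold appearance count (desc), minimum p across the
    folds where they appeared (asc), then edge identity, and the first
    ``top_k`` are returned with ranks 1..top_k. Deterministic and stable under
    permutation of each fold's list.
    """
    counts: dict[EdgeKey, int] = {}
    best_p: dict[EdgeKey, float] = {}
    for f, fold in enumerate(per_fold_pvalues):
        if len(fold) < top_m:
            raise ValueError(f"fold {f} has {len(fold)} edges, fewer than top_m={top_m}")
        top = sorted(fold, key=lambda ep: (ep[1], ep[0]))[:top_m]
        for edge, p in top:
            counts[edge] = counts.get(edge, 0) + 1
            best_p[edge] = min(best_p.get(edge, np.inf), p)
    ordered = sorted(counts, key=lambda e: (-counts[e], best_p[e], e))
    rows = [
        (edge, counts[edge], best_p[edge], rank + 1)
        for rank, edge in enumerate(ordered[:top_k])
    ]
    return EdgeRanking(rows=rows)


def edge_to_names(
    edge: int | tuple[int, int],
    atlas: RegionAtlas,
    modality: str = "T1",
) -> tuple[str, str, str, str]:
    """Annotate an edge (region pair or upper-triangle position) with names.

    Returns ``(name_a, name_b, lobe_pair, modality)`` in Table style, e.g.
    ``("L_Supplementary motor area", "L_Calcarine cortex", "frontal-occipital",
    "T1")``.
    """
    if isinstance(edge, (int, np.integer)):
        a, b = _triangle_position_to_pair(int(edge), atlas.n_regions)
    else:
        a, b = int(edge[0]), int(edge[1])
    if not (0 <= a < atlas.n_regions and 0 <= b < atlas.n_regions):
        raise IndexError(f"region index out of range for a {atlas.n_regions}-region atlas")
    lobe_pair = f"{atlas.lobes[a]}-{atlas.lobes[b]}"
    return atlas.names[a], atlas.names[b], lobe_pair, modality


def _triangle_position_to_pair(pos: int, n: int) -> tuple[int, int]:
    ia, ib = np.triu_indices(n, k=1)
    if not 0 <= pos < ia.size:
        raise IndexError(f"upper-triangle position {pos} out of range")
    return int(ia[pos]), int(ib[pos])


def fold_pvalue_lists(
    cv_result: CVResult, repeat: int = 0
) -> list[list[tuple[EdgeKey, float]]]:
    """Per-fold (edge, training p-value) lists for one repeat of a CV run."""
    rep = cv_result.per_repeat[repeat]
    meta = cv_result.column_meta
    return [
        [(meta[j], float(p)) for j, p in enumerate(fold.selection.p_values)]
        for fold in rep.folds
    ]


def rank_cv_edges(
    cv_result: CVResult,
    repeat: int | None = 0,
    top_m: int = 20,
    top_k: int = 9,
) -> EdgeRanking:
    """Rank discriminative edges from a CV run's stored per-fold p-values.

    ``repeat=None`` aggregates fold counts over all repeats instead of using a
    single repeat's k folds.
    """
    if repeat is not None:
        folds = fold_pvalue_lists(cv_result, repeat)
    else:
        folds = [
            fold
            for r in range(len(cv_result.per_repeat))
            for fold in fold_pvalue_lists(cv_result, r)
        ]
    return rank_edges(folds, top_m=top_m, top_k=top_k)


def gender_edge_analysis(
    features: np.ndarray,
    labels: Sequence[int],
    sex: Sequence[str],
    edges: Sequence[int],
    significance: float = 0.01,
) -> pd.DataFrame:
    """Group-difference t-tests per edge for all / male / female subjects.

    ``edges`` are feature-column indices; ``labels`` +/-1 group codes; ``sex``
    "M"/"F" per subject. Strata with fewer than 2 subjects per group yield a
    missing p with a flag. Returns a DataFrame with p_all/p_male/p_female and
    boolean ``sig_*`` columns at the reference level (default p < 0.01).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    sex = np.asarray(sex)
    unknown = set(sex) - {"M", "F"}
    if unknown:
        raise ValueError(f"unknown sex code(s): {sorted(unknown)}")
    strata = {
        "all": np.ones(sex.shape[0], dtype=bool),
        "male": sex == "M",
        "female": sex == "F",
    }
    rows = []
    for col in edges:
        rec: dict = {"edge": int(col)}
        for name, mask in strata.items():
            g1 = features[mask & (labels == 1), col]
            g0 = features[mask & (labels != 1), col]
            if g1.size < 2 or g0.size < 2:
                rec[f"p_{name}"] = np.nan
                rec[f"missing_{name}"] = True
                rec[f"sig_{name}"] = False
            else:
                _, p = ttest_two_sample(g1, g0)
                rec[f"p_{name}"] = p
                rec[f"missing_{name}"] = False
                rec[f"sig_{name}"] = bool(p < significance)
        rows.append(rec)
    return pd.DataFrame(rows)
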