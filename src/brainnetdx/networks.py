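"""Per-subject brain-network construction and feature fusion.

Two individual networks are built for every subject over the same R cortical
regions:

* **T1 gray-matter similarity network** — edge weight between regions a and b is
  the Gaussian kernel of their mean cortical thicknesses,

  .. math:: f_{ab} = \\exp\\left(-\\frac{(u_a - u_b)^2}{2(\\partial_a^2 + \\partial_b^2)}\\right)

  where :math:`u` is the across-vertex mean thickness and :math:`\\partial` the
  across-vertex SD of a region. Weights lie in (0, 1] and depend only on the
  thickness *difference*, so a global thickness offset cancels.

* **ASL CBF network** — each region is summarised by a fixed-length vector of
  empirical quantiles of its voxel CBF distribution; the edge weight is the
  Pearson correlation of the two regions' quantile vectors. Being a Pearson
  correlation it is invariant to positive affine transforms of either region's
  CBF values — it compares distribution *shapes*, not levels.

Both matrices are symmetric with unit diagonal; their strict upper triangles
(row-major, a < b) are vectorised into R(R-1)/2 features per modality, z-scored
per column (train-set statistics only), weighted ``w_T1`` / ``1 - w_T1`` and
concatenated into the fused classifier input.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import SubjectRecord

__all__ = [
    "RegionalSummary",
    "ConnectivityMatrix",
    "ZScoreNormalization",
    "FusedFeatureSet",
    "DegenerateEdgeWarning",
    "regional_summaries",
    "gm_edge_weight",
    "gm_network",
    "cbf_network",
    "upper_triangle_vector",
    "upper_triangle_pairs",
    "fit_zscore",
    "apply_zscore",
    "fuse_features",
    "subject_feature_blocks",
    "extract_roi_samples",
    "write_network_tsv",
    "read_network_tsv",
    "write_feature_set",
]

DEFAULT_Q = 50


class DegenerateEdgeWarning(UserWarning):
    """A degenerate edge (zero SDs / constant region) hit a limit convention."""


@dataclass
class RegionalSummary:
    """Per-region summary feeding both networks.

    ``mean_thickness``/``sd_thickness`` are the u and SD of the Gaussian kernel;
    ``cbf_quantiles`` is the non-decreasing empirical-quantile descriptor of the
    region's voxel CBF distribution (levels ``(i + 0.5)/q``).
    """

    region_index: int
    mean_thickness: float
    sd_thickness: float
    cbf_quantiles: np.ndarray

    def __post_init__(self) -> None:
        self.cbf_quantiles = np.asarray(self.cbf_quantiles, dtype=float)
        if self.sd_thickness < 0:
            raise ValueError("sd_thickness must be >= 0")
        if not self.mean_thickness > 0:
            raise ValueError("mean_thickness must be > 0")
        if np.any(np.diff(self.cbf_quantiles) < 0):
            raise ValueError("cbf_quantiles must be non-decreasing")


@dataclass
class ConnectivityMatrix:
    """Symmetric R x R edge-weight matrix tagged with its modality."""

    modality: str  # "T1" or "ASL"
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.modality not in ("T1", "ASL"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.weights.ndim != 2 or self.weights.shape[0] != self.weights.shape[1]:
            raise ValueError("weights must be a square matrix")

    @property
    def n_regions(self) -> int:
        return self.weights.shape[0]


@dataclass
class ZScoreNormalization:
    """Per-column mean/SD fitted on training rows; SD-0 columns map to 0."""

    mean: np.ndarray
    sd: np.ndarray
    zero_sd: np.ndarray  # boolean flag per column


@dataclass
class FusedFeatureSet:
    """Weighted, concatenated T1 + ASL edge features for n subjects.

    ``column_meta`` holds one ``(modality, region_a, region_b)`` triple per
    column, so both networks are exactly reconstructible up to the applied
    scalar weights.
    """

    matrix: np.ndarray
    column_meta: list[tuple[str, int, int]]
    w_t1: float
    normalization: tuple[ZScoreNormalization, ZScoreNormalization] | None = None

    @property
    def w_asl(self) -> float:
        return 1.0 - self.w_t1


def regional_summaries(subject: SubjectRecord, q: int = DEFAULT_Q) -> list[RegionalSummary]:
    """Summarise every region of a subject: thickness mean/SD + CBF quantiles.

    The SD uses the n-1 denominator; quantile levels are ``(i + 0.5)/q`` with
    linear interpolation between order statistics.
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    levels = (np.arange(q) + 0.5) / q
    out = []
    for r in range(subject.n_regions):
        thick = np.asarray(subject.thickness_samples[r], dtype=float)
        cbf = np.asarray(subject.cbf_samples[r], dtype=float)
        if thick.size < 2:
            raise ValueError(
                f"region {r}: need >= 2 thickness samples (SD undefined), got {thick.size}"
            )
        if cbf.size == 0:
            raise ValueError(f"region {r}: no CBF samples")
        out.append(
            RegionalSummary(
                region_index=r,
                mean_thickness=float(np.mean(thick)),
                sd_thickness=float(np.std(thick, ddof=1)),
                cbf_quantiles=np.quantile(cbf, levels),
            )
        )
    return out


def gm_edge_weight(a: RegionalSummary, b: RegionalSummary) -> float:
    """Gaussian-kernel similarity of two regions' thickness summaries.

    Degenerate case (both SDs zero): returns 1 if the means agree, else 0, and
    emits a :class:`DegenerateEdgeWarning`.
    """
    var = a.sd_thickness**2 + b.sd_thickness**2
    diff = a.mean_thickness - b.mean_thickness
    if var == 0.0:
        warnings.warn(
            f"degenerate edge ({a.region_index}, {b.region_index}): both SDs zero",
            DegenerateEdgeWarning,
            stacklevel=2,
        )
        return 1.0 if diff == 0.0 else 0.0
    return float(np.exp(-(diff**2) / (2.0 * var)))


def gm_network(summaries: Sequence[RegionalSummary]) -> ConnectivityMatrix:
    """Build the T1 gray-matter similarity network from regional summaries."""
    if len(summaries) < 2:
        raise ValueError("need >= 2 regional summaries")
    u = np.array([s.mean_thickness for s in summaries])
    v = np.array([s.sd_thickness for s in summaries]) ** 2
    var = v[:, None] + v[None, :]
    diff2 = (u[:, None] - u[None, :]) ** 2
    degenerate = var == 0.0
    if np.any(degenerate & ~np.eye(len(u), dtype=bool)):
        warnings.warn(
            "degenerate edges with zero combined SD; applying limit convention",
            DegenerateEdgeWarning,
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.exp(-diff2 / (2.0 * var))
    w[degenerate] = np.where(diff2[degenerate] == 0.0, 1.0, 0.0)
    np.fill_diagonal(w, 1.0)
    return ConnectivityMatrix(modality="T1", weights=w)


def cbf_network(summaries: Sequence[RegionalSummary]) -> ConnectivityMatrix:
    """Build the ASL network: Pearson correlation of CBF quantile descriptors.

    Constant (zero-variance) descriptors have undefined correlation; their
    off-diagonal entries are set to 0 with a warning.
    """
    if len(summaries) < 2:
        raise ValueError("need >= 2 regional summaries")
    qmat = np.stack([s.cbf_quantiles for s in summaries])
    if qmat.shape[1] < 3:
        raise ValueError("need q >= 3 quantiles for a meaningful correlation")
    sd = qmat.std(axis=1)
    constant = sd == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.corrcoef(qmat)
    if constant.any():
        warnings.warn(
            f"constant CBF descriptor for regions {np.flatnonzero(constant).tolist()}; "
            "their correlations are undefined and set to 0",
            DegenerateEdgeWarning,
            stacklevel=2,
        )
        w[constant, :] = 0.0
        w[:, constant] = 0.0
    w = np.clip((w + w.T) / 2.0, -1.0, 1.0)  # symmetrise fp noise
    np.fill_diagonal(w, 1.0)
    return ConnectivityMatrix(modality="ASL", weights=w)


def upper_triangle_pairs(n_regions: int) -> list[tuple[int, int]]:
    """Row-major (a, b) with a < b — the fixed edge ordering used everywhere."""
    ia, ib = np.triu_indices(n_regions, k=1)
    return list(zip(ia.tolist(), ib.tolist()))


def upper_triangle_vector(
    m: ConnectivityMatrix, atol: float = 1e-10
) -> tuple[np.ndarray, list[tuple[str, int, int]]]:
    """Vectorise the strict upper triangle of a symmetric connectivity matrix.

    Returns ``(values, meta)`` where ``meta[i] = (modality, a, b)`` and entries
    follow row-major order (0,1), (0,2), ..., (1,2), ...; length R(R-1)/2.
    """
    w = m.weights
    if not np.allclose(w, w.T, atol=atol, rtol=0.0):
        raise ValueError("matrix is not symmetric within tolerance 1e-10")
    ia, ib = np.triu_indices(w.shape[0], k=1)
    meta = [(m.modality, int(a), int(b)) for a, b in zip(ia, ib)]
    return w[ia, ib].copy(), meta


def fit_zscore(train_matrix: np.ndarray) -> ZScoreNormalization:
    """Fit per-column z-score statistics (n-1 SD) on training rows only."""
    x = np.asarray(train_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("train_matrix must be 2-D with >= 2 rows")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    return ZScoreNormalization(mean=mean, sd=sd, zero_sd=sd == 0.0)


def apply_zscore(matrix: np.ndarray, norm: ZScoreNormalization) -> np.ndarray:
    """Apply a fitted normalization; zero-SD columns map to 0."""
    x = np.asarray(matrix, dtype=float)
    if x.shape[1] != norm.mean.shape[0]:
        raise ValueError(
            f"normalization fitted on {norm.mean.shape[0]} columns, got {x.shape[1]}"
        )
    sd = np.where(norm.zero_sd, 1.0, norm.sd)
    z = (x - norm.mean) / sd
    z[:, norm.zero_sd] = 0.0
    return z


def fuse_features(
    t1_block: np.ndarray,
    asl_block: np.ndarray,
    w_t1: float,
    t1_meta: Sequence[tuple[str, int, int]] | None = None,
    asl_meta: Sequence[tuple[str, int, int]] | None = None,
) -> FusedFeatureSet:
    """Concatenate z-scored T1 and ASL edge blocks with weights w / (1 - w)."""
    if not 0.0 <= w_t1 <= 1.0:
        raise ValueError("w_t1 must lie in [0, 1]")
    t1 = np.asarray(t1_block, dtype=float)
    asl = np.asarray(asl_block, dtype=float)
    if t1.shape[0] != asl.shape[0]:
        raise ValueError(
            f"subject-count mismatch: T1 block has {t1.shape[0]} rows, ASL {asl.shape[0]}"
        )
    if t1_meta is None:
        r = _infer_regions(t1.shape[1])
        t1_meta = [("T1", a, b) for a, b in upper_triangle_pairs(r)]
    if asl_meta is None:
        r = _infer_regions(asl.shape[1])
        asl_meta = [("ASL", a, b) for a, b in upper_triangle_pairs(r)]
    matrix = np.hstack([w_t1 * t1, (1.0 - w_t1) * asl])
    meta = list(t1_meta) + list(asl_meta)
    if len(set(meta)) != len(meta):
        raise ValueError("duplicate column metadata in fused feature set")
    return FusedFeatureSet(matrix=matrix, column_meta=meta, w_t1=float(w_t1))


def _infer_regions(n_edges: int) -> int:
    r = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
    if r * (r - 1) // 2 != n_edges:
        raise ValueError(f"{n_edges} is not of the form R(R-1)/2")
    return r


def subject_feature_blocks(
    subjects: Sequence[SubjectRecord], q: int = DEFAULT_Q
) -> tuple[np.ndarray, np.ndarray, list[tuple[str, int, int]], list[tuple[str, int, int]]]:
    """Raw (un-normalized) per-subject edge-feature blocks for both modalities.

    Returns ``(X_t1, X_asl, t1_meta, asl_meta)`` with one row per subject.
    """
    t1_rows, asl_rows = [], []
    t1_meta = asl_meta = None
    for s in subjects:
        summ = regional_summaries(s, q=q)
        v1, m1 = upper_triangle_vector(gm_network(summ))
        v2, m2 = upper_triangle_vector(cbf_network(summ))
        t1_rows.append(v1)
        asl_rows.append(v2)
        t1_meta, asl_meta = m1, m2
    return np.vstack(t1_rows), np.vstack(asl_rows), t1_meta, asl_meta


def extract_roi_samples(
    cbf_volume: str | Path,
    label_volume: str | Path,
    label_map: dict[int, int],
) -> dict[int, np.ndarray]:
    """Pull per-region voxel CBF values out of registered NIfTI volumes.

    ``label_map`` maps region index -> integer label value in the label volume.
    Regions whose label is absent from the volume yield an empty array with a
    warning. Both volumes must share grid dimensions; the label volume must be
    integer-valued.
    """
    import nibabel as nib

    cbf_img = nib.load(str(cbf_volume))
    lab_img = nib.load(str(label_volume))
    cbf = np.asarray(cbf_img.get_fdata(), dtype=float)
    lab = np.asarray(lab_img.get_fdata())
    if cbf.shape != lab.shape:
        raise ValueError(
            f"volume grids differ: CBF {cbf.shape} vs labels {lab.shape}"
        )
    if not np.allclose(lab, np.round(lab)):
        raise ValueError("label volume is not integer-valued")
    lab = np.round(lab).astype(int)
    out: dict[int, np.ndarray] = {}
    for region, value in label_map.items():
        mask = lab == int(value)
        if not mask.any():
            warnings.warn(
                f"label {value} (region {region}) absent from label volume",
                UserWarning,
                stacklevel=2,
            )
        out[int(region)] = cbf[mask]
    return out


# ---------------------------------------------------------------------------
# Serialization (TSV networks; TSV + JSON sidecar feature sets)
# ---------------------------------------------------------------------------

def write_network_tsv(m: ConnectivityMatrix, names: Sequence[str], path: str | Path) -> None:
    if len(names) != m.n_regions:
        raise ValueError("name count does not match matrix size")
    pd.DataFrame(m.weights, columns=list(names)).to_csv(path, sep="\t", index=False)


def read_network_tsv(path: str | Path, modality: str) -> tuple[ConnectivityMatrix, list[str]]:
    df = pd.read_csv(path, sep="\t")
    return ConnectivityMatrix(modality=modality, weights=df.to_numpy(float)), list(df.columns)


def write_feature_set(fs: FusedFeatureSet, prefix: str | Path) -> tuple[Path, Path]:
    """Write a fused feature set as ``<prefix>.tsv`` + ``<prefix>.json`` sidecar."""
    prefix = Path(prefix)
    tsv = prefix.with_suffix(".tsv")
    js = prefix.with_suffix(".json")
    cols = [f"{m}_{a}_{b}" for m, a, b in fs.column_meta]
    pd.DataFrame(fs.matrix, columns=cols).to_csv(tsv, sep="\t", index=False)
    sidecar = {
        "w_t1": fs.w_t1,
        "column_meta": [list(c) for c in fs.column_meta],
    }
    if fs.normalization is not None:
        sidecar["normalization"] = [
            {"mean": n.mean.tolist(), "sd": n.sd.tolist(), "zero_sd": n.zero_sd.tolist()}
            for n in fs.normalization
        ]
    js.write_text(json.dumps(sidecar, sort_keys=True))
    return tsv, js
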