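"""Synthetic multimodal cohort simulator.

Generates two-group (ASD vs TD) cohorts of per-region vertex cortical-thickness
samples and voxel CBF samples with controllable group effects in designated
regions, so the whole network/selection/classification pipeline can be exercised
and calibrated without access to any real (private) imaging data.

Generative model
----------------
Cohort-level parameters are drawn once per cohort from ``base_seed``:

* region ``r`` has population mean thickness ``mu_r ~ Uniform(2.0, 3.5)`` mm and
  across-vertex SD ``sigma_r ~ Uniform(0.2, 0.5)`` mm;
* region ``r`` has population mean CBF ``Normal(50, 8)`` mL/100g/min and
  across-voxel SD ``Uniform(5, 10)``.

Subject ``s`` has a global thickness offset ``Normal(0, 0.1)`` and a global CBF
offset ``Normal(0, 3)``. Vertex values are ``Normal(mu_r + offset_s + delta, sigma_r)``
where ``delta`` equals the configured effect size when the subject is ASD and the
region is in ``affected_regions``, else 0; voxel CBF values analogously. Sex is
Bernoulli with the study marginals (24/30 male in ASD, 14/22 in TD); age is
normal (ASD 4.71 +/- 1.41, TD 5.49 +/- 1.68 years) truncated to (2, 9) by
resampling.

Each subject owns an independent RNG substream keyed by (group, within-group
index), so enlarging one group never perturbs the other group's subjects and
cohorts are reproducible field-for-field from ``base_seed``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ASD",
    "TD",
    "CohortConfig",
    "SubjectRecord",
    "ConfigurationError",
    "CohortFormatError",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
]

ASD = "ASD"
TD = "TD"

_GROUPS = (ASD, TD)
_SEXES = ("M", "F")

# Table-1 style demographic marginals used by the simulator.
_MALE_PROB = {ASD: 24 / 30, TD: 14 / 22}
_AGE_MEAN = {ASD: 4.71, TD: 5.49}
_AGE_SD = {ASD: 1.41, TD: 1.68}
_AGE_BOUNDS = (2.0, 9.0)

# Substream tags keeping cohort-level and per-subject draws independent.
_POP_STREAM = 1_000_003
_GROUP_STREAM = {ASD: 2, TD: 3}


class ConfigurationError(ValueError):
    """Raised when a :class:`CohortConfig` field is invalid; names the field."""


class CohortFormatError(ValueError):
    """Raised when an on-disk cohort is malformed; names the file (and line)."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a simulated two-group cohort.

    Defaults mirror the study conditions: 30 ASD vs 22 TD subjects and 78
    cortical regions. ``thickness_effect_mm = cbf_effect = 0`` defines the null
    cohort (no group difference anywhere).
    """

    n_asd: int = 30
    n_td: int = 22
    n_regions: int = 78
    vertices_per_region: int = 200
    voxels_per_region: int = 150
    affected_regions: tuple[int, ...] = ()
    thickness_effect_mm: float = 0.0
    cbf_effect: float = 0.0
    base_seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "affected_regions", tuple(self.affected_regions))
        self.validate()

    def validate(self) -> None:
        if self.n_asd < 2:
            raise ConfigurationError("n_asd must be >= 2")
        if self.n_td < 2:
            raise ConfigurationError("n_td must be >= 2")
        if self.n_regions < 2:
            raise ConfigurationError("n_regions must be >= 2")
        if self.vertices_per_region < 2:
            raise ConfigurationError("vertices_per_region must be >= 2")
        if self.voxels_per_region < 1:
            raise ConfigurationError("voxels_per_region must be >= 1")
        for r in self.affected_regions:
            if not 0 <= int(r) < self.n_regions:
                raise ConfigurationError(
                    f"affected_regions entry {r} out of range [0, {self.n_regions})"
                )
        if self.thickness_effect_mm < 0:
            raise ConfigurationError("thickness_effect_mm must be >= 0")
        if self.cbf_effect < 0:
            raise ConfigurationError("cbf_effect must be >= 0")


@dataclass
class SubjectRecord:
    """One subject's raw per-region measurements plus metadata.

    ``thickness_samples[r]`` holds the vertex thickness values (mm) of region
    ``r``; ``cbf_samples[r]`` the voxel CBF values (mL/100 g/min).
    """

    subject_id: str
    group: str
    sex: str
    age: float
    thickness_samples: list[np.ndarray] = field(default_factory=list)
    cbf_samples: list[np.ndarray] = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return len(self.thickness_samples)


def _population_params(config: CohortConfig):
    rng = np.random.default_rng([config.base_seed, _POP_STREAM])
    r = config.n_regions
    mu_thick = rng.uniform(2.0, 3.5, r)
    sd_thick = rng.uniform(0.2, 0.5, r)
    mu_cbf = rng.normal(50.0, 8.0, r)
    sd_cbf = rng.uniform(5.0, 10.0, r)
    return mu_thick, sd_thick, mu_cbf, sd_cbf


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      bounds: tuple[float, float]) -> float:
    lo, hi = bounds
    while True:  # resample-on-reject
        v = rng.normal(mean, sd)
        if lo < v < hi:
            return float(v)


def _simulate_subject(config: CohortConfig, group: str, j: int,
                      pop) -> SubjectRecord:
    mu_thick, sd_thick, mu_cbf, sd_cbf = pop
    rng = np.random.default_rng([config.base_seed, _GROUP_STREAM[group], j])
    sex = "M" if rng.random() < _MALE_PROB[group] else "F"
    age = _truncated_normal(rng, _AGE_MEAN[group], _AGE_SD[group], _AGE_BOUNDS)
    off_thick = rng.normal(0.0, 0.1)
    off_cbf = rng.normal(0.0, 3.0)
    affected = set(config.affected_regions)
    thickness, cbf = [], []
    for r in range(config.n_regions):
        d_t = config.thickness_effect_mm if (group == ASD and r in affected) else 0.0
        d_c = config.cbf_effect if (group == ASD and r in affected) else 0.0
        thickness.append(rng.normal(mu_thick[r] + off_thick + d_t, sd_thick[r],
                                    config.vertices_per_region))
        cbf.append(rng.normal(mu_cbf[r] + off_cbf + d_c, sd_cbf[r],
                              config.voxels_per_region))
    sid = f"{group.lower()}{j + 1:03d}"
    return SubjectRecord(subject_id=sid, group=group, sex=sex, age=age,
                         thickness_samples=thickness, cbf_samples=cbf)


def simulate_cohort(config: CohortConfig) -> list[SubjectRecord]:
    """Simulate a cohort of ``n_asd + n_td`` subjects (ASD first).

    Deterministic given ``config`` (including ``base_seed``).
    """
    config.validate()
    pop = _population_params(config)
    subjects = [_simulate_subject(config, ASD, j, pop) for j in range(config.n_asd)]
    subjects += [_simulate_subject(config, TD, j, pop) for j in range(config.n_td)]
    return subjects


# ---------------------------------------------------------------------------
# On-disk layout: subjects.tsv + one long-format TSV per subject.
# ---------------------------------------------------------------------------

def write_cohort(cohort: Sequence[SubjectRecord], directory: str | Path) -> list[Path]:
    """Write a cohort as ``subjects.tsv`` plus one measurements TSV per subject.

    Each per-subject file has columns ``region_index``, ``measurement_type``
    (``thickness`` or ``cbf``) and ``value`` — one row per vertex/voxel sample.
    Returns the list of files written. The layout round-trips through
    :func:`read_cohort` and is byte-deterministic for a given cohort.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    meta = pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in cohort],
            "group": [s.group for s in cohort],
            "sex": [s.sex for s in cohort],
            "age": [repr(float(s.age)) for s in cohort],
        }
    )
    meta_path = directory / "subjects.tsv"
    meta.to_csv(meta_path, sep="\t", index=False)
    written.append(meta_path)
    for s in cohort:
        rows = []
        for r, vals in enumerate(s.thickness_samples):
            rows.extend((r, "thickness", repr(float(v))) for v in vals)
        for r, vals in enumerate(s.cbf_samples):
            rows.extend((r, "cbf", repr(float(v))) for v in vals)
        df = pd.DataFrame(rows, columns=["region_index", "measurement_type", "value"])
        p = directory / f"{s.subject_id}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written.append(p)
    return written


def _parse_subject_file(path: Path) -> tuple[list[np.ndarray], list[np.ndarray]]:
    try:
        df = pd.read_csv(path, sep="\t")
    except Exception as exc:  # malformed TSV
        raise CohortFormatError(f"{path}: cannot parse TSV ({exc})") from exc
    expected = ["region_index", "measurement_type", "value"]
    if list(df.columns) != expected:
        raise CohortFormatError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )
    bad_type = ~df["measurement_type"].isin(["thickness", "cbf"])
    if bad_type.any():
        line = int(df.index[bad_type][0]) + 2  # + header + 1-based
        raise CohortFormatError(
            f"{path}, line {line}: unknown measurement_type "
            f"{df['measurement_type'][bad_type].iloc[0]!r}"
        )
    values = pd.to_numeric(df["value"], errors="coerce")
    if values.isna().any():
        line = int(df.index[values.isna()][0]) + 2
        raise CohortFormatError(f"{path}, line {line}: non-numeric value")
    out: dict[str, list[np.ndarray]] = {}
    for kind in ("thickness", "cbf"):
        sub = df[df["measurement_type"] == kind]
        present = sorted(sub["region_index"].unique())
        if not present:
            raise CohortFormatError(f"{path}: no {kind} measurements")
        n_regions = int(max(present)) + 1
        missing = sorted(set(range(n_regions)) - set(int(r) for r in present))
        if missing:
            raise CohortFormatError(
                f"{path}: missing {kind} measurements for region indices {missing}"
            )
        out[kind] = [
            values[sub.index[sub["region_index"] == r]].to_numpy(float)
            for r in range(n_regions)
        ]
    if len(out["thickness"]) != len(out["cbf"]):
        raise CohortFormatError(
            f"{path}: thickness covers {len(out['thickness'])} regions but cbf "
            f"covers {len(out['cbf'])}"
        )
    return out["thickness"], out["cbf"]


def read_cohort(directory: str | Path) -> list[SubjectRecord]:
    """Read a cohort written by :func:`write_cohort`; inverse of it."""
    directory = Path(directory)
    meta_path = directory / "subjects.tsv"
    if not meta_path.exists():
        raise CohortFormatError(f"{meta_path}: file not found")
    meta = pd.read_csv(meta_path, sep="\t")
    required = ["subject_id", "group", "sex", "age"]
    if list(meta.columns) != required:
        raise CohortFormatError(
            f"{meta_path}: expected columns {required}, found {list(meta.columns)}"
        )
    subjects = []
    for i, row in meta.iterrows():
        line = int(i) + 2
        if row["group"] not in _GROUPS:
            raise CohortFormatError(
                f"{meta_path}, line {line}: invalid group code {row['group']!r} "
                f"(expected one of {list(_GROUPS)})"
            )
        if row["sex"] not in _SEXES:
            raise CohortFormatError(
                f"{meta_path}, line {line}: invalid sex code {row['sex']!r} "
                f"(expected one of {list(_SEXES)})"
            )
        try:
            age = float(row["age"])
        except (TypeError, ValueError) as exc:
            raise CohortFormatError(
                f"{meta_path}, line {line}: non-numeric age {row['age']!r}"
            ) from exc
        subj_path = directory / f"{row['subject_id']}.tsv"
        if not subj_path.exists():
            raise CohortFormatError(f"{subj_path}: file not found")
        thickness, cbf = _parse_subject_file(subj_path)
        subjects.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                sex=str(row["sex"]),
                age=age,
                thickness_samples=thickness,
                cbf_samples=cbf,
            )
        )
    return subjects
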