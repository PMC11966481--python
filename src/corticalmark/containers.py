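"""Core in-memory containers shared across the pipeline stages.

Everything tabular is a thin wrapper around :class:`pandas.DataFrame`;
volumes are plain numpy arrays plus the minimal metadata the computations
need (mask, voxel size, region records).  NIfTI affines are passed through
untouched by :mod:`corticalmark.io`; all computation happens in voxel space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VolumeTimeSeries",
    "ParcellationAtlas",
    "ReHoMap",
    "RegionalMeasureTable",
    "TemplateVector",
    "canonical_region_name",
]

#: metadata columns of a cohort table; everything else is a region measure
SUBJECT_COLUMNS = ["subject_id", "age", "sex", "dx", "severity"]


def canonical_region_name(name: str) -> str:
    """Normalize a region name for cross-source matching.

    Lowercase, strip, and collapse whitespace/hyphens to underscores so that
    e.g. ``"Caudal Anterior-Cingulate"`` and ``caudal_anterior_cingulate``
    refer to the same parcel.
    """
    out = str(name).strip().lower()
    for ch in (" ", "-", "."):
        out = out.replace(ch, "_")
    while "__" in out:
        out = out.replace("__", "_")
    return out


@dataclass
class VolumeTimeSeries:
    """A 4-D BOLD-like volume with a spatial mask.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        Intensity time series; arbitrary units.
    mask : ndarray of bool, shape (x, y, z)
        Voxels to analyze.  Must contain at least one ``True`` voxel, and
        the data must be finite inside it.
    voxel_dims : tuple of float
        Voxel edge lengths in mm (metadata only).
    """

    data: np.ndarray
    mask: np.ndarray
    voxel_dims: tuple = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4-D (x,y,z,t), got shape {self.data.shape}")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match spatial shape "
                f"{self.data.shape[:3]}"
            )
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 timepoints for rank statistics")
        if not self.mask.any():
            raise ValueError("mask is empty")
        if not np.isfinite(self.data[self.mask]).all():
            raise ValueError("non-finite values inside the mask")
        if len(self.voxel_dims) != 3 or any(v <= 0 for v in self.voxel_dims):
            raise ValueError("voxel_dims must be 3 positive lengths")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class ParcellationAtlas:
    """Integer label volume plus one record per region.

    ``regions`` holds columns ``region_id`` (positive int, matching the label
    grid), ``name``, ``hemisphere`` ('L'/'R') and unit-sphere centroid
    coordinates ``cx, cy, cz``.
    """

    labels: np.ndarray
    regions: pd.DataFrame

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D integer grid")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must have an integer dtype")
        required = {"region_id", "name", "hemisphere", "cx", "cy", "cz"}
        missing = required - set(self.regions.columns)
        if missing:
            raise ValueError(f"region table missing columns: {sorted(missing)}")
        grid_ids = set(np.unique(self.labels)) - {0}
        table_ids = set(self.regions["region_id"].astype(int))
        if grid_ids != table_ids:
            raise ValueError(
                f"label grid / region table mismatch: only-in-grid={sorted(grid_ids - table_ids)}, "
                f"only-in-table={sorted(table_ids - grid_ids)}"
            )
        norms = np.linalg.norm(self.regions[["cx", "cy", "cz"]].to_numpy(float), axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("region centroids must have unit norm")

    @property
    def region_ids(self) -> np.ndarray:
        return self.regions["region_id"].to_numpy(int)

    def centroids(self, hemisphere: str | None = None) -> np.ndarray:
        """Unit-sphere centroids, optionally restricted to one hemisphere."""
        df = self.regions
        if hemisphere is not None:
            df = df[df["hemisphere"] == hemisphere]
        return df[["cx", "cy", "cz"]].to_numpy(float)

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


@dataclass
class ReHoMap:
    """Voxelwise Kendall's W values plus the neighborhood size used."""

    values: np.ndarray
    neighbor_counts: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.neighbor_counts = np.asarray(self.neighbor_counts)
        if self.values.shape != self.neighbor_counts.shape:
            raise ValueError("values and neighbor_counts must share a shape")
        defined = np.isfinite(self.values)
        vals = self.values[defined]
        if vals.size and (vals.min() < -1e-12 or vals.max() > 1 + 1e-12):
            raise ValueError("defined ReHo values must lie in [0, 1]")


@dataclass
class RegionalMeasureTable:
    """Subjects x regions measures joined to covariates and diagnosis.

    ``subjects`` has columns ``subject_id, age, sex, dx, severity`` (sex and
    dx coded 0/1; severity may be NaN, typically for controls).  ``measures``
    is row-aligned with ``subjects`` and has one column per region.
    """

    subjects: pd.DataFrame
    measures: pd.DataFrame
    measure_name: str = "reho"

    def __post_init__(self) -> None:
        if len(self.subjects) != len(self.measures):
            raise ValueError("subjects and measures must have the same number of rows")
        if self.subjects["subject_id"].duplicated().any():
            dupes = self.subjects.loc[self.subjects["subject_id"].duplicated(), "subject_id"]
            raise ValueError(f"duplicated subject_id values: {sorted(set(dupes))}")
        for col in ("subject_id", "age", "sex", "dx"):
            if col not in self.subjects.columns:
                raise ValueError(f"subjects table missing column {col!r}")
        if "severity" not in self.subjects.columns:
            self.subjects = self.subjects.assign(severity=np.nan)
        self.subjects = self.subjects.reset_index(drop=True)
        self.measures = self.measures.reset_index(drop=True)

    @property
    def region_ids(self) -> list:
        return list(self.measures.columns)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def to_frame(self) -> pd.DataFrame:
        """Single wide table: covariate columns followed by region columns."""
        return pd.concat([self.subjects[SUBJECT_COLUMNS], self.measures], axis=1)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, measure_name: str = "reho") -> "RegionalMeasureTable":
        meta = [c for c in SUBJECT_COLUMNS if c in frame.columns]
        regions = [c for c in frame.columns if c not in SUBJECT_COLUMNS]
        return cls(frame[meta].copy(), frame[regions].copy(), measure_name=measure_name)

    def with_measures(self, measures: pd.DataFrame) -> "RegionalMeasureTable":
        return RegionalMeasureTable(
            self.subjects.copy(), measures.reset_index(drop=True), self.measure_name
        )


@dataclass
class TemplateVector:
    """Per-region template effect sizes (case - control Cohen's d).

    Deficits are negative by convention, matching case-control maps where the
    case group is impaired.  Region names are canonicalized on construction.
    """

    values: pd.Series
    source_label: str = "template"

    def __post_init__(self) -> None:
        s = pd.Series(self.values, dtype=float)
        s.index = [canonical_region_name(r) for r in s.index]
        if s.index.duplicated().any():
            raise ValueError("duplicate region names in template")
        if len(s) < 3:
            raise ValueError("template needs at least 3 regions")
        if not np.isfinite(s.to_numpy()).all():
            raise ValueError("template values must be finite")
        if float(np.std(s.to_numpy())) == 0.0:
            raise ValueError("template has zero variance across regions")
        self.values = s

    @property
    def regions(self) -> list:
        return list(self.values.index)
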