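"""File I/O: NIfTI-1 volumes via nibabel, TSV tables, YAML configs.

TSV conventions (canonical interchange format): tab-delimited, UTF-8,
'.' decimal separator, missing values spelled ``NA``.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .containers import ParcellationAtlas, RegionalMeasureTable, TemplateVector, VolumeTimeSeries

__all__ = [
    "read_bold",
    "write_volume",
    "read_atlas",
    "write_atlas",
    "read_regional_table",
    "write_regional_table",
    "read_template",
    "write_template",
    "read_tsv",
    "write_tsv",
    "read_yaml",
    "write_json",
]

_TSV_KW = dict(sep="\t", na_rep="NA", index=False)


def write_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, float_format="%.10g", **_TSV_KW)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)


def write_volume(data: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    """Write a 3-D or 4-D array as NIfTI-1; identity affine unless given."""
    if affine is None:
        affine = np.eye(4)
    arr = np.asarray(data)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.int32)
    else:
        arr = arr.astype(np.float32)
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def read_bold(bold_path, mask_path=None) -> VolumeTimeSeries:
    img = nib.load(str(bold_path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{bold_path}: expected 4-D BOLD, got shape {data.shape}")
    zooms = img.header.get_zooms()
    voxel_dims = tuple(float(z) for z in zooms[:3])
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = np.isfinite(data).all(axis=3) & (np.abs(data).sum(axis=3) > 0)
    return VolumeTimeSeries(data, mask, voxel_dims)


def write_atlas(atlas: ParcellationAtlas, labels_path, regions_path) -> None:
    write_volume(atlas.labels, labels_path)
    out = atlas.regions.rename(columns={"name": "region"})
    write_tsv(out[["region_id", "region", "hemisphere", "cx", "cy", "cz"]], regions_path)


def read_atlas(labels_path, regions_path) -> ParcellationAtlas:
    labels = np.asarray(nib.load(str(labels_path)).dataobj).astype(np.int32)
    regions = read_tsv(regions_path).rename(columns={"region": "name"})
    return ParcellationAtlas(labels, regions)


def write_regional_table(table: RegionalMeasureTable, path) -> None:
    write_tsv(table.to_frame(), path)


def read_regional_table(path, measure_name: str = "reho") -> RegionalMeasureTable:
    return RegionalMeasureTable.from_frame(read_tsv(path), measure_name=measure_name)


def write_template(template: TemplateVector, path) -> None:
    write_tsv(
        pd.DataFrame({"region": template.values.index, "d": template.values.to_numpy()}), path
    )


def read_template(path, source_label: str | None = None) -> TemplateVector:
    df = read_tsv(path)
    if "region" not in df.columns or "d" not in df.columns:
        raise ValueError(f"{path}: template TSV needs columns 'region' and 'd'")
    return TemplateVector(
        pd.Series(df["d"].to_numpy(float), index=df["region"]),
        source_label=source_label or str(path),
    )


def read_yaml(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}


def write_json(obj, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
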