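"""Regional homogeneity (ReHo): voxelwise Kendall's coefficient of concordance.

ReHo quantifies the temporal coherence of a voxel's BOLD time series with its
3x3x3 neighborhood (27 voxels including the center).  For K series of length
T, each series is converted to midranks over time and Kendall's W is

    W = 12 * S / (K^2 (T^3 - T) - K * sum_k C_k),
    S = sum_t (R_t - K (T + 1) / 2)^2,

where R_t is the rank sum at timepoint t and C_k = sum_groups (g^3 - g) is
the tie correction of series k.  W lies in [0, 1]: 1 for perfect concordance,
with null expectation 1/K under independence.

Mask edges are handled by computing W over whichever neighbors fall inside
the mask (K < 27 allowed, floored at ``min_neighbors``); constant series
carry no rank information and are excluded from the neighborhood before W is
computed.  The per-voxel neighborhood size actually used is recorded.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ParcellationAtlas, RegionalMeasureTable, ReHoMap, VolumeTimeSeries

__all__ = [
    "kendalls_w",
    "reho_map",
    "extract_regional_means",
    "average_hemispheres",
]


def _tie_correction(ranks: np.ndarray) -> np.ndarray:
    """C_k = sum over tied groups of (g^3 - g), per series (last axis = time)."""
    srt = np.sort(ranks, axis=-1)
    # run lengths of equal consecutive midranks
    out = np.zeros(ranks.shape[:-1], dtype=float)
    T = ranks.shape[-1]
    # midranks are exact multiples of 0.5, so exact equality is safe
    same = np.concatenate(
        [np.zeros(ranks.shape[:-1] + (1,), bool), srt[..., 1:] == srt[..., :-1]],
        axis=-1,
    )
    # group sizes via cumulative trick: for each position, size of the run ending there
    run = np.zeros(ranks.shape, dtype=int)
    for t in range(T):
        if t == 0:
            run[..., 0] = 1
        else:
            run[..., t] = np.where(same[..., t], run[..., t - 1] + 1, 1)
    # a run of final length g contributes g^3 - g exactly once: count it at the
    # last element of the run (where the next position starts a new run)
    is_end = np.concatenate(
        [~same[..., 1:], np.ones(ranks.shape[:-1] + (1,), bool)], axis=-1
    )
    g = np.where(is_end, run, 0).astype(float)
    out = (g**3 - g).sum(axis=-1)
    return out


def kendalls_w(series: np.ndarray) -> float:
    """Kendall's coefficient of concordance for K time series of length T.

    Parameters
    ----------
    series : array-like, shape (K, T)
        K >= 2 series over T >= 3 timepoints; all values finite.

    Returns
    -------
    float
        W in [0, 1]; NaN if every series is fully tied (denominator zero).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 2:
        raise ValueError(f"expected a (K, T) array, got shape {x.shape}")
    K, T = x.shape
    if K < 2:
        raise ValueError(f"need at least 2 series, got {K}")
    if T < 3:
        raise ValueError(f"need at least 3 timepoints, got {T}")
    if not np.isfinite(x).all():
        raise ValueError("non-finite values in input series")

    ranks = rankdata(x, axis=1)  # midranks
    R = ranks.sum(axis=0)
    S = float(((R - K * (T + 1) / 2.0) ** 2).sum())
    C = _tie_correction(ranks).sum()
    denom = K * K * (T**3 - T) - K * C
    if denom <= 0:
        return float("nan")
    return 12.0 * S / denom


def reho_map(vts: VolumeTimeSeries, min_neighbors: int = 2) -> ReHoMap:
    """Voxelwise ReHo over 3x3x3 in-mask neighborhoods.

    For every in-mask voxel, Kendall's W is computed over the in-mask,
    non-constant voxels of its 27-voxel block (itself included).  Voxels with
    fewer than ``min_neighbors`` usable series, and all out-of-mask voxels,
    get NaN.

    Returns
    -------
    ReHoMap
        ``values``: W per voxel; ``neighbor_counts``: series count K used.
    """
    if min_neighbors < 2:
        raise ValueError("min_neighbors must be >= 2")
    mask = vts.mask
    data = vts.data
    T = vts.n_timepoints

    # constant (all-tied) series are excluded: no rank information
    valid = mask & (np.nanmax(data, axis=3) > np.nanmin(data, axis=3))

    ranks = np.zeros(data.shape, dtype=float)
    C = np.zeros(mask.shape, dtype=float)
    if valid.any():
        v = data[valid]
        rv = rankdata(v, axis=1)
        ranks[valid] = rv
        C[valid] = _tie_correction(rv)

    shape = mask.shape
    rank_sum = np.zeros(data.shape, dtype=float)
    k_sum = np.zeros(shape, dtype=np.int32)
    c_sum = np.zeros(shape, dtype=float)
    validf = valid.astype(float)

    def _shift_slices(d):
        if d > 0:
            return slice(d, None), slice(None, -d)
        if d < 0:
            return slice(None, d), slice(-d, None)
        return slice(None), slice(None)

    for dx in (-1, 0, 1):
        sx_dst, sx_src = _shift_slices(dx)
        for dy in (-1, 0, 1):
            sy_dst, sy_src = _shift_slices(dy)
            for dz in (-1, 0, 1):
                sz_dst, sz_src = _shift_slices(dz)
                dst = (sx_dst, sy_dst, sz_dst)
                src = (sx_src, sy_src, sz_src)
                rank_sum[dst] += ranks[src] * validf[src][..., None]
                k_sum[dst] += valid[src]
                c_sum[dst] += C[src]

    K = k_sum.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        S = ((rank_sum - K[..., None] * (T + 1) / 2.0) ** 2).sum(axis=3)
        denom = K * K * (T**3 - T) - K * c_sum
        W = 12.0 * S / denom

    defined = mask & (k_sum >= min_neighbors) & (denom > 0)
    W[~defined] = np.nan
    counts = np.where(mask, k_sum, 0)
    return ReHoMap(values=W, neighbor_counts=counts)


def extract_regional_means(map3d: np.ndarray, atlas: ParcellationAtlas) -> pd.Series:
    """Mean of defined (non-NaN) voxel values per atlas region.

    Background (label 0) never contributes.  A region whose voxels are all
    undefined yields NaN and a warning.
    """
    vol = np.asarray(map3d, dtype=float)
    if vol.shape != atlas.labels.shape:
        raise ValueError(
            f"map shape {vol.shape} does not match atlas shape {atlas.labels.shape}"
        )
    out = {}
    for _, rec in atlas.regions.iterrows():
        rid = int(rec["region_id"])
        vals = vol[atlas.labels == rid]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            warnings.warn(
                f"region {rec['name']} ({rec['hemisphere']}, id={rid}) has no defined voxels",
                RuntimeWarning,
                stacklevel=2,
            )
            out[rid] = np.nan
        else:
            out[rid] = float(vals.mean())
    return pd.Series(out, name="regional_mean")


def average_hemispheres(
    table: RegionalMeasureTable, regions: pd.DataFrame
) -> RegionalMeasureTable:
    """Collapse left/right region columns to bilateral means per subject.

    ``regions`` maps each measure column to a region ``name`` and
    ``hemisphere``; columns are keyed by ``region_id`` or by
    ``"{name}_{hemisphere}"``.  The bilateral value is (L + R) / 2; if either
    side is NaN the result is NaN.  Unpaired names raise with the orphan list.
    """
    by_name: dict[str, dict[str, object]] = {}
    for _, rec in regions.iterrows():
        col = rec["region_id"] if rec["region_id"] in table.measures.columns else None
        if col is None:
            alt = f"{rec['name']}_{rec['hemisphere']}"
            col = alt if alt in table.measures.columns else None
        if col is None:
            raise ValueError(f"no measure column found for region {rec['name']}/{rec['hemisphere']}")
        by_name.setdefault(rec["name"], {})[rec["hemisphere"]] = col

    orphans = sorted(n for n, sides in by_name.items() if set(sides) != {"L", "R"})
    if orphans:
        raise ValueError(f"regions without an L/R pair: {orphans}")

    merged = {
        name: (
            table.measures[sides["L"]].to_numpy(float)
            + table.measures[sides["R"]].to_numpy(float)
        )
        / 2.0
        for name, sides in by_name.items()
    }
    return table.with_measures(pd.DataFrame(merged))
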