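"""Synthetic cohorts, atlases, and BOLD-like volumes for end-to-end testing.

Real resting-state case-control samples with planted, known ground truth do
not exist, so every pipeline input is generated here: a mirrored block
parcellation standing in for a bilateral cortical atlas, 4-D time series
with a controllable shared-signal fraction per region (which maps directly
onto ReHo), and regional cohort tables with planted per-region standardized
effects, additive age/sex covariate structure and severity ratings coupled
to each case's individual expression of the planted pattern.

All generators are pure functions of their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ParcellationAtlas, RegionalMeasureTable, VolumeTimeSeries

__all__ = ["SimulationConfig", "make_toy_atlas", "simulate_bold", "simulate_regional_cohort"]


def _as_region_vector(value, n_regions: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_regions, float(arr))
    if arr.shape != (n_regions,):
        raise ValueError(f"{name} must be a scalar or length-{n_regions} vector")
    return arr


@dataclass
class SimulationConfig:
    """Parameters of a two-group regional cohort simulation.

    The planted measure model for subject i, region j is

        x_ij = region_mean_j + beta_age_j * age_i + beta_sex_j * sex_i
               + dx_i * planted_d_j * region_sd_j + eps_ij,

    with eps_ij ~ N(0, region_sd_j^2), ages ~ Uniform(20, 70), sex ~
    Bernoulli(0.5) coded 0/1.  ``planted_d`` is therefore recovered (in
    expectation) as the per-region case-control Cohen's d.  Severity is
    generated for cases only, as a noisy monotone function of each case's
    pattern-expression score sum_j planted_d_j * z_ij, targeting a Pearson
    correlation of ``severity_link``.

    ``age_case_shift`` adds a constant to case ages (default 0), which
    produces an age-confounded design for testing covariate adjustment.
    """

    n_cases: int
    n_controls: int
    region_count: int = 34
    planted_d: object = 0.0
    beta_age: object = 0.0
    beta_sex: object = 0.0
    region_mean: object = 1.0
    region_sd: object = 0.15
    severity_link: float = 0.4
    age_case_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 cases and 2 controls")
        if self.region_count < 1:
            raise ValueError("region_count must be positive")
        if not -1.0 <= self.severity_link <= 1.0:
            raise ValueError("severity_link must lie in [-1, 1]")
        R = self.region_count
        self.planted_d = _as_region_vector(self.planted_d, R, "planted_d")
        self.beta_age = _as_region_vector(self.beta_age, R, "beta_age")
        self.beta_sex = _as_region_vector(self.beta_sex, R, "beta_sex")
        self.region_mean = _as_region_vector(self.region_mean, R, "region_mean")
        self.region_sd = _as_region_vector(self.region_sd, R, "region_sd")
        if not np.isfinite(self.planted_d).all():
            raise ValueError("planted_d must be finite")
        if (self.region_sd <= 0).any():
            raise ValueError("region_sd must be strictly positive")

    @property
    def region_names(self) -> list:
        return [f"region{j + 1:02d}" for j in range(self.region_count)]


def make_toy_atlas(grid_shape, n_region_pairs: int, seed: int = 0) -> ParcellationAtlas:
    """Mirrored-block parcellation on a rectangular grid.

    The left half of the x-axis is partitioned into ``n_region_pairs``
    contiguous blocks; the right hemisphere mirrors them across the
    mid-sagittal plane (odd grids leave the central plane as background).
    Region ids are 1..P for left regions and P+1..2P for their right
    partners; centroids are mean voxel coordinates relative to the grid
    center, projected to the unit sphere, so L/R pairs mirror exactly.
    """
    nx, ny, nz = (int(s) for s in grid_shape)
    if min(nx, ny, nz) < 1 or n_region_pairs < 1:
        raise ValueError("grid dimensions and n_region_pairs must be positive")
    if nx * ny * nz < 8 * n_region_pairs:
        raise ValueError(
            f"grid {grid_shape} too small for {n_region_pairs} region pairs "
            f"(need >= {8 * n_region_pairs} voxels)"
        )
    half = nx // 2
    left = np.stack(
        np.meshgrid(np.arange(half), np.arange(ny), np.arange(nz), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    if len(left) < 4 * n_region_pairs:
        raise ValueError(
            f"left hemisphere of grid {grid_shape} has {len(left)} voxels; "
            f"{n_region_pairs} pairs need >= {4 * n_region_pairs}"
        )
    # contiguous chunks along a (z, y, x) raster give compact-ish blocks
    order = np.lexsort((left[:, 0], left[:, 1], left[:, 2]))
    chunks = np.array_split(left[order], n_region_pairs)

    rng = np.random.default_rng(seed)
    ids = rng.permutation(n_region_pairs) + 1  # which block gets which id

    labels = np.zeros((nx, ny, nz), dtype=np.int32)
    center = (np.array([nx, ny, nz]) - 1) / 2.0
    records = []
    for block, left_id in zip(chunks, ids):
        right_id = int(left_id) + n_region_pairs
        xs, ys, zs = block[:, 0], block[:, 1], block[:, 2]
        labels[xs, ys, zs] = left_id
        labels[nx - 1 - xs, ys, zs] = right_id
        c = block.mean(axis=0) - center
        c = c / np.linalg.norm(c)
        name = f"region{int(left_id):02d}"
        records.append((int(left_id), name, "L", *c))
        records.append((right_id, name, "R", -c[0], c[1], c[2]))
    regions = pd.DataFrame(
        sorted(records), columns=["region_id", "name", "hemisphere", "cx", "cy", "cz"]
    )
    return ParcellationAtlas(labels, regions)


def simulate_bold(
    atlas: ParcellationAtlas,
    n_timepoints: int,
    coherence,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> VolumeTimeSeries:
    """4-D series with a controllable shared-signal fraction per region.

    Within region j, each voxel's series is

        sqrt(coherence_j) * shared_j(t) + sqrt(1 - coherence_j) * private(t),

    where shared_j and private are independent standard Gaussian innovations
    scaled by ``noise_sd``.  ``coherence_j`` in [0, 1) is the fraction of
    variance shared across the region: 0 gives pairwise-independent voxels
    (ReHo at its 1/K null), values near 1 drive regional ReHo toward 1.
    Background voxels receive independent noise; the mask is ``labels > 0``.
    """
    if n_timepoints < 10:
        raise ValueError("need at least 10 timepoints")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    region_ids = atlas.region_ids
    coh = np.asarray(coherence, dtype=float)
    if coh.ndim == 0:
        coh = np.full(len(region_ids), float(coh))
    if coh.shape != (len(region_ids),):
        raise ValueError(f"coherence must be scalar or one value per region ({len(region_ids)})")
    if (coh < 0).any() or (coh >= 1).any():
        raise ValueError("coherence values must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    labels = atlas.labels
    data = rng.normal(0.0, noise_sd, size=labels.shape + (n_timepoints,))
    shared = rng.normal(0.0, noise_sd, size=(len(region_ids), n_timepoints))
    for j, rid in enumerate(region_ids):
        sel = labels == rid
        data[sel] = np.sqrt(coh[j]) * shared[j] + np.sqrt(1.0 - coh[j]) * data[sel]
    return VolumeTimeSeries(data, labels > 0)


def simulate_regional_cohort(config: SimulationConfig) -> RegionalMeasureTable:
    """Two-group regional measure table with planted effects (see config)."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cases + cfg.n_controls
    dx = np.concatenate([np.ones(cfg.n_cases, int), np.zeros(cfg.n_controls, int)])
    age = rng.uniform(20.0, 70.0, size=n) + cfg.age_case_shift * dx
    sex = rng.integers(0, 2, size=n)

    eps = rng.normal(0.0, 1.0, size=(n, cfg.region_count)) * cfg.region_sd
    x = (
        cfg.region_mean
        + np.outer(age, cfg.beta_age)
        + np.outer(sex, cfg.beta_sex)
        + np.outer(dx, cfg.planted_d * cfg.region_sd)
        + eps
    )

    # severity: noisy monotone (affine) function of the case's expression of
    # the planted pattern, targeting corr = severity_link
    severity = np.full(n, np.nan)
    case = dx == 1
    if case.any():
        z = (eps[case] / cfg.region_sd) + cfg.planted_d  # deviation in SD units
        score = z @ cfg.planted_d
        sd = score.std()
        std_score = (score - score.mean()) / sd if sd > 0 else np.zeros(case.sum())
        link = cfg.severity_link
        latent = link * std_score + np.sqrt(1.0 - link**2) * rng.normal(size=case.sum())
        severity[case] = 18.0 + 6.0 * latent  # HDRS-like scale, monotone in latent

    subjects = pd.DataFrame(
        {
            "subject_id": [f"sub-{i + 1:04d}" for i in range(n)],
            "age": age,
            "sex": sex,
            "dx": dx,
            "severity": severity,
        }
    )
    measures = pd.DataFrame(x, columns=cfg.region_names)
    return RegionalMeasureTable(subjects, measures, measure_name="synthetic")
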