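"""Spatial agreement between regional effect-size maps.

Pearson correlation across parcels overstates significance when maps share
spatial structure, so map-level inference uses the spin permutation test:
parcel centroids on the unit sphere are rotated by uniform random rotations,
each parcel is reassigned the value of the parcel whose original centroid is
nearest to its rotated position (duplicates allowed), and the observed
correlation is compared with the rotated null.  Bilateral-averaged maps are
spun on single-hemisphere centroids.

Correlations from different cohort pairs are compared with Fisher's
r-to-z transform:

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MapCorrelationResult",
    "pearson_map_correlation",
    "random_rotation",
    "spin_permutation_p",
    "compare_correlations_fisher",
]


@dataclass
class MapCorrelationResult:
    """Observed map correlation with its spin-permutation null."""

    r: float
    n_regions: int
    p_spin: float
    n_perm: int
    null_distribution: np.ndarray
    seed: int

    def as_dict(self) -> dict:
        return {
            "r": self.r,
            "n_regions": self.n_regions,
            "p_spin": self.p_spin,
            "n_perm": self.n_perm,
            "seed": self.seed,
        }


def _complete_pairs(map_a, map_b):
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("maps must be 1-D vectors over the same ordered region set")
    ok = np.isfinite(a) & np.isfinite(b)
    return a, b, ok


def pearson_map_correlation(map_a, map_b) -> float:
    """Pearson correlation over regions, pairwise-complete on NaNs."""
    a, b, ok = _complete_pairs(map_a, map_b)
    if ok.sum() < 3:
        raise ValueError(f"need >= 3 complete region pairs, have {int(ok.sum())}")
    aa, bb = a[ok], b[ok]
    if aa.std() == 0 or bb.std() == 0:
        raise ValueError("zero variance in a map over the complete regions")
    return float(np.corrcoef(aa, bb)[0, 1])


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """One rotation matrix drawn uniformly (Haar) from SO(3).

    QR-orthonormalizes a Gaussian 3x3, fixes column signs by the sign of R's
    diagonal (Haar on O(3)), then flips one column if det = -1.
    """
    g = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(g)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _spin_assignments(centroids: np.ndarray, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """(n_perm, R) indices: region i takes the value of assignment[p, i]."""
    rots = np.stack([random_rotation(rng) for _ in range(n_perm)])  # (P,3,3)
    rotated = np.einsum("pij,rj->pri", rots, centroids)  # (P,R,3)
    # nearest ORIGINAL centroid to each rotated centroid
    d2 = ((rotated[:, :, None, :] - centroids[None, None, :, :]) ** 2).sum(axis=-1)
    return d2.argmin(axis=-1)


def spin_permutation_p(
    map_a, map_b, centroids, n_perm: int = 999, seed: int = 0
) -> MapCorrelationResult:
    """Two-sided spin-permutation p for the map correlation.

    Only ``map_a`` is permuted (the standard construction).  p uses the +1
    smoothing p = (1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1), so it is never
    zero and never below 1/(n_perm+1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    cent = np.asarray(centroids, dtype=float)
    a, b, ok = _complete_pairs(map_a, map_b)
    if cent.shape != (len(a), 3):
        raise ValueError(f"centroids must be ({len(a)}, 3), got {cent.shape}")
    if not np.allclose(np.linalg.norm(cent, axis=1), 1.0, atol=1e-6):
        raise ValueError("centroids must be unit vectors")
    if len(np.unique(np.round(cent, 9), axis=0)) < len(cent):
        raise ValueError("duplicate centroids")
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} regions dropped pairwise before spinning",
            RuntimeWarning,
            stacklevel=2,
        )
    a, b, cent = a[ok], b[ok], cent[ok]
    r_obs = pearson_map_correlation(a, b)

    rng = np.random.default_rng(seed)
    assign = _spin_assignments(cent, n_perm, rng)
    perm_a = a[assign]  # (n_perm, R)

    # vectorized Pearson of each permuted map_a against fixed map_b
    pa = perm_a - perm_a.mean(axis=1, keepdims=True)
    pb = b - b.mean()
    denom = np.sqrt((pa**2).sum(axis=1) * (pb**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r_null = (pa @ pb) / denom
    r_null = np.where(np.isfinite(r_null), r_null, 0.0)  # degenerate spins count as r=0

    p = (1.0 + np.sum(np.abs(r_null) >= abs(r_obs))) / (n_perm + 1.0)
    return MapCorrelationResult(
        r=r_obs,
        n_regions=int(len(a)),
        p_spin=float(p),
        n_perm=int(n_perm),
        null_distribution=r_null,
        seed=int(seed),
    )


def compare_correlations_fisher(r1: float, n1: int, r2: float, n2: int) -> dict:
    """Fisher r-to-z comparison of two independent correlations.

    Returns {'z', 'p'} with p the two-sided standard-normal tail.
    """
    if not (abs(r1) < 1 and abs(r2) < 1):
        raise ValueError("correlations must satisfy |r| < 1 (atanh is infinite at 1)")
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 in both samples")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return {"z": float(z), "p": float(p)}
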