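"""Permutation inference for regional brain maps.

Cortical maps live on a sphere, so plain permutation destroys their spatial
autocorrelation and inflates false positives. The spin test preserves it:
parcel coordinates are rotated by a Haar-uniform random rotation and each
original parcel is reassigned the value of a rotated parcel through the
minimum-total-distance assignment (Hungarian algorithm). Because the
parcellation covers one shared sphere (hemisphere is just the sign of x),
a single global rotation keeps every rotated parcel close to an occupied
position; per-hemisphere rotations of half-spheres would push points into
unoccupied territory and distort the assignment. Maps without a spherical
geometry (brainstem nuclei, arbitrary annotations) fall back to plain
label shuffling. p-values are two-sided with the add-one convention
``p = (1 + #{|null| >= |obs|}) / (1 + n_reps)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist
from scipy.stats import special_ortho_group
from statsmodels.stats.multitest import multipletests

from .exceptions import ParameterError, ShapeError
from .parcellation import ParcellationScheme


@dataclass
class SpinNull:
    """Precomputed spin permutations of the cortical regions.

    ``permutations[r]`` is an index array pi such that ``values[pi]`` is
    the r-th spun map; rows are bijections of 0..n_cortex-1. The
    hemisphere blocks record which cortex-order indices belong to each
    hemisphere; the rotation is global, so a value may cross hemispheres.
    """

    permutations: np.ndarray     # n_reps x n_cortex
    hemisphere_blocks: dict      # {"L": idx, "R": idx} into the cortex order
    seed: int

    @property
    def n_reps(self) -> int:
        return self.permutations.shape[0]


def generate_spins(scheme: ParcellationScheme, n_reps: int = 10000,
                   seed: int = 0) -> SpinNull:
    """Build a spin-permutation table for the cortical regions of a scheme.

    Each repetition draws one Haar-uniform rotation of the full cortical
    sphere and solves the assignment between original and rotated
    spherical coordinates. A rotated parcel may land in either hemisphere:
    the parcellation tiles a single shared sphere, so the global rotation
    is the measure-preserving symmetry of its geometry.
    """
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    ctx = scheme.indices("cortex")
    coords = scheme.sphere_coords[ctx]
    if np.isnan(coords).any():
        raise ParameterError("cortical regions lack sphere coordinates")
    hemi = scheme.table.loc[ctx, "hemisphere"].to_numpy()
    if set(hemi) - {"L", "R"}:
        raise ParameterError("cortical spin test requires L/R hemispheres only")
    blocks = {h: np.flatnonzero(hemi == h) for h in ("L", "R")}

    rng = np.random.default_rng(seed)
    perms = np.empty((n_reps, ctx.size), dtype=np.intp)
    for r in range(n_reps):
        R = special_ortho_group.rvs(3, random_state=rng)
        rotated = coords @ R.T
        rows, cols = linear_sum_assignment(cdist(coords, rotated))
        perm = np.empty(ctx.size, dtype=np.intp)
        perm[rows] = cols
        perms[r] = perm
    return SpinNull(perms, blocks, seed)


def _null_correlations(map_a: np.ndarray, map_b: np.ndarray,
                       perms: np.ndarray, stat: str) -> np.ndarray:
    if stat == "spearman":
        map_a = stats.rankdata(map_a)
        map_b = stats.rankdata(map_b)
    elif stat != "pearson":
        raise ParameterError(f"unknown statistic {stat!r}")
    A = map_a[perms].astype(float)
    A = A - A.mean(axis=1, keepdims=True)
    b = map_b - map_b.mean()
    denom = np.linalg.norm(A, axis=1) * np.linalg.norm(b)
    return (A @ b) / denom


def spin_pvalue(map_a: np.ndarray, map_b: np.ndarray, spins: SpinNull,
                stat: str = "pearson") -> tuple[float, float]:
    """Observed correlation of two cortical maps and its two-sided spin
    p-value (map_a is spun against fixed map_b)."""
    map_a = np.asarray(map_a, dtype=float)
    map_b = np.asarray(map_b, dtype=float)
    if map_a.shape != map_b.shape or map_a.size != spins.permutations.shape[1]:
        raise ShapeError("maps must match the spun cortical scheme")
    if np.ptp(map_a) == 0 or np.ptp(map_b) == 0:
        warnings.warn("constant map: correlation undefined", stacklevel=2)
        return np.nan, np.nan
    if stat == "spearman":
        observed = float(stats.spearmanr(map_a, map_b)[0])
    else:
        observed = float(stats.pearsonr(map_a, map_b)[0])
    null = _null_correlations(map_a, map_b, spins.permutations, stat)
    p = (1 + int(np.sum(np.abs(null) >= abs(observed)))) / (1 + spins.n_reps)
    return observed, float(p)


def permutation_null(map_a: np.ndarray, map_b: np.ndarray, n_reps: int = 10000,
                     seed: int = 0, stat: str = "pearson") -> tuple[float, float]:
    """Plain label-shuffle permutation test (for maps without a sphere)."""
    map_a = np.asarray(map_a, dtype=float)
    map_b = np.asarray(map_b, dtype=float)
    if map_a.shape != map_b.shape:
        raise ShapeError("maps must have equal length")
    if n_reps < 1:
        raise ParameterError("n_reps must be >= 1")
    if np.ptp(map_a) == 0 or np.ptp(map_b) == 0:
        warnings.warn("constant map: correlation undefined", stacklevel=2)
        return np.nan, np.nan
    rng = np.random.default_rng(seed)
    perms = np.stack([rng.permutation(map_a.size) for _ in range(n_reps)])
    if stat == "spearman":
        observed = float(stats.spearmanr(map_a, map_b)[0])
    else:
        observed = float(stats.pearsonr(map_a, map_b)[0])
    null = _null_correlations(map_a, map_b, perms, stat)
    p = (1 + int(np.sum(np.abs(null) >= abs(observed)))) / (1 + n_reps)
    return observed, float(p)


def fdr_bh(pvalues, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject
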