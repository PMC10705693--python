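"""Multiple linear regression and dominance analysis.

Dominance analysis partitions a regression's explained variance among
predictors: the total dominance of predictor *i* is the average, over
subset sizes and over subsets of that size not containing *i*, of the
increase in fit when *i* is added -- i.e. the Shapley value of the fit
function over predictor subsets. With the fit measured as adjusted R^2
(whose empty-model value is 0), Shapley efficiency makes the dominances
sum exactly to the full model's adjusted R^2; normalizing by that total
gives percent contributions that sum to 100.

All 2^p - 1 submodels are enumerated (p <= 20 enforced; no approximation is
silently substituted). Submodel R^2 values are computed from the
correlation matrix of the z-scored design, so the enumeration costs one
p x p solve per subset.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .exceptions import ParameterError
from .parcellation import AnnotationTable


@dataclass
class DominanceResult:
    predictors: list[str]
    r2_full: float
    r2_adj_full: float
    total_dominance: np.ndarray
    percent_contribution: np.ndarray
    n_predictors: int
    n_observations: int


def _as_matrix(y, X):
    if isinstance(y, AnnotationTable):
        names_y = y.map_name
        y = y.values
    else:
        names_y = "y"
    cols, names = [], []
    for i, x in enumerate(X):
        if isinstance(x, AnnotationTable):
            cols.append(x.values)
            names.append(x.map_name)
        else:
            cols.append(np.asarray(x, dtype=float))
            names.append(f"x{i}")
    Xm = np.column_stack(cols)
    return np.asarray(y, dtype=float).ravel(), Xm, names, names_y


def _zscore_cols(M: np.ndarray) -> np.ndarray:
    sd = M.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ParameterError("constant predictor or response cannot be z-scored")
    return (M - M.mean(axis=0)) / sd


def fit_mlr(y, X) -> tuple[np.ndarray, float, float]:
    """OLS of a (z-scored) response on z-scored predictors.

    Returns (coefficients, R^2, adjusted R^2). Rank-deficient designs raise
    an error naming the offending predictors.
    """
    yv, Xm, names, _ = _as_matrix(y, X)
    n, p = Xm.shape
    if n <= p + 1:
        raise ParameterError(f"need n > p + 1 observations (n={n}, p={p})")
    Xz = _zscore_cols(Xm)
    yz = _zscore_cols(yv[:, None]).ravel()
    rank = np.linalg.matrix_rank(Xz)
    if rank < p:
        _, R = np.linalg.qr(Xz)
        bad = [names[j] for j in np.flatnonzero(
            np.abs(np.diag(R)) < 1e-8 * np.abs(np.diag(R)).max())]
        raise ParameterError(f"collinear predictors: {bad or names}")
    design = np.column_stack([np.ones(n), Xz])
    beta, *_ = np.linalg.lstsq(design, yz, rcond=None)
    resid = yz - design @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((yz - yz.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return beta[1:], r2, r2_adj


def _subset_r2(corr_xx: np.ndarray, corr_xy: np.ndarray,
               subset: tuple[int, ...]) -> float:
    idx = list(subset)
    r = corr_xy[idx]
    beta = np.linalg.solve(corr_xx[np.ix_(idx, idx)], r)
    return float(r @ beta)


def _adjust(r2: float, n: int, k: int) -> float:
    if k == 0:
        return 0.0
    return 1.0 - (1.0 - r2) * (n - 1) / (n - k - 1)


def dominance_analysis(y, X, use_adjusted: bool = True,
                       averaging: str = "within_sizes") -> DominanceResult:
    """Complete dominance analysis over all 2^p - 1 predictor subsets.

    ``averaging="within_sizes"`` (default) averages incremental fit within
    each subset size and then across sizes (the Shapley convention);
    ``"flat"`` averages over all submodels with equal weight. The fit is
    adjusted R^2 by default (``use_adjusted=False`` uses raw R^2, whose
    dominances sum to the full model's raw R^2 instead).
    """
    yv, Xm, names, _ = _as_matrix(y, X)
    n, p = Xm.shape
    if p > 20:
        raise ParameterError(
            f"p={p} > 20: full submodel enumeration refused")
    if averaging not in ("within_sizes", "flat"):
        raise ParameterError(f"unknown averaging {averaging!r}")
    _, r2_full, r2_adj_full = fit_mlr(yv, [Xm[:, j] for j in range(p)])

    Xz = _zscore_cols(Xm)
    yz = _zscore_cols(yv[:, None]).ravel()
    corr_xx = Xz.T @ Xz / n
    corr_xy = Xz.T @ yz / n

    def fit_of(subset: tuple[int, ...]) -> float:
        if not subset:
            return 0.0
        r2 = _subset_r2(corr_xx, corr_xy, subset)
        return _adjust(r2, n, len(subset)) if use_adjusted else r2

    # cache fit for every subset keyed by bitmask
    fit_cache: dict[int, float] = {0: 0.0}
    for size in range(1, p + 1):
        for subset in combinations(range(p), size):
            mask = sum(1 << j for j in subset)
            fit_cache[mask] = fit_of(subset)

    sums = np.zeros((p, p))     # predictor x base-subset size
    counts = np.zeros((p, p))
    flat_sums = np.zeros(p)
    flat_counts = np.zeros(p)
    for size in range(0, p):
        for subset in combinations(range(p), size):
            mask = sum(1 << j for j in subset)
            base = fit_cache[mask]
            for i in range(p):
                if mask & (1 << i):
                    continue
                inc = fit_cache[mask | (1 << i)] - base
                sums[i, size] += inc
                counts[i, size] += 1
                flat_sums[i] += inc
                flat_counts[i] += 1
    if averaging == "within_sizes":
        dominance = (sums / counts).mean(axis=1)
    else:
        dominance = flat_sums / flat_counts
    total_fit = r2_adj_full if use_adjusted else r2_full
    percent = (dominance / total_fit * 100.0 if total_fit != 0
               else np.full(p, np.nan))
    return DominanceResult(names, r2_full, r2_adj_full, dominance, percent,
                           p, n)
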