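"""Dominant-pattern removal and residual-profile similarity.

Every region's vector of connectivity with the brainstem follows, to first
order, the brainstem weighted-degree pattern. To expose structure beyond
that dominant pattern, each region's brainstem-connectivity profile is
regressed (ordinary least squares, with intercept) on the degree pattern
and the residuals are retained. Similarity matrices are pairwise Spearman
correlations of residual profiles: between brainstem nuclei (over their
cortical residual profiles) or between cortical regions (over their
brainstem residual profiles).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import DegreeMap, FunctionalConnectome
from .exceptions import ParameterError, ShapeError
from .parcellation import AnnotationTable, ParcellationScheme


@dataclass
class ResidualProfiles:
    """Node x brainstem residual connectivity matrix.

    Brainstem nodes' own self-connection entries are NaN (excluded from the
    fit and the output rather than zero-filled).
    """

    matrix: np.ndarray          # n_nodes x n_brainstem, NaN = excluded
    node_indices: np.ndarray    # global region ids of the rows
    regressor: DegreeMap
    scheme: ParcellationScheme


@dataclass
class SimilarityMatrix:
    """Region x region Spearman similarity of residual profiles."""

    matrix: np.ndarray
    axis: str  # brainstem_nuclei | cortical_regions
    scheme: ParcellationScheme


def regress_degree(fc: FunctionalConnectome, degree: DegreeMap,
                   nodes: str = "all") -> ResidualProfiles:
    """OLS-residualize each node's brainstem profile on (1, degree).

    ``nodes`` selects which rows to residualize: "all" (cortex + brainstem),
    "cortex", or "brainstem". For brainstem rows the self-connection entry
    is excluded from both the fit and the output.
    """
    if degree.source_block != "brainstem":
        raise ParameterError("degree regressor must be defined over the brainstem")
    d = np.asarray(degree.values, dtype=float)
    bst = fc.scheme.indices("brainstem")
    if d.size != bst.size:
        raise ShapeError("degree length does not match brainstem block")
    if np.ptp(d[np.isfinite(d)]) == 0:
        raise ParameterError("constant degree vector: regression is rank-deficient")
    if nodes == "all":
        node_idx = np.arange(len(fc.scheme))
    else:
        node_idx = fc.scheme.indices(nodes)
    profiles = fc.matrix[np.ix_(node_idx, bst)].astype(float).copy()
    # exclude brainstem self-connections
    bs_pos = {g: i for i, g in enumerate(bst)}
    for row, g in enumerate(node_idx):
        if g in bs_pos:
            profiles[row, bs_pos[g]] = np.nan

    resid = np.full_like(profiles, np.nan)
    for row in range(profiles.shape[0]):
        y = profiles[row]
        ok = np.isfinite(y) & np.isfinite(d)
        if ok.sum() < 3:
            warnings.warn(f"node row {row}: too few valid entries", stacklevel=2)
            continue
        X = np.column_stack([np.ones(ok.sum()), d[ok]])
        beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
        resid[row, ok] = y[ok] - X @ beta
    return ResidualProfiles(resid, node_idx, degree, fc.scheme)


def _spearman_pairwise(mat: np.ndarray, min_periods: int = 3) -> np.ndarray:
    """Spearman correlation between columns of ``mat`` with pairwise
    deletion of NaN entries; cells with < min_periods pairs are NaN."""
    if not np.isnan(mat).any():
        ranks = np.apply_along_axis(stats.rankdata, 0, mat)
        ranks -= ranks.mean(axis=0)
        denom = np.sqrt((ranks ** 2).sum(axis=0))
        if np.any(denom == 0):
            out = pd.DataFrame(mat).corr(method="spearman",
                                         min_periods=min_periods).to_numpy()
            return out
        c = (ranks.T @ ranks) / np.outer(denom, denom)
        return np.clip(c, -1.0, 1.0)
    return pd.DataFrame(mat).corr(method="spearman",
                                  min_periods=min_periods).to_numpy()


def similarity(profiles: ResidualProfiles, axis: str) -> SimilarityMatrix:
    """Pairwise Spearman similarity of residual profiles.

    ``axis="brainstem_nuclei"``: correlate pairs of brainstem nuclei over
    their cortical residual profiles (nuclei are columns, cortical rows are
    observations). ``axis="cortical_regions"``: correlate pairs of cortical
    regions over their brainstem residual profiles.
    """
    ctx_rows = np.flatnonzero(np.isin(profiles.node_indices,
                                      profiles.scheme.indices("cortex")))
    if axis == "brainstem_nuclei":
        data = profiles.matrix[ctx_rows, :]          # obs = cortical rows
    elif axis == "cortical_regions":
        data = profiles.matrix[ctx_rows, :].T        # obs = brainstem entries
    else:
        raise ParameterError(f"unknown similarity axis {axis!r}")
    if data.shape[0] < 3:
        raise ParameterError("need >= 3 observations per profile pair")
    s = _spearman_pairwise(data)
    s = (s + s.T) / 2.0
    np.fill_diagonal(s, 1.0)
    return SimilarityMatrix(s, axis, profiles.scheme)


def degree_profile_correlation(fc: FunctionalConnectome,
                               degree: DegreeMap) -> tuple[AnnotationTable, float]:
    """Spearman correlation of every node's brainstem profile with the
    brainstem weighted-degree pattern; returns the per-node map and its
    median."""
    d = np.asarray(degree.values, dtype=float)
    bst = fc.scheme.indices("brainstem")
    bs_pos = {g: i for i, g in enumerate(bst)}
    out = np.full(len(fc.scheme), np.nan)
    for node in range(len(fc.scheme)):
        y = fc.matrix[node, bst].astype(float).copy()
        if node in bs_pos:
            y[bs_pos[node]] = np.nan
        ok = np.isfinite(y) & np.isfinite(d)
        if ok.sum() < 3 or np.ptp(y[ok]) == 0:
            continue
        out[node], _ = stats.spearmanr(y[ok], d[ok])
    median = float(np.nanmedian(out))
    return AnnotationTable("degree_profile_r", out, scope="all"), median
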