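"""Functional connectome construction and descriptive statistics.

Functional connectivity (FC) is the zero-lag Pearson correlation between
regional time series; the group connectome is the plain mean of subject
connectomes (no Fisher transform). Weighted degree -- the signed sum of a
region's FC to a target block -- quantifies hubness; block comparisons use
Welch's t-test and one-way ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError, ShapeError
from .parcellation import AnnotationTable, ParcellationScheme, TimeSeriesSet


@dataclass
class FunctionalConnectome:
    """Region x region Pearson correlation matrix.

    Masked (zero-variance) regions carry NaN rows/columns; valid diagonal
    entries are exactly 1.
    """

    matrix: np.ndarray
    scheme: ParcellationScheme
    level: str = "subject"  # subject | group

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ShapeError(f"FC matrix must be square, got {m.shape}")
        if m.shape[0] != len(self.scheme):
            raise ShapeError("FC size does not match parcellation")
        self.matrix = m

    def block(self, source: str, target: str) -> np.ndarray:
        """Sub-matrix of FC from a source structure block to a target block."""
        return self.matrix[np.ix_(self.scheme.indices(source),
                                  self.scheme.indices(target))]


@dataclass
class DegreeMap:
    """Per-region summed FC to a target block (signed by default)."""

    values: np.ndarray
    source_block: str
    target_block: str
    sign_handling: str = "signed"


def build_fc(ts: TimeSeriesSet, scheme: ParcellationScheme) -> FunctionalConnectome:
    """Pairwise Pearson correlation of regional time series.

    Zero-variance regions get NaN rows/columns with a warning instead of
    propagating meaningless correlations.
    """
    if ts.n_timepoints < 3:
        raise ParameterError("need at least 3 timepoints for correlation")
    if ts.n_regions != len(scheme):
        raise ShapeError("time-series region count does not match parcellation")
    data = ts.data
    degenerate = np.nanstd(data, axis=1) == 0
    already_masked = np.isnan(data).any(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(np.nan_to_num(data))
    bad = degenerate | already_masked
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} zero-variance region(s) masked",
                      stacklevel=2)
    r[bad, :] = np.nan
    r[:, bad] = np.nan
    valid = ~bad
    r[np.ix_(valid, valid)] = np.clip(r[np.ix_(valid, valid)], -1.0, 1.0)
    r[np.diag_indices_from(r)] = np.where(valid, 1.0, np.nan)
    return FunctionalConnectome(r, scheme, level="subject")


def group_average(fcs: list[FunctionalConnectome]) -> FunctionalConnectome:
    """Element-wise mean of raw correlations across subjects.

    Masked entries are averaged over the subjects in which they are valid.
    """
    if not fcs:
        raise ParameterError("group_average needs at least one connectome")
    scheme = fcs[0].scheme
    for fc in fcs[1:]:
        if fc.matrix.shape != fcs[0].matrix.shape or fc.scheme is not scheme:
            if not np.array_equal(fc.scheme.labels, scheme.labels):
                raise ShapeError("connectomes use different parcellations")
    stack = np.stack([fc.matrix for fc in fcs])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    return FunctionalConnectome(mean, scheme, level="group")


def weighted_degree(fc: FunctionalConnectome, source_block: str,
                    target_block: str,
                    sign_handling: str = "signed") -> DegreeMap:
    """Signed sum of FC from each source region to all target regions.

    When source and target coincide the diagonal is excluded. The
    ``positive_only`` option zeroes negative correlations before summing.
    """
    if sign_handling not in ("signed", "positive_only"):
        raise ParameterError(f"unknown sign_handling {sign_handling!r}")
    src = fc.scheme.indices(source_block)
    tgt = fc.scheme.indices(target_block)
    if tgt.size == 0:
        raise ParameterError(f"empty target block {target_block!r}")
    block = fc.matrix[np.ix_(src, tgt)].copy()
    if source_block == target_block:
        np.fill_diagonal(block, 0.0)
    if sign_handling == "positive_only":
        block = np.clip(block, 0.0, None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        values = np.nansum(np.where(np.isnan(block), np.nan, block), axis=1)
        allnan = np.isnan(block).all(axis=1)
        values[allnan] = np.nan
    return DegreeMap(values, source_block, target_block, sign_handling)


def _pair_values(fc: FunctionalConnectome, block_pair: tuple[str, str]):
    """FC values and centroid distances for a block pair (upper triangle if
    the blocks coincide, full cross-block otherwise)."""
    a, b = block_pair
    ia, ib = fc.scheme.indices(a), fc.scheme.indices(b)
    cent = fc.scheme.centroids
    if np.isnan(cent[np.concatenate([ia, ib])]).any():
        raise ParameterError("missing centroid coordinates")
    sub = fc.matrix[np.ix_(ia, ib)]
    diff = cent[ia][:, None, :] - cent[ib][None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    if a == b:
        iu = np.triu_indices(len(ia), k=1)
        return dist[iu], sub[iu]
    return dist.ravel(), sub.ravel()


def fc_distance_profile(fc: FunctionalConnectome,
                        block_pair: tuple[str, str] = ("cortex", "cortex")):
    """Euclidean centroid distance vs FC for a block pair.

    Returns ``(distance_mm, fc_values, r, p)``; the correlation is Pearson
    on raw values and NaN (with a warning) when FC is constant.
    """
    dist, vals = _pair_values(fc, block_pair)
    ok = np.isfinite(vals)
    dist, vals = dist[ok], vals[ok]
    if vals.size < 3 or np.ptp(vals) == 0 or np.ptp(dist) == 0:
        warnings.warn("distance-FC correlation undefined (constant input)",
                      stacklevel=2)
        return dist, vals, np.nan, np.nan
    r, p = stats.pearsonr(dist, vals)
    return dist, vals, float(r), float(p)


def block_comparison_ttest(fc: FunctionalConnectome):
    """Welch's two-sided t-test: brainstem-cortex FC entries vs
    within-brainstem entries (upper triangle). Positive t means the
    between-block connectivity is stronger."""
    between = fc.block("brainstem", "cortex").ravel()
    bs = fc.block("brainstem", "brainstem")
    within = bs[np.triu_indices(bs.shape[0], k=1)]
    between = between[np.isfinite(between)]
    within = within[np.isfinite(within)]
    if between.size < 2 or within.size < 2:
        raise ParameterError("both entry sets need at least 2 values")
    if np.ptp(between) == 0 and np.ptp(within) == 0:
        warnings.warn("degenerate variance in both groups; t undefined",
                      stacklevel=2)
        return np.nan, np.nan
    t, p = stats.ttest_ind(between, within, equal_var=False)
    return float(t), float(p)


def class_anova(values: np.ndarray | AnnotationTable | DegreeMap,
                classes) -> tuple[float, float]:
    """One-way fixed-effects ANOVA of a regional map across categorical
    classes; classes with fewer than 2 members are excluded with a warning."""
    if isinstance(values, AnnotationTable):
        values = values.values
    elif isinstance(values, DegreeMap):
        values = values.values
    values = np.asarray(values, dtype=float)
    classes = np.asarray(classes)
    ok = np.isfinite(values)
    groups = []
    for c in pd.unique(classes[ok]):
        g = values[ok & (classes == c)]
        if g.size < 2:
            warnings.warn(f"class {c!r} has < 2 members; excluded", stacklevel=2)
            continue
        groups.append(g)
    if len(groups) < 2:
        raise ParameterError("ANOVA needs >= 2 classes with >= 2 members")
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)
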