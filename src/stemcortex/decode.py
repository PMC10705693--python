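"""Cognitive decoding: rank a cortical map's correlations against a battery
of annotation maps (meta-analytic term maps, receptor maps, ...)."""

from __future__ import annotations

from dataclasses import dataclass
from math import floor

import numpy as np
import pandas as pd
from scipy import stats

from .connectome import DegreeMap
from .exceptions import ParameterError, ShapeError
from .nulls import SpinNull, fdr_bh, spin_pvalue
from .parcellation import AnnotationTable


@dataclass
class DecodingReport:
    """Per-term correlations for one cortical map, ranked by descending r
    (ties broken by term label)."""

    map_name: str
    table: pd.DataFrame  # columns: term, r, p_spin, fdr_pass

    def top(self, fraction: float = 0.10) -> pd.DataFrame:
        return top_fraction(self, fraction)


def correlate_battery(map_values, battery: list[AnnotationTable],
                      spins: SpinNull | None = None, q: float = 0.05,
                      stat: str = "pearson",
                      map_name: str = "map") -> DecodingReport:
    """Correlate one cortical map with every map in a battery.

    Spin p-values and a Benjamini-Hochberg rejection flag are attached when
    a spin table is supplied.
    """
    if isinstance(map_values, DegreeMap):
        map_name = f"{map_values.source_block}->{map_values.target_block}"
        map_values = map_values.values
    elif isinstance(map_values, AnnotationTable):
        map_name = map_values.map_name
        map_values = map_values.values
    v = np.asarray(map_values, dtype=float)
    if not battery:
        raise ParameterError("battery is empty")
    rows = []
    for term in battery:
        if term.values.size != v.size:
            raise ShapeError(
                f"term {term.map_name!r} length {term.values.size} != map {v.size}")
        if spins is not None:
            r, p = spin_pvalue(v, term.values, spins, stat=stat)
        else:
            if stat == "spearman":
                r = float(stats.spearmanr(v, term.values)[0])
            else:
                r = float(stats.pearsonr(v, term.values)[0])
            p = np.nan
        rows.append((term.map_name, r, p))
    df = pd.DataFrame(rows, columns=["term", "r", "p_spin"])
    if spins is not None:
        df["fdr_pass"] = fdr_bh(df["p_spin"].to_numpy(), q=q)
    else:
        df["fdr_pass"] = False
    df = df.sort_values(["r", "term"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    return DecodingReport(map_name, df)


def top_fraction(report: DecodingReport, fraction: float = 0.10) -> pd.DataFrame:
    """The floor(fraction * battery size) most positively correlated terms."""
    if not 0 < fraction <= 1:
        raise ParameterError("fraction must lie in (0, 1]")
    n = len(report.table)
    if n == 0:
        raise ParameterError("empty decoding report")
    k = floor(fraction * n)
    return report.table.iloc[:k].reset_index(drop=True)
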