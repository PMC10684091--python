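"""Contingency testing of gene classes against expression states.

Pearson chi-square without continuity correction (a flag restores Yates),
plus Benjamini-Hochberg step-up adjustment across families of tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ContingencyResult", "chi_square", "bh_adjust", "class_state_tables"]


@dataclass
class ContingencyResult:
    table: pd.DataFrame  # r x c counts with row/column labels
    chi2: float
    df: int
    p: float
    p_adjusted: float | None = None
    comparison: str = ""


def _as_frame(table) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table
    arr = np.asarray(table)
    return pd.DataFrame(
        arr,
        index=[f"row{i}" for i in range(arr.shape[0])],
        columns=[f"col{j}" for j in range(arr.shape[1])],
    )


def chi_square(table, correction: bool = False, comparison: str = "") -> ContingencyResult:
    """Pearson chi-square test of independence on an r x c count table.

    Raises on any zero row/column margin (naming the offending margin) and
    warns when any expected count falls below 5.
    """
    frame = _as_frame(table)
    obs = frame.to_numpy(dtype=float)
    if obs.ndim != 2 or min(obs.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (obs < 0).any():
        raise ValueError("contingency table must be non-negative")
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    for i, s in enumerate(row_sums):
        if s == 0:
            raise ValueError(f"zero margin: row {frame.index[i]!r}")
    for j, s in enumerate(col_sums):
        if s == 0:
            raise ValueError(f"zero margin: column {frame.columns[j]!r}")
    expected = np.outer(row_sums, col_sums) / obs.sum()
    if (expected < 5).any():
        warnings.warn(
            "expected cell count below 5; chi-square approximation may be poor",
            UserWarning,
            stacklevel=2,
        )
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=correction)
    return ContingencyResult(
        table=frame, chi2=float(chi2), df=int(df), p=float(p), comparison=comparison
    )


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    # enforce monotonicity from the largest rank down
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty(n, dtype=float)
    out[order] = adjusted_sorted
    return out.tolist()


def class_state_tables(
    labels: pd.DataFrame,
    states: pd.DataFrame,
    state_column: str = "expressed_overall",
    exclude_het: bool = True,
    correction: bool = False,
) -> list[ContingencyResult]:
    """Build LSG-vs-other contingency tables per state and chi-square them.

    ``labels`` needs columns (gene_id, class); ``states`` needs gene_id plus
    one or more state columns (boolean or categorical).  For each state
    column a table of class x state counts is tested, and p-values are
    BH-adjusted across the family of tables.  HET-domain genes are dropped
    from the "other" margin by default, so the comparison is LSG vs
    non-HET non-LSG genes; HET_LSG genes always count as LSG.
    """
    if isinstance(state_column, str):
        state_columns = [state_column]
    else:
        state_columns = list(state_column)
    merged = labels.merge(states, on="gene_id", how="inner")
    if merged.empty:
        raise ValueError("labels and states share no genes")
    present = set(merged["class"])
    if not present & {"LSG", "HET_LSG"}:
        raise ValueError("class 'LSG' absent from the gene universe")
    if exclude_het:
        merged = merged[merged["class"] != "HET"]
    merged = merged.assign(
        _group=np.where(merged["class"].isin(["LSG", "HET_LSG"]), "LSG", "other")
    )
    results = []
    for col in state_columns:
        tab = pd.crosstab(merged["_group"], merged[col])
        results.append(chi_square(tab, correction=correction, comparison=col))
    adjusted = bh_adjust([r.p for r in results])
    for r, a in zip(results, adjusted):
        r.p_adjusted = a
    return results


def results_to_frame(results: Sequence[ContingencyResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        flat = {
            f"{ri}|{ci}": int(r.table.loc[ri, ci])
            for ri in r.table.index
            for ci in r.table.columns
        }
        rows.append(
            {"comparison": r.comparison, "chi2": r.chi2, "df": r.df, "p": r.p,
             "p_adjusted": r.p_adjusted, **flat}
        )
    return pd.DataFrame(rows)
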