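"""Co-expression coordination within physically linked gene clusters.

A cluster is coordinately expressed when at least one pair of member genes
has a correlation above 0.5 across the developmental conditions where both
are measurable.  Conditions where a gene is unmeasurable (relative level 0)
are dropped pairwise, never imputed; constant or all-zero profiles yield
undefined correlations and are excluded from the maximum rather than being
scored 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression import RelativeExpressionTable
from .maxgap import GeneCluster

__all__ = ["CoordinationResult", "cluster_correlations", "screen_clusters"]

COORDINATION_THRESHOLD = 0.5
MIN_SHARED_CONDITIONS = 3


@dataclass
class CoordinationResult:
    cluster_id: str
    gene_ids: tuple[str, ...]
    correlations: pd.DataFrame  # symmetric, unit diagonal where defined, NaN otherwise
    max_offdiag_r: float  # NaN when no pair is usable
    coordinated: bool
    n_pairs: int
    reason: str = "ok"


def _pair_r(
    x: np.ndarray, y: np.ndarray, method: str, min_shared: int
) -> float:
    shared = (x > 0) & (y > 0)  # level 0 marks unmeasurable conditions
    if shared.sum() < min_shared:
        return np.nan
    xs, ys = x[shared], y[shared]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return np.nan  # constant profile carries no coordination signal
    if method == "pearson":
        return float(stats.pearsonr(xs, ys).statistic)
    if method == "spearman":
        return float(stats.spearmanr(xs, ys).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def cluster_correlations(
    cluster: GeneCluster | Sequence[str],
    rel: RelativeExpressionTable,
    include_neighbors: Sequence[str] = (),
    method: str = "pearson",
    threshold: float = COORDINATION_THRESHOLD,
    min_shared: int = MIN_SHARED_CONDITIONS,
    cluster_id: str = "",
) -> CoordinationResult:
    """Pairwise correlations of member profiles and the coordination call.

    ``include_neighbors`` may list flanking non-focal gene ids to fold into
    the correlation matrix (neighbor behavior of the supplementary tables);
    by default only cluster members count.
    """
    if isinstance(cluster, GeneCluster):
        members = list(cluster.gene_ids)
        cid = cluster_id or f"{cluster.chromosome}:{cluster.member_indices[0]}"
    else:
        members = list(cluster)
        cid = cluster_id or ",".join(members)
    genes = members + [g for g in include_neighbors if g not in members]
    known = [g for g in genes if g in set(rel.genes)]
    profiles = rel.level.loc[known].to_numpy() if known else np.empty((0, 0))

    mat = pd.DataFrame(np.nan, index=known, columns=known)
    for i, gi in enumerate(known):
        mat.loc[gi, gi] = 1.0 if (profiles[i] > 0).sum() >= min_shared else np.nan
    n_pairs = 0
    for i in range(len(known)):
        for j in range(i + 1, len(known)):
            r = _pair_r(profiles[i], profiles[j], method, min_shared)
            mat.iloc[i, j] = mat.iloc[j, i] = r
            if not np.isnan(r):
                n_pairs += 1

    off = mat.to_numpy()[np.triu_indices(len(known), k=1)] if len(known) > 1 else np.array([])
    defined = off[~np.isnan(off)]
    if n_pairs == 0:
        max_r = float("nan")
        reason = "fewer_than_2_usable_genes"
        coordinated = False
    else:
        max_r = float(defined.max())
        reason = "ok"
        coordinated = max_r > threshold
    return CoordinationResult(
        cluster_id=cid,
        gene_ids=tuple(members),
        correlations=mat,
        max_offdiag_r=max_r,
        coordinated=coordinated,
        n_pairs=n_pairs,
        reason=reason,
    )


def screen_clusters(
    clusters: Sequence[GeneCluster],
    rel: RelativeExpressionTable,
    method: str = "pearson",
    threshold: float = COORDINATION_THRESHOLD,
    min_shared: int = MIN_SHARED_CONDITIONS,
) -> list[CoordinationResult]:
    """One result per cluster, sorted by max pairwise r descending (NaN last)."""
    results = [
        cluster_correlations(
            cl, rel, method=method, threshold=threshold, min_shared=min_shared,
            cluster_id=f"cluster_{i + 1}",
        )
        for i, cl in enumerate(clusters)
    ]
    return sorted(
        results,
        key=lambda r: (np.isnan(r.max_offdiag_r), -(r.max_offdiag_r if not np.isnan(r.max_offdiag_r) else 0)),
    )


def results_to_frame(results: Sequence[CoordinationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cluster_id": [r.cluster_id for r in results],
            "genes": [",".join(r.gene_ids) for r in results],
            "n_pairs": [r.n_pairs for r in results],
            "max_r": [r.max_offdiag_r for r in results],
            "coordinated": [r.coordinated for r in results],
            "reason": [r.reason for r in results],
        }
    )
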