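"""Max-gap cluster detection on chromosomes with permutation significance.

A max-gap cluster at gap parameter g is a maximal run of focal (labeled)
genes in chromosomal order in which consecutive focal genes are separated by
at most g non-focal genes.  Runs of a single gene are never clusters.
Significance is assessed against a chromosome-stratified uniform permutation
null on the label vector, and p-values are Benjamini-Hochberg adjusted across
all clusters genome-wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .enrichment import bh_adjust
from .layout import ChromosomeLayout, DEFAULT_FOCAL_CLASSES

__all__ = [
    "GeneCluster",
    "find_clusters",
    "find_cluster_indices",
    "cluster_pvalue",
    "assign_cluster_pvalues",
    "summarize_clusters",
    "max_cluster_size",
]


@dataclass
class GeneCluster:
    chromosome: str
    member_indices: tuple[int, ...]
    gene_ids: tuple[str, ...]
    max_gap: int
    gap_sequence: tuple[int, ...] = ()
    p_value: float | None = None
    p_adjusted: float | None = None

    @property
    def size(self) -> int:
        return len(self.member_indices)

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("a cluster has at least 2 members")
        if any(g > self.max_gap for g in self.gap_sequence):
            raise ValueError("gap_sequence entry exceeds max_gap")


def find_cluster_indices(labels: np.ndarray, max_gap: int) -> list[tuple[int, ...]]:
    """Greedy left-to-right scan for maximal gap-bounded groups of 1-positions.

    Maximal groups are unique under the gap rule: consecutive labeled
    positions either are or are not within max_gap of each other, so group
    boundaries are forced.
    """
    if max_gap < 0:
        raise ValueError(f"max_gap must be >= 0, got {max_gap}")
    positions = np.flatnonzero(np.asarray(labels))
    groups: list[tuple[int, ...]] = []
    current: list[int] = []
    for pos in positions:
        if current and pos - current[-1] - 1 > max_gap:
            if len(current) >= 2:
                groups.append(tuple(current))
            current = []
        current.append(int(pos))
    if len(current) >= 2:
        groups.append(tuple(current))
    return groups


def find_clusters(
    layout: ChromosomeLayout,
    max_gap: int,
    focal_classes=DEFAULT_FOCAL_CLASSES,
) -> list[GeneCluster]:
    """All size->=2 max-gap clusters of focal genes on one chromosome."""
    labels = layout.label_vector(focal_classes)
    clusters = []
    for members in find_cluster_indices(labels, max_gap):
        gaps = tuple(
            members[i + 1] - members[i] - 1 for i in range(len(members) - 1)
        )
        clusters.append(
            GeneCluster(
                chromosome=layout.chromosome,
                member_indices=members,
                gene_ids=tuple(layout.genes[i].gene_id for i in members),
                max_gap=max_gap,
                gap_sequence=gaps,
            )
        )
    return clusters


def max_cluster_size(positions: np.ndarray, max_gap: int) -> int:
    """Largest gap-bounded group size among sorted labeled positions."""
    if len(positions) == 0:
        return 0
    gaps = np.diff(positions) - 1
    within = gaps <= max_gap
    # longest run of consecutive True, +1 labeled gene
    best = run = 0
    for w in within:
        run = run + 1 if w else 0
        best = max(best, run)
    return best + 1


def _null_max_sizes(
    n: int, k: int, max_gap: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Max cluster sizes under uniform placement of k labels among n genes."""
    out = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        pos = np.sort(rng.choice(n, size=k, replace=False))
        out[i] = max_cluster_size(pos, max_gap)
    return out


def cluster_pvalue(
    cluster: GeneCluster,
    layout: ChromosomeLayout,
    n_perm: int = 1999,
    seed: int | None = None,
    focal_classes=DEFAULT_FOCAL_CLASSES,
) -> float:
    """Permutation p-value: chance of an equal-or-larger cluster under the null.

    p = (1 + #{permutations of the chromosome's labels containing a cluster
    of size >= cluster.size at the same max_gap}) / (1 + n_perm).
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    produced = find_cluster_indices(layout.label_vector(focal_classes), cluster.max_gap)
    if cluster.member_indices not in produced or cluster.chromosome != layout.chromosome:
        raise ValueError(
            f"cluster {cluster.gene_ids} was not produced from layout "
            f"{layout.chromosome} at max_gap={cluster.max_gap}"
        )
    labels = layout.label_vector(focal_classes)
    n, k = len(labels), int(labels.sum())
    rng = np.random.default_rng(seed)
    null = _null_max_sizes(n, k, cluster.max_gap, n_perm, rng)
    hits = int((null >= cluster.size).sum())
    return (1 + hits) / (1 + n_perm)


def assign_cluster_pvalues(
    layouts: Sequence[ChromosomeLayout],
    max_gap: int,
    n_perm: int = 1999,
    seed: int | None = None,
    focal_classes=DEFAULT_FOCAL_CLASSES,
) -> list[GeneCluster]:
    """Find clusters on every chromosome, attach permutation p-values and
    genome-wide BH-adjusted p-values.

    One shared null sample of max cluster sizes is drawn per chromosome (the
    null depends only on that chromosome's gene and label counts), which keeps
    p-values for clusters of the same chromosome mutually consistent.
    """
    rng = np.random.default_rng(seed)
    clusters: list[GeneCluster] = []
    for lay in layouts:
        found = find_clusters(lay, max_gap, focal_classes)
        if not found:
            continue
        labels = lay.label_vector(focal_classes)
        null = _null_max_sizes(len(labels), int(labels.sum()), max_gap, n_perm, rng)
        for cl in found:
            hits = int((null >= cl.size).sum())
            clusters.append(replace(cl, p_value=(1 + hits) / (1 + n_perm)))
    if clusters:
        adjusted = bh_adjust([cl.p_value for cl in clusters])
        clusters = [replace(cl, p_adjusted=a) for cl, a in zip(clusters, adjusted)]
    return clusters


def summarize_clusters(
    clusters: Sequence[GeneCluster], class_total: int
) -> pd.DataFrame:
    """Per-size tally of clusters and clustered genes, with a totals row.

    ``pct_genes`` is genes-in-size-bin / class_total * 100, where class_total
    is the number of focal genes in the genome.
    """
    clustered_genes = sum(cl.size for cl in clusters)
    if class_total < clustered_genes:
        raise ValueError(
            f"class_total ({class_total}) is smaller than the number of "
            f"clustered genes ({clustered_genes})"
        )
    sizes = sorted({cl.size for cl in clusters})
    rows = []
    for s in sizes:
        n_clusters = sum(1 for cl in clusters if cl.size == s)
        n_genes = s * n_clusters
        rows.append(
            {
                "cluster_size": str(s),
                "n_clusters": n_clusters,
                "n_genes": n_genes,
                "pct_genes": 100.0 * n_genes / class_total if class_total else 0.0,
            }
        )
    total_clusters = sum(r["n_clusters"] for r in rows)
    rows.append(
        {
            "cluster_size": "Total",
            "n_clusters": total_clusters,
            "n_genes": clustered_genes,
            "pct_genes": 100.0 * clustered_genes / class_total if class_total else 0.0,
        }
    )
    return pd.DataFrame(rows, columns=["cluster_size", "n_clusters", "n_genes", "pct_genes"])
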