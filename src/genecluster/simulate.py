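"""Synthetic genomes, homology-hit tables, and replicated count matrices.

Every downstream stage of the pipeline is exercised against data from this
module, with planted structure returned as machine-readable ground truth:

* :func:`simulate_genome` — chromosomes of ordered genes with planted
  contiguous focal-gene clusters, optionally biased toward chromosome ends.
* :func:`simulate_hits` — a homology hit table whose lineage classification
  recovers the planted gene classes exactly.
* :func:`simulate_counts` — negative-binomial count matrices with replicated
  timepoints, coordinated clusters sharing a latent profile, and genes that
  are silent in whole condition blocks.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .layout import ChromosomeLayout, GeneRecord
from .lineage import DEFAULT_RANK_LADDER

__all__ = [
    "GenomeSimConfig",
    "ExpressionSimConfig",
    "simulate_genome",
    "simulate_hits",
    "simulate_counts",
    "simulate_block_labels",
]


# ---------------------------------------------------------------------------
# Configs


@dataclass
class GenomeSimConfig:
    n_chromosomes: int = 7
    genes_per_chromosome: int = 300
    lsg_fraction: float = 0.07
    het_count: int = 20
    cluster_size_distribution: dict[int, float] = field(
        default_factory=lambda: {2: 0.40, 3: 0.25, 4: 0.15, 5: 0.10, 6: 0.05, 8: 0.03, 10: 0.02}
    )
    telomere_bias: float = 0.7
    background_lsg_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.genes_per_chromosome < 1:
            raise ValueError("chromosome and gene counts must be positive")
        for frac_name in ("lsg_fraction", "telomere_bias", "background_lsg_rate"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{frac_name} must lie in [0, 1], got {v}")
        if self.het_count < 0:
            raise ValueError("het_count must be non-negative")
        probs = self.cluster_size_distribution
        if probs:
            if any(size < 2 for size in probs):
                raise ValueError("cluster sizes must be >= 2")
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"cluster size probabilities must sum to 1, got {total}")


@dataclass
class ExpressionSimConfig:
    n_timepoints: int = 4
    n_replicates: int = 3
    library_size: float = 2_000_000.0
    #: NB overdispersion coefficient alpha: var = mu + alpha * mu^2
    #: (alpha -> 0 recovers Poisson counts)
    dispersion: float = 0.05
    coordinated_cluster_ids: list[int] = field(default_factory=list)
    silent_gene_fraction: float = 0.1
    fold_change_range: tuple[float, float] = (1.0, 8.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per timepoint")
        if self.n_timepoints < 1:
            raise ValueError("need at least 1 timepoint")
        if self.dispersion <= 0:
            raise ValueError(f"dispersion must be > 0, got {self.dispersion}")
        lo, hi = self.fold_change_range
        if lo <= 0 or hi < lo:
            raise ValueError(f"bad fold_change_range {self.fold_change_range}")
        if not 0.0 <= self.silent_gene_fraction <= 1.0:
            raise ValueError("silent_gene_fraction must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Genome simulation


def _draw_cluster_sizes(rng, probs: dict[int, float], target: int) -> list[int]:
    """Draw sizes from the configured distribution until ~target genes planted."""
    if not probs or target < 2:
        return []
    sizes = np.array(sorted(probs), dtype=int)
    p = np.array([probs[s] for s in sizes], dtype=float)
    p /= p.sum()
    drawn: list[int] = []
    remaining = target
    while remaining >= int(sizes.min()):
        s = int(rng.choice(sizes, p=p))
        if s > remaining:
            feasible = sizes[sizes <= remaining]
            if len(feasible) == 0:
                break
            s = int(rng.choice(feasible))
        drawn.append(s)
        remaining -= s
    return drawn


def _telomere_position(rng, n: int, size: int, biased: bool) -> int:
    """Candidate start index; biased draws hug either end of the gene order."""
    if biased:
        u = float(rng.beta(0.5, 3.0))  # mass piles up near 0
        frac = u if rng.random() < 0.5 else 1.0 - u
    else:
        frac = float(rng.random())
    return min(n - size, int(frac * (n - size + 1)))


def _place_clusters(
    rng, n: int, sizes: list[int], telomere_bias: float
) -> list[tuple[int, int]]:
    """Place clusters of the given sizes on one chromosome, never touching.

    A one-gene margin is kept on each side of every cluster so that planted
    clusters remain distinct even at max_gap = 0.
    """
    demand = sum(sizes) + max(0, len(sizes) - 1)
    if demand > n:
        raise ValueError(
            f"cluster demand ({sum(sizes)} genes in {len(sizes)} clusters) exceeds "
            f"chromosome capacity ({n} genes)"
        )
    occupied = np.zeros(n + 2, dtype=bool)  # padded: index i+1 is gene i
    placed: list[tuple[int, int]] = []
    for size in sorted(sizes, reverse=True):
        ok = False
        for _ in range(500):
            start = _telomere_position(rng, n, size, rng.random() < telomere_bias)
            window = occupied[start : start + size + 2]  # includes both margins
            if not window.any():
                occupied[start + 1 : start + 1 + size] = True
                placed.append((start, size))
                ok = True
                break
        if not ok:  # deterministic fallback: first free slot
            for start in range(n - size + 1):
                if not occupied[start : start + size + 2].any():
                    occupied[start + 1 : start + 1 + size] = True
                    placed.append((start, size))
                    ok = True
                    break
        if not ok:
            raise ValueError(
                f"could not place a size-{size} cluster on a chromosome of {n} genes"
            )
    return sorted(placed)


def simulate_genome(
    config: GenomeSimConfig,
) -> tuple[list[ChromosomeLayout], list[dict]]:
    """Generate ordered, labeled chromosomes plus the planted-cluster truth.

    Returns ``(layouts, truth)`` where ``truth`` is a list of dicts, one per
    planted cluster, with keys ``cluster_id``, ``chromosome``, ``start_index``,
    ``size`` and ``gene_ids``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_chr, gpc = config.n_chromosomes, config.genes_per_chromosome
    total = n_chr * gpc

    target_lsg = int(round(config.lsg_fraction * total))
    expected_background = config.background_lsg_rate * total
    planted_target = max(0, int(round(target_lsg - expected_background)))
    sizes = _draw_cluster_sizes(rng, config.cluster_size_distribution, planted_target)

    # round-robin-ish random assignment of clusters to chromosomes
    chrom_sizes: list[list[int]] = [[] for _ in range(n_chr)]
    for s in sizes:
        chrom_sizes[int(rng.integers(n_chr))].append(s)

    layouts: list[ChromosomeLayout] = []
    truth: list[dict] = []
    planted_mask: list[np.ndarray] = []
    cluster_id = 0
    for ci in range(n_chr):
        chrom = f"chr{ci + 1}"
        placed = _place_clusters(rng, gpc, chrom_sizes[ci], config.telomere_bias)
        labels = np.array(["other"] * gpc, dtype=object)
        in_cluster = np.zeros(gpc, dtype=bool)
        gene_ids = [f"{chrom}_g{j + 1:04d}" for j in range(gpc)]
        for start, size in placed:
            cluster_id += 1
            labels[start : start + size] = "LSG"
            in_cluster[start : start + size] = True
            truth.append(
                {
                    "cluster_id": cluster_id,
                    "chromosome": chrom,
                    "start_index": start,
                    "size": size,
                    "gene_ids": gene_ids[start : start + size],
                }
            )
        # background singles (and possibly chance clusters) outside planted runs
        if config.background_lsg_rate > 0:
            bg = rng.random(gpc) < config.background_lsg_rate
            labels[bg & ~in_cluster] = "LSG"
        planted_mask.append(in_cluster)

        # coordinates: increasing, non-overlapping
        lengths = rng.integers(500, 3000, size=gpc)
        gaps = rng.integers(50, 2000, size=gpc)
        starts = np.cumsum(gaps) + np.concatenate([[0], np.cumsum(lengths)[:-1]])
        strands = rng.choice(["+", "-"], size=gpc)
        genes = [
            GeneRecord(
                gene_id=gene_ids[j],
                start=int(starts[j]),
                end=int(starts[j] + lengths[j]),
                strand=str(strands[j]),
                label=str(labels[j]),
            )
            for j in range(gpc)
        ]
        layouts.append(ChromosomeLayout(chromosome=chrom, genes=genes))

    _assign_het(rng, layouts, truth, planted_mask, config.het_count)
    return layouts, truth


def _assign_het(rng, layouts, truth, planted_mask, het_count: int) -> None:
    """Sprinkle HET-domain genes: half adjacent to planted clusters, half random.

    A small number of planted cluster members become HET_LSG (genes carrying
    both labels), mirroring the handful of dual-annotated genes in real data.
    """
    if het_count == 0:
        return
    n_chr = len(layouts)
    flat: list[tuple[int, int]] = [
        (ci, j) for ci in range(n_chr) for j in range(len(layouts[ci]))
    ]
    adjacent: list[tuple[int, int]] = []
    for t in truth:
        ci = int(t["chromosome"].removeprefix("chr")) - 1
        lo, hi = t["start_index"] - 1, t["start_index"] + t["size"]
        for j in (lo, hi):
            if 0 <= j < len(layouts[ci]):
                adjacent.append((ci, j))
    n_dual = min(3, het_count, sum(t["size"] for t in truth))
    dual_pool = [
        (int(t["chromosome"].removeprefix("chr")) - 1, t["start_index"] + k)
        for t in truth
        for k in range(t["size"])
    ]
    chosen: set[tuple[int, int]] = set()
    if dual_pool and n_dual:
        idx = rng.choice(len(dual_pool), size=n_dual, replace=False)
        chosen.update(dual_pool[i] for i in np.atleast_1d(idx))
    while len(chosen) < het_count:
        pool = adjacent if (adjacent and rng.random() < 0.5) else flat
        ci, j = pool[int(rng.integers(len(pool)))]
        if layouts[ci].genes[j].label == "other":
            chosen.add((ci, j))
    for ci, j in chosen:
        g = layouts[ci].genes[j]
        new_label = "HET_LSG" if g.label in ("LSG", "HET_LSG") else "HET"
        layouts[ci].genes[j] = GeneRecord(g.gene_id, g.start, g.end, g.strand, new_label)


def simulate_block_labels(
    n: int,
    blocks: Sequence[tuple[int, int]],
    block_rate: float,
    background_rate: float,
    seed: int = 0,
) -> np.ndarray:
    """Bernoulli 0/1 label vector with elevated rate inside [start, end) blocks."""
    rng = np.random.default_rng(seed)
    p = np.full(n, background_rate, dtype=float)
    for start, end in blocks:
        p[start:end] = block_rate
    return (rng.random(n) < p).astype(np.int8)


# ---------------------------------------------------------------------------
# Homology hits

DEFAULT_IN_GENUS_TAXA = ("N_tetrasperma", "N_discreta", "N_sitophila")


def simulate_hits(
    layouts: Sequence[ChromosomeLayout],
    outgroup_taxa: Sequence[str],
    seed: int = 0,
    in_genus_taxa: Sequence[str] = DEFAULT_IN_GENUS_TAXA,
    rank_ladder: Sequence[str] = DEFAULT_RANK_LADDER,
) -> pd.DataFrame:
    """Homology hit table consistent with each gene's planted class.

    Focal genes (LSG / HET_LSG) receive only in-genus hits at E <= 0.05 (plus
    occasional decoy out-of-genus hits above the cutoff); every other gene
    receives at least one out-of-genus hit at E <= 0.05 whose rank encodes a
    randomly drawn true stratum.  In-genus reciprocal-best orthologs are
    emitted below the ortholog cutoff (1e-10).
    """
    if not outgroup_taxa:
        raise ValueError("outgroup_taxa must be non-empty")
    rng = np.random.default_rng(seed)
    genus_rank = rank_ladder[0]
    deeper_ranks = list(rank_ladder[1:])
    rows: list[tuple[str, str, str, float, bool]] = []
    for lay in layouts:
        for g in lay.genes:
            is_focal = g.label in ("LSG", "HET_LSG")
            n_in = int(rng.integers(1, len(in_genus_taxa) + 1))
            taxa = rng.choice(in_genus_taxa, size=n_in, replace=False)
            for t, taxon in enumerate(taxa):
                e = 10.0 ** rng.uniform(-40.0, -11.0)  # below ortholog cutoff
                rows.append((g.gene_id, str(taxon), genus_rank, e, t == 0))
            if is_focal:
                if rng.random() < 0.3:  # decoy: excluded by the broad cutoff
                    rows.append(
                        (
                            g.gene_id,
                            str(rng.choice(outgroup_taxa)),
                            str(rng.choice(deeper_ranks)),
                            float(rng.uniform(0.06, 5.0)),
                            False,
                        )
                    )
            else:
                stratum = str(rng.choice(deeper_ranks))
                depth = deeper_ranks.index(stratum)
                # defining hit at the true stratum, plus shallower extras
                n_extra = int(rng.integers(0, 3))
                picks = [depth] + list(rng.integers(0, depth + 1, size=n_extra))
                for d in picks:
                    e = 10.0 ** rng.uniform(-50.0, math.log10(0.05))
                    rows.append(
                        (
                            g.gene_id,
                            str(rng.choice(outgroup_taxa)),
                            deeper_ranks[int(d)],
                            e,
                            False,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=["query_gene", "subject_taxon", "mrca_rank", "e_value", "reciprocal_best"],
    )


# ---------------------------------------------------------------------------
# Count matrices


def simulate_counts(
    layouts: Sequence[ChromosomeLayout],
    config: ExpressionSimConfig,
    cluster_truth: Sequence[dict] = (),
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Replicated NB count matrix emulating a multi-timepoint RNA-seq series.

    Returns ``(counts, sample_sheet, truth)``.  ``counts`` is genes x samples;
    ``sample_sheet`` has columns (sample, condition, replicate); ``truth``
    carries the latent per-gene log-fold profiles, the silent-gene blocks and
    the shared profiles of coordinated clusters.

    Genes belonging to a coordinated cluster (selected from ``cluster_truth``
    by ``config.coordinated_cluster_ids``) share one latent log-profile across
    timepoints; their counts differ only by baseline abundance and sampling
    noise.  Silent genes are zeroed in whole condition blocks so that
    "not expressed at any sampled point" is realizable.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    gene_ids = [g.gene_id for lay in layouts for g in lay.genes]
    n_genes = len(gene_ids)
    T, R = config.n_timepoints, config.n_replicates
    conditions = [f"t{t + 1}" for t in range(T)]
    samples = [f"{c}_r{r + 1}" for c in conditions for r in range(R)]
    sheet = pd.DataFrame(
        {
            "sample": samples,
            "condition": [c for c in conditions for _ in range(R)],
            "replicate": [r + 1 for _ in conditions for r in range(R)],
        }
    )

    truth_by_id = {t["cluster_id"]: t for t in cluster_truth}
    missing = [cid for cid in config.coordinated_cluster_ids if cid not in truth_by_id]
    if missing:
        raise ValueError(f"coordinated_cluster_ids not present in cluster truth: {missing}")

    gene_index = {g: i for i, g in enumerate(gene_ids)}
    lo, hi = config.fold_change_range
    log_lo, log_hi = math.log(lo), math.log(hi)

    # independent per-gene latent log-fold profiles across timepoints
    log_profiles = rng.uniform(log_lo, log_hi, size=(n_genes, T))
    cluster_profiles: dict[int, list[float]] = {}
    for cid in config.coordinated_cluster_ids:
        shared = rng.uniform(log_lo, log_hi, size=T)
        cluster_profiles[cid] = shared.tolist()
        for gid in truth_by_id[cid]["gene_ids"]:
            log_profiles[gene_index[gid]] = shared

    baseline = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)

    # silent genes are zero across the whole series; a further 15% of the
    # remaining genes are zeroed in a contiguous proper sub-block of
    # conditions, so "never expressed" and "silent at some points" both occur.
    # Coordinated-cluster members keep their shared profile intact and are
    # exempt, except in the degenerate everything-silent case.
    coordinated_genes = {
        gene_index[gid]
        for cid in config.coordinated_cluster_ids
        for gid in truth_by_id[cid]["gene_ids"]
    }
    silent = rng.random(n_genes) < config.silent_gene_fraction
    if config.silent_gene_fraction < 1.0:
        silent[list(coordinated_genes)] = False
    silent_blocks: dict[str, list[str]] = {}
    expressed = np.ones((n_genes, T), dtype=bool)
    for i in range(n_genes):
        if silent[i]:
            expressed[i, :] = False
            silent_blocks[gene_ids[i]] = list(conditions)
        elif T > 1 and i not in coordinated_genes and rng.random() < 0.15:
            width = int(rng.integers(1, T))
            start = int(rng.integers(0, T - width + 1))
            expressed[i, start : start + width] = False
            silent_blocks[gene_ids[i]] = conditions[start : start + width]

    mu_gene_cond = baseline[:, None] * np.exp(log_profiles) * expressed
    size_factors = rng.lognormal(mean=0.0, sigma=0.08, size=len(samples))

    counts = np.zeros((n_genes, len(samples)), dtype=np.int64)
    for si, (cond,) in enumerate(zip(sheet["condition"])):
        t = conditions.index(cond)
        mu_t = mu_gene_cond[:, t]
        tot = mu_t.sum()
        if tot > 0:
            mu = mu_t / tot * config.library_size * size_factors[si]
            shape = 1.0 / config.dispersion * np.ones(n_genes)
            lam = np.where(
                mu > 0, rng.gamma(shape, np.maximum(mu, 1e-300) * config.dispersion), 0.0
            )
            counts[:, si] = rng.poisson(lam)

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=samples)
    truth = {
        "log_profiles": {g: log_profiles[i].tolist() for i, g in enumerate(gene_ids)},
        "baseline": {g: float(baseline[i]) for i, g in enumerate(gene_ids)},
        "silent_blocks": silent_blocks,
        "cluster_profiles": cluster_profiles,
        "size_factors": dict(zip(samples, size_factors.tolist())),
    }
    return counts_df, sheet, truth
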