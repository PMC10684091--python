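"""Relative-expression tables, detectability and expression-state calls.

Counts are condensed per condition with a Gamma-Poisson posterior on the
library-size-normalized rate (Jeffreys-style prior with configurable
pseudocount), then rescaled so the lowest detectable condition sits at 1;
conditions with no measurable expression are reported as 0 with a [0, 0]
interval.  Interval endpoints and contrasts are computed on the log scale
with trigamma variances of the Gamma posterior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .enrichment import bh_adjust

__all__ = [
    "RelativeExpressionTable",
    "relative_expression",
    "call_dynamic",
    "status_across_stages",
    "classify_pair",
    "PAIR_CATEGORIES",
]

Z95 = float(stats.norm.ppf(0.975))

PAIR_CATEGORIES = (
    "only_in_mutant",
    "higher_in_mutant",
    "no_difference",
    "not_measurable_in_either",
    "higher_in_wildtype",
    "only_in_wildtype",
)


@dataclass
class RelativeExpressionTable:
    """Per gene x condition relative levels with uncertainty and detectability.

    ``level`` rows satisfy: minimum over detectable conditions == 1, and 0 in
    unmeasurable conditions.  ``log_mean`` / ``log_var`` hold the posterior
    log absolute normalized rate and its variance (used for contrasts);
    ``total_counts`` / ``total_exposure`` summarize each gene across all
    samples for strain-vs-strain comparisons.
    """

    level: pd.DataFrame
    lower95: pd.DataFrame
    upper95: pd.DataFrame
    detectable: pd.DataFrame
    log_mean: pd.DataFrame
    log_var: pd.DataFrame
    total_counts: pd.Series
    total_exposure: float

    @property
    def genes(self) -> list[str]:
        return list(self.level.index)

    @property
    def conditions(self) -> list[str]:
        return list(self.level.columns)

    def to_frame(self) -> pd.DataFrame:
        """S6/S8-shaped wide table: fold change per condition, lowest = 1."""
        out = self.level.copy()
        out.insert(0, "gene_id", out.index)
        return out.reset_index(drop=True)


def _check_sheet(counts: pd.DataFrame, samples: pd.DataFrame) -> None:
    for col in ("sample", "condition", "replicate"):
        if col not in samples.columns:
            raise ValueError(f"sample sheet missing column {col!r}")
    if samples["sample"].duplicated().any():
        raise ValueError("sample sheet maps a sample to more than one condition")
    missing = set(samples["sample"]) - set(counts.columns)
    if missing:
        raise ValueError(f"samples absent from count matrix: {sorted(missing)}")


def relative_expression(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    pseudocount: float = 0.5,
    detect_threshold: float = 1.0,
    lib_sizes: pd.Series | None = None,
) -> RelativeExpressionTable:
    """Condense replicated counts into a relative-expression table.

    A gene is detectable in a condition iff its normalized count (per
    million) reaches ``detect_threshold`` in at least half the replicates.
    Levels are posterior mean rates rescaled by the smallest detectable
    condition; 95% intervals come from the log-scale Gamma posterior of the
    condition rate combined with the reference condition's uncertainty.
    All-zero genes are reported as 0 everywhere, without error.
    """
    _check_sheet(counts, samples)
    if lib_sizes is None:
        lib_sizes = counts.sum(axis=0).astype(float)
    else:
        lib_sizes = lib_sizes.astype(float)
    cpm = counts / lib_sizes * 1e6
    conditions = list(dict.fromkeys(samples["condition"]))
    genes = counts.index

    level = pd.DataFrame(0.0, index=genes, columns=conditions)
    lower = pd.DataFrame(0.0, index=genes, columns=conditions)
    upper = pd.DataFrame(0.0, index=genes, columns=conditions)
    detectable = pd.DataFrame(False, index=genes, columns=conditions)
    log_mean = pd.DataFrame(-np.inf, index=genes, columns=conditions)
    log_var = pd.DataFrame(np.inf, index=genes, columns=conditions)

    rate = {}
    for cond in conditions:
        smp = samples.loc[samples["condition"] == cond, "sample"].tolist()
        if len(smp) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 replicates")
        k = counts[smp].sum(axis=1).astype(float)
        exposure = float(lib_sizes[smp].sum()) / 1e6  # per-million scale
        detectable[cond] = (cpm[smp] >= detect_threshold).sum(axis=1) >= np.ceil(
            len(smp) / 2
        )
        post_shape = k + pseudocount
        rate[cond] = post_shape / exposure
        log_mean[cond] = np.log(post_shape) - np.log(exposure)
        log_var[cond] = special.polygamma(1, post_shape)

    rates = pd.DataFrame(rate)
    det = detectable.to_numpy()
    any_det = det.any(axis=1)
    masked = rates.to_numpy().copy()
    masked[~det] = np.inf
    ref_idx = np.argmin(masked, axis=1)
    ref_rate = rates.to_numpy()[np.arange(len(genes)), ref_idx]
    ref_logv = log_var.to_numpy()[np.arange(len(genes)), ref_idx]

    for ci, cond in enumerate(conditions):
        ok = any_det & det[:, ci]
        lvl = np.where(ok, rates[cond].to_numpy() / ref_rate, 0.0)
        se = np.sqrt(log_var[cond].to_numpy() + ref_logv)
        level[cond] = lvl
        lower[cond] = np.where(ok, lvl * np.exp(-Z95 * se), 0.0)
        upper[cond] = np.where(ok, lvl * np.exp(Z95 * se), 0.0)

    return RelativeExpressionTable(
        level=level,
        lower95=lower,
        upper95=upper,
        detectable=detectable,
        log_mean=log_mean,
        log_var=log_var,
        total_counts=counts[samples["sample"]].sum(axis=1).astype(float),
        total_exposure=float(lib_sizes[samples["sample"]].sum()) / 1e6,
    )


def call_dynamic(
    rel: RelativeExpressionTable,
    fold: float = 5.0,
    alpha: float = 0.05,
    adjust: bool = True,
) -> pd.DataFrame:
    """Call genes with >= fold-change between extreme conditions, significant
    at ``alpha`` after BH adjustment across genes.

    Genes detectable in fewer than two conditions are excluded (flagged, never
    dynamic).  Returns a frame with columns (gene_id, max_fold, p, p_adjusted,
    dynamic, excluded); the set of dynamic genes is
    ``set(frame.loc[frame.dynamic, "gene_id"])``.
    """
    if len(rel.conditions) < 2:
        raise ValueError("need at least 2 conditions to call dynamic genes")
    det = rel.detectable.to_numpy()
    levels = rel.level.to_numpy()
    logm = rel.log_mean.to_numpy()
    logv = rel.log_var.to_numpy()
    n_genes = len(rel.genes)

    excluded = det.sum(axis=1) < 2
    max_fold = np.zeros(n_genes)
    p = np.ones(n_genes)
    for i in range(n_genes):
        if excluded[i]:
            continue
        idx = np.flatnonzero(det[i])
        hi = idx[np.argmax(levels[i, idx])]
        lo = idx[np.argmin(levels[i, idx])]
        max_fold[i] = levels[i, hi]  # lowest detectable level is 1
        se = np.sqrt(logv[i, hi] + logv[i, lo])
        z = (logm[i, hi] - logm[i, lo]) / se if se > 0 else 0.0
        p[i] = 2.0 * stats.norm.sf(abs(z))
    tested = ~excluded
    p_adj = np.ones(n_genes)
    if tested.any():
        p_adj[tested] = bh_adjust(p[tested]) if adjust else p[tested]
    dynamic = tested & (max_fold >= fold) & (p_adj <= alpha)
    return pd.DataFrame(
        {
            "gene_id": rel.genes,
            "max_fold": max_fold,
            "p": p,
            "p_adjusted": p_adj,
            "dynamic": dynamic,
            "excluded": excluded,
        }
    )


def status_across_stages(rel: RelativeExpressionTable, min_points: int = 2) -> pd.DataFrame:
    """Cross-stage expressed / not-expressed status per gene.

    A gene is expressed overall iff detected in at least ``min_points``
    conditions; genes detected at exactly one point carry single_point_only
    (the parenthetical tallies of the summary tables).
    """
    if len(rel.conditions) < 2:
        raise ValueError("need at least 2 sampled points")
    n_det = rel.detectable.sum(axis=1).astype(int)
    return pd.DataFrame(
        {
            "gene_id": rel.genes,
            "n_points_detected": n_det.to_numpy(),
            "expressed_overall": (n_det >= min_points).to_numpy(),
            "single_point_only": (n_det == 1).to_numpy(),
        }
    )


def classify_pair(
    rel_mutant: RelativeExpressionTable,
    rel_wildtype: RelativeExpressionTable,
    alpha: float = 0.05,
    adjust: bool = True,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Six-way mutant-vs-wildtype category per gene.

    Detectability decides the exclusive categories first (only_in_mutant /
    only_in_wildtype / not_measurable_in_either); genes measurable in both
    strains are compared on pooled normalized abundance with a log-scale
    Gamma contrast, BH-adjusted across genes.  Categories are exhaustive and
    mutually exclusive.
    """
    if list(rel_mutant.genes) != list(rel_wildtype.genes):
        raise ValueError("mutant and wildtype tables must share the gene universe")
    genes = rel_mutant.genes
    det_m = rel_mutant.detectable.any(axis=1).to_numpy()
    det_w = rel_wildtype.detectable.any(axis=1).to_numpy()

    km = rel_mutant.total_counts.to_numpy() + pseudocount
    kw = rel_wildtype.total_counts.to_numpy() + pseudocount
    log_ratio = (np.log(km) - np.log(rel_mutant.total_exposure)) - (
        np.log(kw) - np.log(rel_wildtype.total_exposure)
    )
    se = np.sqrt(special.polygamma(1, km) + special.polygamma(1, kw))
    z = np.where(se > 0, log_ratio / se, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))

    both = det_m & det_w
    p_adj = np.ones(len(genes))
    if both.any():
        p_adj[both] = bh_adjust(p[both]) if adjust else p[both]

    category = np.full(len(genes), "no_difference", dtype=object)
    category[~det_m & ~det_w] = "not_measurable_in_either"
    category[det_m & ~det_w] = "only_in_mutant"
    category[~det_m & det_w] = "only_in_wildtype"
    sig = both & (p_adj <= alpha)
    category[sig & (log_ratio > 0)] = "higher_in_mutant"
    category[sig & (log_ratio < 0)] = "higher_in_wildtype"
    return pd.DataFrame(
        {"gene_id": genes, "category": category, "p": p, "p_adjusted": p_adj}
    )
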