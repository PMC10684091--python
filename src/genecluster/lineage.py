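"""Lineage-specificity (phylostratum) classification from homology hit tables.

A hit table has one row per (query gene, subject taxon) pair with the
taxonomic rank of their most recent common ancestor, an E-value, and a
reciprocal-best flag.  Classification retains hits at a broad E-value cutoff
and assigns each gene the most inclusive rank among its retained hits; a gene
whose retained hits are all in-genus is lineage-specific.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "DEFAULT_RANK_LADDER",
    "PhylostratumAssignment",
    "filter_hits",
    "classify_lineage",
    "stratum_census",
    "assignments_to_frame",
]

#: Rank ladder ordered from most exclusive (in-genus) to most inclusive.
DEFAULT_RANK_LADDER = (
    "Neurospora",
    "Sordariomycetes",
    "Pezizomycotina",
    "Ascomycota",
    "Dikarya",
    "Eukaryote",
)

#: Stratum label for genes with no retained hits at any cutoff.
SELF_ONLY_STRATUM = "unclassified-self-only"

HIT_COLUMNS = ["query_gene", "subject_taxon", "mrca_rank", "e_value", "reciprocal_best"]


@dataclass(frozen=True)
class PhylostratumAssignment:
    gene: str
    stratum: str
    is_lsg: bool
    in_genus_orthologs: tuple[str, ...] = ()
    flagged: bool = False  # True for zero-hit, self-only genes


def _check_table(table: pd.DataFrame, ladder: Sequence[str]) -> None:
    missing = [c for c in HIT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"hit table missing columns: {missing}")
    if len(table) and (table["e_value"] < 0).any():
        raise ValueError("e_value must be non-negative")
    if len(table):
        bad = set(table["mrca_rank"]) - set(ladder)
        if bad:
            raise ValueError(f"mrca_rank values outside the rank ladder: {sorted(bad)}")


def filter_hits(table: pd.DataFrame, e_cutoff: float) -> pd.DataFrame:
    """Retain rows with e_value <= e_cutoff, preserving row order."""
    if e_cutoff <= 0:
        raise ValueError(f"e_cutoff must be > 0, got {e_cutoff}")
    if table.empty:
        return table.copy()
    return table[table["e_value"] <= e_cutoff].copy()


def classify_lineage(
    table: pd.DataFrame,
    broad_cutoff: float = 0.05,
    ortholog_cutoff: float = 1e-10,
    rank_ladder: Sequence[str] = DEFAULT_RANK_LADDER,
    genes: Iterable[str] | None = None,
) -> list[PhylostratumAssignment]:
    """Assign each gene its phylostratum and lineage-specificity flag.

    The stratum is the most inclusive rank among hits retained at
    ``broad_cutoff`` (the smallest clade containing all evidence); a gene is
    lineage-specific iff every retained hit is in-genus.  ``in_genus_orthologs``
    lists reciprocal-best in-genus subjects at ``ortholog_cutoff``.  Genes
    named in ``genes`` but absent from the table after filtering are assigned
    the flagged self-only stratum and counted as lineage-specific.
    """
    _check_table(table, rank_ladder)
    ladder = list(rank_ladder)
    rank_depth = {r: i for i, r in enumerate(ladder)}
    genus_rank = ladder[0]

    retained = filter_hits(table, broad_cutoff)
    universe: list[str] = list(dict.fromkeys(table["query_gene"])) if len(table) else []
    if genes is not None:
        for g in genes:
            if g not in set(universe):
                universe.append(g)

    ortho = filter_hits(table, ortholog_cutoff)
    ortho = ortho[(ortho["mrca_rank"] == genus_rank) & ortho["reciprocal_best"]]
    ortho_map: dict[str, tuple[str, ...]] = {
        g: tuple(sorted(set(grp["subject_taxon"])))
        for g, grp in ortho.groupby("query_gene")
    }

    depth_by_gene = (
        retained.assign(_depth=retained["mrca_rank"].map(rank_depth))
        .groupby("query_gene")["_depth"]
        .max()
        if len(retained)
        else pd.Series(dtype=int)
    )

    out: list[PhylostratumAssignment] = []
    for g in universe:
        if g in depth_by_gene.index:
            depth = int(depth_by_gene[g])
            out.append(
                PhylostratumAssignment(
                    gene=g,
                    stratum=ladder[depth],
                    is_lsg=depth == 0,
                    in_genus_orthologs=ortho_map.get(g, ()),
                )
            )
        else:
            out.append(
                PhylostratumAssignment(
                    gene=g,
                    stratum=SELF_ONLY_STRATUM,
                    is_lsg=True,
                    in_genus_orthologs=ortho_map.get(g, ()),
                    flagged=True,
                )
            )
    return out


def stratum_census(assignments: Sequence[PhylostratumAssignment]) -> dict[str, int]:
    """Count genes per stratum; counts sum to the number of genes."""
    if not assignments:
        raise ValueError("assignments must be non-empty")
    census: dict[str, int] = {}
    for a in assignments:
        census[a.stratum] = census.get(a.stratum, 0) + 1
    return census


def assignments_to_frame(assignments: Sequence[PhylostratumAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [a.gene for a in assignments],
            "stratum": [a.stratum for a in assignments],
            "is_lsg": [a.is_lsg for a in assignments],
            "in_genus_orthologs": [";".join(a.in_genus_orthologs) for a in assignments],
            "flagged": [a.flagged for a in assignments],
        }
    )
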