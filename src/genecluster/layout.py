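"""Ordered gene layouts: the positional substrate shared by all analyses.

A :class:`ChromosomeLayout` holds the genes of one chromosome in ascending
coordinate order, each carrying a class label.  All clustering machinery
operates on the 0/1 label vector derived from a layout, never on base-pair
coordinates: gaps are counted in genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Recognized gene class labels.
GENE_CLASSES = ("LSG", "HET", "HET_LSG", "other")

#: Classes counted as "focal" (label 1) in positional analyses by default.
DEFAULT_FOCAL_CLASSES = frozenset({"LSG", "HET_LSG"})


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene: half-open 0-based [start, end) coordinates."""

    gene_id: str
    start: int
    end: int
    strand: str = "+"
    label: str = "other"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"gene {self.gene_id}: end ({self.end}) must exceed start ({self.start})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if self.label not in GENE_CLASSES:
            raise ValueError(f"gene {self.gene_id}: unknown class {self.label!r}")


@dataclass
class ChromosomeLayout:
    """Genes of one chromosome in ascending, non-overlapping coordinate order."""

    chromosome: str
    genes: list[GeneRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        prev_end = -1
        prev_id = None
        for g in self.genes:
            if g.start < prev_end:
                raise ValueError(
                    f"{self.chromosome}: gene {g.gene_id} (start {g.start}) overlaps "
                    f"or precedes {prev_id} (end {prev_end})"
                )
            prev_end, prev_id = g.end, g.gene_id

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def labels(self) -> list[str]:
        return [g.label for g in self.genes]

    def label_vector(
        self, focal_classes: Iterable[str] = DEFAULT_FOCAL_CLASSES
    ) -> np.ndarray:
        """0/1 vector marking genes whose class is in ``focal_classes``."""
        focal = frozenset(focal_classes)
        return np.fromiter(
            (1 if g.label in focal else 0 for g in self.genes),
            dtype=np.int8,
            count=len(self.genes),
        )


def total_genes(layouts: Sequence[ChromosomeLayout]) -> int:
    return sum(len(lay) for lay in layouts)


def label_table(layouts: Sequence[ChromosomeLayout]):
    """Long-form (gene_id, class) table over all chromosomes, in genome order."""
    import pandas as pd

    rows = [
        (lay.chromosome, g.gene_id, g.label)
        for lay in layouts
        for g in lay.genes
    ]
    return pd.DataFrame(rows, columns=["chromosome", "gene_id", "class"])
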