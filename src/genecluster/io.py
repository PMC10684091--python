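"""Readers and writers for the plain-text formats used across the pipeline.

GFF3 handling is deliberately minimal: the pipeline only ever deals in
one-record-per-gene files that it writes itself, so a light parser is used
instead of a database-backed library.  Internal coordinates are 0-based
half-open; GFF3 output is 1-based inclusive.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .layout import ChromosomeLayout, GeneRecord

# ---------------------------------------------------------------------------
# GFF3


def write_gff3(layouts: Sequence[ChromosomeLayout], path) -> None:
    lines = ["##gff-version 3"]
    for lay in layouts:
        for g in lay.genes:
            lines.append(
                "\t".join(
                    [
                        lay.chromosome,
                        "genecluster",
                        "gene",
                        str(g.start + 1),  # 1-based inclusive
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path) -> pd.DataFrame:
    """Parse gene records from a GFF3 file into a genome-ordered frame."""
    rows = []
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9 or fields[2] != "gene":
            continue
        attrs = dict(
            kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
        )
        rows.append(
            {
                "chromosome": fields[0],
                "gene_id": attrs.get("ID", f"{fields[0]}:{fields[3]}"),
                "start": int(fields[3]) - 1,  # back to 0-based half-open
                "end": int(fields[4]),
                "strand": fields[6],
            }
        )
    if not rows:
        raise ValueError(f"no gene records found in {path}")
    return pd.DataFrame(rows)


def build_layouts(
    genes: pd.DataFrame, labels: pd.DataFrame | None = None
) -> list[ChromosomeLayout]:
    """Assemble layouts from a gene frame (read_gff3) plus a label table."""
    if labels is not None:
        lab = dict(zip(labels["gene_id"], labels["class"]))
    else:
        lab = {}
    layouts = []
    for chrom, grp in genes.groupby("chromosome", sort=True):
        grp = grp.sort_values("start")
        recs = [
            GeneRecord(
                gene_id=r.gene_id,
                start=int(r.start),
                end=int(r.end),
                strand=r.strand,
                label=lab.get(r.gene_id, "other"),
            )
            for r in grp.itertuples()
        ]
        layouts.append(ChromosomeLayout(chromosome=chrom, genes=recs))
    return layouts


# ---------------------------------------------------------------------------
# TSV tables


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)


def write_labels(layouts: Sequence[ChromosomeLayout], path) -> None:
    from .layout import label_table

    write_tsv(label_table(layouts)[["gene_id", "class"]], path)


# ---------------------------------------------------------------------------
# BED output for clusters


def clusters_to_bed(clusters, layouts: Sequence[ChromosomeLayout]) -> pd.DataFrame:
    """BED-shaped frame: chrom, span start/end, cluster name, -10*log10(p)."""
    by_chrom = {lay.chromosome: lay for lay in layouts}
    rows = []
    for i, cl in enumerate(clusters):
        lay = by_chrom[cl.chromosome]
        first = lay.genes[cl.member_indices[0]]
        last = lay.genes[cl.member_indices[-1]]
        p = cl.p_value
        score = 0 if p is None else min(1000, int(round(-10.0 * np.log10(max(p, 1e-100)))))
        rows.append(
            {
                "chrom": cl.chromosome,
                "chromStart": first.start,
                "chromEnd": last.end,
                "name": f"cluster_{i + 1}|size={cl.size}|genes={','.join(cl.gene_ids)}",
                "score": score,
                "strand": ".",
            }
        )
    return pd.DataFrame(
        rows, columns=["chrom", "chromStart", "chromEnd", "name", "score", "strand"]
    )


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, header=False)


def read_cluster_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "chromStart", "chromEnd", "name", "score", "strand"],
    )
    parts = df["name"].str.split("|")
    df["cluster_id"] = parts.str[0]
    df["gene_ids"] = parts.str[2].str.removeprefix("genes=").str.split(",")
    return df


# ---------------------------------------------------------------------------
# JSON


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
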