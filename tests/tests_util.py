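"""Shared helpers for the test suite."""

from genecluster.layout import ChromosomeLayout, GeneRecord


def two_gene_layout():
    return ChromosomeLayout(
        chromosome="chrT",
        genes=[
            GeneRecord("g_lsg", 0, 500, "+", "LSG"),
            GeneRecord("g_other", 1000, 1500, "+", "other"),
        ],
    )
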