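import numpy as np
import pytest

from genecluster.layout import ChromosomeLayout, GeneRecord
from genecluster.simulate import GenomeSimConfig, simulate_genome


def make_layout(labels, chromosome="chrT"):
    """Layout with one gene per label; coordinates are synthetic but valid."""
    genes = [
        GeneRecord(
            gene_id=f"{chromosome}_g{i + 1:03d}",
            start=i * 1000,
            end=i * 1000 + 500,
            strand="+",
            label="LSG" if v else "other",
        )
        for i, v in enumerate(labels)
    ]
    return ChromosomeLayout(chromosome=chromosome, genes=genes)


@pytest.fixture
def small_genome():
    cfg = GenomeSimConfig(
        n_chromosomes=2,
        genes_per_chromosome=120,
        lsg_fraction=0.12,
        het_count=8,
        background_lsg_rate=0.0,
        telomere_bias=0.6,
        seed=11,
    )
    return simulate_genome(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
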