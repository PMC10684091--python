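import numpy as np
import pandas as pd
import pytest
from scipy import stats

from genecluster.lineage import classify_lineage
from genecluster.maxgap import find_clusters
from genecluster.simulate import (
    ExpressionSimConfig,
    GenomeSimConfig,
    simulate_block_labels,
    simulate_counts,
    simulate_genome,
    simulate_hits,
)


def total_lsg(layouts):
    return int(sum(lay.label_vector().sum() for lay in layouts))


class TestGenomeConfig:
    def test_bad_probability_mass_rejected(self):
        cfg = GenomeSimConfig(cluster_size_distribution={2: 0.5, 3: 0.4})
        with pytest.raises(ValueError, match="sum to 1"):
            cfg.validate()

    def test_singleton_cluster_size_rejected(self):
        cfg = GenomeSimConfig(cluster_size_distribution={1: 1.0})
        with pytest.raises(ValueError, match=">= 2"):
            cfg.validate()

    def test_cluster_demand_exceeding_capacity_errors(self):
        # two size-5 clusters plus a separating margin need 11 > 10 slots
        cfg = GenomeSimConfig(
            n_chromosomes=1,
            genes_per_chromosome=10,
            lsg_fraction=1.0,
            het_count=0,
            background_lsg_rate=0.0,
            cluster_size_distribution={5: 1.0},
            seed=0,
        )
        with pytest.raises(ValueError, match="capacity|place"):
            simulate_genome(cfg)


class TestSimulateGenome:
    def test_zero_lsg_fraction_gives_no_lsg_labels(self):
        cfg = GenomeSimConfig(
            n_chromosomes=2,
            genes_per_chromosome=50,
            lsg_fraction=0.0,
            background_lsg_rate=0.0,
            het_count=0,
            seed=3,
        )
        layouts, truth = simulate_genome(cfg)
        assert truth == []
        assert total_lsg(layouts) == 0

    def test_single_planted_cluster_is_contiguous(self):
        cfg = GenomeSimConfig(
            n_chromosomes=1,
            genes_per_chromosome=60,
            lsg_fraction=5 / 60,
            background_lsg_rate=0.0,
            het_count=0,
            cluster_size_distribution={5: 1.0},
            seed=5,
        )
        layouts, truth = simulate_genome(cfg)
        assert len(truth) == 1
        assert truth[0]["size"] == 5
        start = truth[0]["start_index"]
        labels = layouts[0].label_vector()
        assert labels[start : start + 5].tolist() == [1] * 5
        assert labels.sum() == 5

    def test_coordinates_strictly_increasing_nonoverlapping(self, small_genome):
        layouts, _ = small_genome
        for lay in layouts:
            starts = [g.start for g in lay.genes]
            assert starts == sorted(starts)
            for a, b in zip(lay.genes, lay.genes[1:]):
                assert a.end <= b.start

    def test_telomere_bias_places_lsg_near_ends(self):
        # oracle: the rank statistic recomputed directly from the layout
        cfg = GenomeSimConfig(
            n_chromosomes=2,
            genes_per_chromosome=250,
            lsg_fraction=0.15,
            het_count=0,
            background_lsg_rate=0.0,
            telomere_bias=0.9,
            seed=1,
        )
        layouts, _ = simulate_genome(cfg)
        lsg_d, other_d = [], []
        for lay in layouts:
            n = len(lay)
            for i, g in enumerate(lay.genes):
                d = min(i, n - 1 - i) / (n - 1)
                (lsg_d if g.label == "LSG" else other_d).append(d)
        res = stats.mannwhitneyu(lsg_d, other_d, alternative="less")
        assert res.pvalue < 0.05

    def test_determinism(self):
        cfg = GenomeSimConfig(n_chromosomes=2, genes_per_chromosome=80, seed=9)
        a, ta = simulate_genome(cfg)
        b, tb = simulate_genome(GenomeSimConfig(n_chromosomes=2, genes_per_chromosome=80, seed=9))
        assert ta == tb
        assert [lay.genes for lay in a] == [lay.genes for lay in b]

    def test_planted_cluster_recovery_at_gap_zero(self, small_genome):
        layouts, truth = small_genome
        found = [
            (cl.chromosome, cl.member_indices)
            for lay in layouts
            for cl in find_clusters(lay, max_gap=0)
        ]
        planted = [
            (t["chromosome"], tuple(range(t["start_index"], t["start_index"] + t["size"])))
            for t in truth
        ]
        assert sorted(found) == sorted(planted)

    def test_marginal_lsg_fraction_converges(self):
        cfg = GenomeSimConfig(
            n_chromosomes=1,
            genes_per_chromosome=2000,
            lsg_fraction=0.10,
            het_count=0,
            background_lsg_rate=0.02,
            seed=17,
        )
        layouts, _ = simulate_genome(cfg)
        n = 2000
        frac = total_lsg(layouts) / n
        sd = np.sqrt(0.10 * 0.90 / n)
        assert abs(frac - 0.10) <= 3 * sd

    def test_het_labels_assigned(self, small_genome):
        layouts, _ = small_genome
        labels = [g.label for lay in layouts for g in lay.genes]
        assert labels.count("HET") + labels.count("HET_LSG") == 8


class TestSimulateHits:
    def test_empty_outgroups_error(self, small_genome):
        layouts, _ = small_genome
        with pytest.raises(ValueError, match="outgroup"):
            simulate_hits(layouts, [], seed=0)

    def test_only_non_lsg_gets_confident_outgroup_hit(self):
        from tests_util import two_gene_layout

        lay = two_gene_layout()
        hits = simulate_hits([lay], ["Podospora"], seed=4)
        confident = hits[hits["e_value"] <= 0.05]
        out_of_genus = confident[confident["mrca_rank"] != "Neurospora"]
        assert set(out_of_genus["query_gene"]) == {"g_other"}

    def test_round_trip_classification(self, small_genome):
        layouts, _ = small_genome
        hits = simulate_hits(layouts, ["Podospora", "Chaetomium"], seed=21)
        assignments = {a.gene: a.is_lsg for a in classify_lineage(hits)}
        for lay in layouts:
            for g in lay.genes:
                assert assignments[g.gene_id] == (g.label in ("LSG", "HET_LSG")), g.gene_id

    def test_deterministic_byte_identical(self, small_genome, tmp_path):
        layouts, _ = small_genome
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        simulate_hits(layouts, ["Podospora"], seed=8).to_csv(p1, sep="\t", index=False)
        simulate_hits(layouts, ["Podospora"], seed=8).to_csv(p2, sep="\t", index=False)
        assert p1.read_bytes() == p2.read_bytes()


class TestSimulateCounts:
    def test_dispersion_must_be_positive(self, small_genome):
        layouts, truth = small_genome
        cfg = ExpressionSimConfig(dispersion=0.0)
        with pytest.raises(ValueError, match="dispersion"):
            simulate_counts(layouts, cfg, truth)

    def test_replicates_floor(self):
        with pytest.raises(ValueError, match="replicates"):
            ExpressionSimConfig(n_replicates=1).validate()

    def test_all_silent_gives_zero_matrix(self, small_genome):
        layouts, truth = small_genome
        cfg = ExpressionSimConfig(silent_gene_fraction=1.0, seed=2)
        counts, _, _ = simulate_counts(layouts, cfg, truth)
        assert (counts.to_numpy() == 0).all()

    def test_coordinated_cluster_shares_profile(self, small_genome):
        layouts, truth = small_genome
        big = max(truth, key=lambda t: t["size"])
        cfg = ExpressionSimConfig(
            n_timepoints=6,
            library_size=5e6,
            dispersion=1e-4,  # noise -> 0: nearly Poisson at high depth
            coordinated_cluster_ids=[big["cluster_id"]],
            silent_gene_fraction=0.0,
            seed=13,
        )
        counts, sheet, truth_expr = simulate_counts(layouts, cfg, truth)
        profs = []
        for gid in big["gene_ids"]:
            by_cond = counts.loc[gid].groupby(sheet.set_index("sample")["condition"]).mean()
            profs.append(by_cond.to_numpy())
        for a in profs[1:]:
            r = np.corrcoef(profs[0], a)[0, 1]
            assert r > 0.99
        shared = truth_expr["cluster_profiles"][big["cluster_id"]]
        for gid in big["gene_ids"]:
            assert truth_expr["log_profiles"][gid] == shared

    def test_unknown_coordinated_cluster_id_errors(self, small_genome):
        layouts, truth = small_genome
        cfg = ExpressionSimConfig(coordinated_cluster_ids=[99999])
        with pytest.raises(ValueError, match="cluster truth"):
            simulate_counts(layouts, cfg, truth)

    def test_mean_count_matches_library_size(self):
        # per-sample proportions are renormalized, so the analytic grand mean
        # is library_size / n_genes regardless of silencing or fold effects
        layouts, truth = simulate_genome(
            GenomeSimConfig(n_chromosomes=5, genes_per_chromosome=200, seed=7)
        )
        cfg = ExpressionSimConfig(seed=7)
        counts, _, _ = simulate_counts(layouts, cfg, truth)
        n_genes = counts.shape[0]
        expected = cfg.library_size / n_genes
        assert abs(counts.to_numpy().mean() - expected) / expected < 0.05

    def test_counts_are_nonnegative_integers(self, small_genome):
        layouts, truth = small_genome
        counts, _, _ = simulate_counts(layouts, ExpressionSimConfig(seed=1), truth)
        arr = counts.to_numpy()
        assert arr.dtype.kind == "i"
        assert (arr >= 0).all()

    def test_determinism(self, small_genome):
        layouts, truth = small_genome
        cfg = ExpressionSimConfig(seed=5)
        c1, s1, _ = simulate_counts(layouts, cfg, truth)
        c2, s2, _ = simulate_counts(layouts, ExpressionSimConfig(seed=5), truth)
        pd.testing.assert_frame_equal(c1, c2)
        pd.testing.assert_frame_equal(s1, s2)


def test_block_labels_rates():
    labels = simulate_block_labels(5000, [(0, 500), (4500, 5000)], 0.6, 0.05, seed=3)
    inside = np.concatenate([labels[:500], labels[4500:]])
    outside = labels[500:4500]
    assert abs(inside.mean() - 0.6) < 0.05
    assert abs(outside.mean() - 0.05) < 0.02
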