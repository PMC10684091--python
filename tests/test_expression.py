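import numpy as np
import pandas as pd
import pytest

from genecluster.expression import (
    PAIR_CATEGORIES,
    call_dynamic,
    classify_pair,
    relative_expression,
    status_across_stages,
)


def sheet_for(conditions, n_rep=3):
    rows = []
    for c in conditions:
        for r in range(n_rep):
            rows.append({"sample": f"{c}_r{r + 1}", "condition": c, "replicate": r + 1})
    return pd.DataFrame(rows)


def counts_from_means(means_by_gene, n_rep=3, noise=None, rng=None):
    """Exact-replicate count matrix from per-condition means (genes x conds)."""
    conds = [f"t{i + 1}" for i in range(len(next(iter(means_by_gene.values()))))]
    sheet = sheet_for(conds, n_rep)
    data = {}
    for s in sheet["sample"]:
        c = int(s.split("_")[0][1:]) - 1
        col = []
        for g, means in means_by_gene.items():
            v = means[c]
            if rng is not None and noise == "poisson":
                v = rng.poisson(v)
            col.append(v)
        data[s] = col
    counts = pd.DataFrame(data, index=list(means_by_gene))
    counts.index.name = "gene_id"
    return counts, sheet


FIXED_LIB = pd.Series(1e6, index=[f"t{t}_r{r}" for t in (1, 2, 3, 4) for r in (1, 2, 3)])


class TestRelativeExpression:
    def test_rescaling_to_lowest_condition(self):
        counts, sheet = counts_from_means({"g1": [5, 10, 50]})
        rel = relative_expression(counts, sheet, lib_sizes=pd.Series(1.0, index=counts.columns))
        lv = rel.level.loc["g1"]
        assert lv.tolist() == pytest.approx([1.0, 2.0, 10.0], rel=0.05)

    def test_all_zero_gene_reported_as_zero(self):
        counts, sheet = counts_from_means({"g0": [0, 0, 0], "g1": [50, 60, 70]})
        rel = relative_expression(counts, sheet)
        assert rel.level.loc["g0"].tolist() == [0.0, 0.0, 0.0]
        assert rel.lower95.loc["g0"].tolist() == [0.0, 0.0, 0.0]
        assert rel.upper95.loc["g0"].tolist() == [0.0, 0.0, 0.0]
        assert not rel.detectable.loc["g0"].any()

    def test_min_detectable_level_is_one(self, rng):
        genes = {f"g{i}": rng.integers(5, 500, size=4).tolist() for i in range(20)}
        counts, sheet = counts_from_means(genes)
        rel = relative_expression(counts, sheet)
        for g in rel.genes:
            det = rel.detectable.loc[g]
            if det.any():
                assert rel.level.loc[g][det].min() == pytest.approx(1.0)

    def test_undetectable_condition_scored_zero(self):
        counts, sheet = counts_from_means({"g1": [0, 200, 300], "g2": [50, 50, 50]})
        rel = relative_expression(counts, sheet)
        assert rel.level.loc["g1", "t1"] == 0.0
        assert not rel.detectable.loc["g1", "t1"]
        assert rel.level.loc["g1", "t2"] == 1.0

    def test_rescaling_invariance_with_fixed_libsizes(self):
        base = {"g1": [10, 40, 80], "g2": [100, 100, 100]}
        counts, sheet = counts_from_means(base)
        scaled = counts.copy()
        scaled.loc["g1"] *= 7
        lib = pd.Series(1e4, index=counts.columns)
        r1 = relative_expression(counts, sheet, lib_sizes=lib)
        r2 = relative_expression(scaled, sheet, lib_sizes=lib)
        np.testing.assert_allclose(
            r1.level.loc["g1"], r2.level.loc["g1"], rtol=0.02
        )

    def test_interval_ordering(self, rng):
        genes = {f"g{i}": rng.integers(1, 400, size=4).tolist() for i in range(30)}
        counts, sheet = counts_from_means(genes, noise="poisson", rng=rng)
        rel = relative_expression(counts, sheet)
        det = rel.detectable.to_numpy()
        lo, lv, hi = rel.lower95.to_numpy(), rel.level.to_numpy(), rel.upper95.to_numpy()
        assert np.all(lo[det] <= lv[det] + 1e-12)
        assert np.all(lv[det] <= hi[det] + 1e-12)

    def test_coverage_of_true_fold(self):
        # a gene with a true 8-fold change: the 95% interval should cover the
        # truth in >= 90% of simulation replicates
        rng = np.random.default_rng(77)
        covered = 0
        n_rep = 200
        for _ in range(n_rep):
            means = {"g1": [50, 400, 100], "filler": [1000, 1000, 1000]}
            counts, sheet = counts_from_means(means, noise="poisson", rng=rng)
            lib = pd.Series(1e6, index=counts.columns)
            rel = relative_expression(counts, sheet, lib_sizes=lib)
            if rel.detectable.loc["g1"].all():
                lo = rel.lower95.loc["g1", "t2"]
                hi = rel.upper95.loc["g1", "t2"]
                if lo <= 8.0 <= hi:
                    covered += 1
        assert covered / n_rep >= 0.90

    def test_missing_sample_errors(self):
        counts, sheet = counts_from_means({"g1": [1, 2, 3]})
        bad = sheet.copy()
        bad.loc[0, "sample"] = "nonexistent"
        with pytest.raises(ValueError, match="absent"):
            relative_expression(counts, bad)

    def test_single_replicate_errors(self):
        counts, sheet = counts_from_means({"g1": [1, 2, 3]}, n_rep=1)
        with pytest.raises(ValueError, match="replicates"):
            relative_expression(counts, sheet)


class TestCallDynamic:
    def test_small_fold_not_dynamic(self):
        counts, sheet = counts_from_means({"g1": [100, 200, 300]})
        rel = relative_expression(counts, sheet)
        out = call_dynamic(rel, fold=5)
        assert not out["dynamic"].iloc[0]

    def test_clear_sixfold_dynamic(self):
        means = {"g1": [200, 200, 1200], "g2": [500, 500, 500]}
        counts, sheet = counts_from_means(means)
        lib = pd.Series(1e6, index=counts.columns)
        rel = relative_expression(counts, sheet, lib_sizes=lib)
        out = call_dynamic(rel, fold=5).set_index("gene_id")
        assert bool(out.loc["g1", "dynamic"])
        assert not bool(out.loc["g2", "dynamic"])

    def test_underdetected_gene_excluded(self):
        counts, sheet = counts_from_means({"g1": [0, 0, 900], "g2": [100, 100, 100]})
        rel = relative_expression(counts, sheet)
        out = call_dynamic(rel).set_index("gene_id")
        assert bool(out.loc["g1", "excluded"])
        assert not bool(out.loc["g1", "dynamic"])

    def test_null_false_positive_rate(self):
        # 1000 genes, no true change: dynamic-call rate <= alpha + 3 SD
        rng = np.random.default_rng(5)
        base = rng.integers(20, 2000, size=1000)
        means = {f"g{i}": [int(b)] * 4 for i, b in enumerate(base)}
        counts, sheet = counts_from_means(means, noise="poisson", rng=rng)
        rel = relative_expression(counts, sheet)
        out = call_dynamic(rel, fold=5, alpha=0.05)
        rate = out["dynamic"].mean()
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 1000)

    def test_requires_two_conditions(self):
        counts, sheet = counts_from_means({"g1": [5]})
        rel = relative_expression(counts, sheet)
        with pytest.raises(ValueError, match="2 conditions"):
            call_dynamic(rel)


class TestStatus:
    @pytest.mark.parametrize(
        "means,expressed,single",
        [
            ([0, 0, 0, 0], False, False),
            ([0, 0, 0, 900], False, True),
            ([0, 0, 800, 900], True, False),
            ([700, 800, 900, 600], True, False),
        ],
    )
    def test_detection_tallies(self, means, expressed, single):
        counts, sheet = counts_from_means({"g1": means, "filler": [500] * 4})
        rel = relative_expression(counts, sheet)
        st = status_across_stages(rel).set_index("gene_id")
        assert bool(st.loc["g1", "expressed_overall"]) == expressed
        assert bool(st.loc["g1", "single_point_only"]) == single

    def test_status_conservation(self, rng):
        genes = {f"g{i}": (rng.integers(0, 2, size=4) * rng.integers(50, 500)).tolist()
                 for i in range(80)}
        counts, sheet = counts_from_means(genes)
        rel = relative_expression(counts, sheet)
        st = status_across_stages(rel)
        n_exp = int(st["expressed_overall"].sum())
        n_single = int(st["single_point_only"].sum())
        n_silent = int((st["n_points_detected"] == 0).sum())
        assert n_exp + n_single + n_silent == len(st)


class TestClassifyPair:
    def _tables(self, mut_means, wt_means, rng=None, noise=None):
        cm, sm = counts_from_means(mut_means, noise=noise, rng=rng)
        cw, sw = counts_from_means(wt_means, noise=noise, rng=rng)
        return (
            relative_expression(cm, sm),
            relative_expression(cw, sw),
        )

    def test_only_in_mutant(self):
        mut, wt = self._tables(
            {"g1": [300, 300, 300], "f": [500] * 3},
            {"g1": [0, 0, 0], "f": [500] * 3},
        )
        out = classify_pair(mut, wt).set_index("gene_id")
        assert out.loc["g1", "category"] == "only_in_mutant"

    def test_not_measurable_in_either(self):
        mut, wt = self._tables(
            {"g1": [0, 0, 0], "f": [500] * 3},
            {"g1": [0, 0, 0], "f": [500] * 3},
        )
        out = classify_pair(mut, wt).set_index("gene_id")
        assert out.loc["g1", "category"] == "not_measurable_in_either"

    def test_only_in_wildtype(self):
        mut, wt = self._tables(
            {"g1": [0, 0, 0], "f": [500] * 3},
            {"g1": [300, 300, 300], "f": [500] * 3},
        )
        out = classify_pair(mut, wt).set_index("gene_id")
        assert out.loc["g1", "category"] == "only_in_wildtype"

    def test_strong_difference_directions(self):
        mut, wt = self._tables(
            {"g1": [5000] * 3, "g2": [50] * 3, "f": [500] * 3},
            {"g1": [50] * 3, "g2": [5000] * 3, "f": [500] * 3},
        )
        out = classify_pair(mut, wt).set_index("gene_id")
        assert out.loc["g1", "category"] == "higher_in_mutant"
        assert out.loc["g2", "category"] == "higher_in_wildtype"

    def test_null_mostly_no_difference(self):
        rng = np.random.default_rng(8)
        means = {f"g{i}": [int(v)] * 3 for i, v in enumerate(rng.integers(50, 800, 200))}
        mut, wt = self._tables(means, means, rng=rng, noise="poisson")
        out = classify_pair(mut, wt)
        frac = (out["category"] == "no_difference").mean()
        assert frac >= 0.95

    def test_categories_partition_universe(self, rng):
        means_m = {f"g{i}": rng.integers(0, 300, size=3).tolist() for i in range(60)}
        means_w = {f"g{i}": rng.integers(0, 300, size=3).tolist() for i in range(60)}
        mut, wt = self._tables(means_m, means_w)
        out = classify_pair(mut, wt)
        assert set(out["category"]) <= set(PAIR_CATEGORIES)
        assert out["category"].value_counts().sum() == 60

    def test_mismatched_universe_errors(self):
        mut, _ = self._tables({"g1": [1, 2, 3]}, {"g1": [1, 2, 3]})
        _, wt = self._tables({"g2": [1, 2, 3]}, {"g2": [1, 2, 3]})
        with pytest.raises(ValueError, match="universe"):
            classify_pair(mut, wt)
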