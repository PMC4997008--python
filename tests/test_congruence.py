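"""Ghost ranges, MIG bounds, the five indices, and the permutation null."""

import numpy as np
import pytest

import stratcong as sc
from stratcong.congruence import TopologyArrays

from conftest import random_binary_tree, random_fo_table


class TestNodeAges:
    def test_worst_fit_tree(self, ages4, t_bad):
        ages = sc.node_ages(t_bad, ages4)
        internal = [ages[n] for n in t_bad.postorder() if not n.is_leaf]
        assert internal == [10, 10, 10]

    def test_best_fit_tree(self, ages4, t_good):
        ages = sc.node_ages(t_good, ages4)
        internal = [ages[n] for n in t_good.postorder() if not n.is_leaf]
        assert internal == [6, 9, 10]

    def test_cherry_tie(self):
        fo = sc.FOTable.from_ages({"A": 5, "B": 5})
        tree = sc.parse_newick("(A,B);")
        assert sc.node_ages(tree, fo)[tree.root] == 5


class TestMIG:
    def test_worst_fit(self, ages4, t_bad):
        result = sc.mig(t_bad, ages4)
        assert result.mig == 11 == result.g_max
        ghosts = dict(result.ghost_ranges)
        assert ghosts[("B",)] == 6 and ghosts[("C",)] == 4 and ghosts[("D",)] == 1

    def test_best_fit_telescopes(self, ages4, t_good):
        result = sc.mig(t_good, ages4)
        assert result.mig == 6 == result.g_min

    def test_intermediate(self, ages4, t_mid):
        result = sc.mig(t_mid, ages4)
        assert result.mig == 7
        ghosts = dict(result.ghost_ranges)
        assert ghosts[("D",)] == 1 and ghosts[("B",)] == 2
        assert ghosts[("B", "C")] == 4

    def test_polytomy_rejected(self, ages4):
        with pytest.raises(sc.PolytomyError):
            sc.mig(sc.parse_newick("(A,B,C,D);"), ages4)


class TestSankoffOracle:
    """The irreversible-age-character optimization is an independent DP; its
    optimum must equal the ghost-range sum on every tree."""

    def test_fixture_trees(self, ages4, t_bad, t_good, t_mid):
        for tree in (t_bad, t_good, t_mid):
            assert sc.sankoff_irreversible_length(tree, ages4) == sc.mig(tree, ages4).mig

    def test_random_trees(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            n = int(rng.integers(4, 17))
            labels = [f"t{i}" for i in range(n)]
            tree = random_binary_tree(rng, labels)
            fo = random_fo_table(rng, labels)
            assert sc.sankoff_irreversible_length(tree, fo) == pytest.approx(
                sc.mig(tree, fo).mig
            )


class TestBounds:
    def test_gmin_gmax_examples(self, ages4):
        assert sc.g_min(ages4) == 6
        assert sc.g_max(ages4) == 11

    def test_all_equal(self):
        fo = sc.FOTable.from_ages({"A": 5, "B": 5, "C": 5})
        assert sc.g_min(fo) == 0 and sc.g_max(fo) == 0

    def test_single_taxon_rejected(self):
        fo = sc.FOTable.from_ages({"A": 5, "B": 3})
        assert sc.g_min(fo) == 2  # two taxa fine
        with pytest.raises(sc.TreeError):
            sc.g_min(fo.subset(["A"]))

    @pytest.mark.parametrize("n", [4, 5, 6])
    def test_exhaustive_topologies_attain_bounds(self, n):
        rng = np.random.default_rng(n)
        labels = [f"t{i}" for i in range(n)]
        ages = rng.choice(np.arange(1.0, 30.0), size=n, replace=False)
        fo = sc.FOTable.from_ages(dict(zip(labels, ages)))
        migs = [sc.mig(t, fo).mig for t in sc.enumerate_topologies(labels)]
        assert min(migs) == sc.g_min(fo)
        assert max(migs) == sc.g_max(fo)


class TestScalarIndices:
    def test_sci_examples(self, ages4, t_bad, t_good, t_mid):
        assert sc.sci(t_bad, ages4) == 0.0
        assert sc.sci(t_good, ages4) == 1.0
        assert sc.sci(t_mid, ages4) == 0.5

    def test_sci_ties_count_as_consistent(self):
        fo = sc.FOTable.from_ages({"A": 5, "B": 5, "C": 5, "D": 5})
        assert sc.sci(sc.parse_newick("((A,B),(C,D));"), fo) == 1.0

    def test_ger_examples(self, ages4, t_bad, t_good, t_mid):
        assert sc.ger(t_good, ages4) == 1.0
        assert sc.ger(t_bad, ages4) == 0.0
        assert sc.ger(t_mid, ages4) == pytest.approx(0.8)

    def test_msm_examples(self, ages4, t_good, t_mid):
        assert sc.msm_star(t_good, ages4) == 1.0
        assert sc.msm_star(t_mid, ages4) == pytest.approx(6 / 7)

    def test_undefined_when_all_fo_equal(self):
        fo = sc.FOTable.from_ages({"A": 5, "B": 5, "C": 5, "D": 5})
        tree = sc.parse_newick("((A,B),(C,D));")
        with pytest.raises(sc.UndefinedIndexError) as err:
            sc.ger(tree, fo)
        assert err.value.reason == "all_fo_equal"
        with pytest.raises(sc.UndefinedIndexError) as err:
            sc.msm_star(tree, fo)
        assert err.value.reason == "zero_mig"

    def test_ger_strictly_decreasing_in_mig(self, ages4):
        """With topology and Gmin/Gmax fixed, GER is strictly decreasing in MIG."""
        lo, hi = sc.g_min(ages4), sc.g_max(ages4)
        gers = [1 - (m - lo) / (hi - lo) for m in np.linspace(lo, hi, 7)]
        assert all(a > b for a, b in zip(gers, gers[1:]))

    def test_balanced_tree_sci_is_half_with_distinct_dates(self):
        """On a 2**k-tip balanced tree with all-distinct FOs, exactly one node
        of each internal sister pair is consistent: SCI = 0.5 exactly."""
        rng = np.random.default_rng(17)
        for k in (3, 4, 5, 6):
            n = 2**k
            labels = [f"t{i}" for i in range(n)]
            tree = sc.generate_balanced(labels)
            ages = rng.permutation(np.arange(1.0, n + 1.0))
            fo = sc.FOTable.from_ages(dict(zip(labels, ages)))
            assert sc.sci(tree, fo) == 0.5


class TestPermutationNull:
    def test_exhaustive_balanced_four(self, ages4, t_mid):
        null = sc.permutation_null(t_mid, ages4, exhaustive=True)
        values, counts = np.unique(null.permuted_mig, return_counts=True)
        assert list(values) == [7, 10] and list(counts) == [8, 16]
        assert null.gt_min == 7 and null.gt_max == 10

    def test_exhaustive_pectinate_attains_global_bounds(self, ages4, t_bad):
        null = sc.permutation_null(t_bad, ages4, exhaustive=True)
        assert null.gt_min == sc.g_min(ages4) == 6
        assert null.gt_max == sc.g_max(ages4) == 11

    def test_all_equal_ages_all_zero(self):
        fo = sc.FOTable.from_ages({"A": 5, "B": 5, "C": 5, "D": 5})
        null = sc.permutation_null(sc.parse_newick("((A,B),(C,D));"), fo, reps=20, seed=0)
        assert np.all(null.permuted_mig == 0)

    def test_seed_determinism(self, ages4, t_mid):
        a = sc.permutation_null(t_mid, ages4, reps=100, seed=5)
        b = sc.permutation_null(t_mid, ages4, reps=100, seed=5)
        assert np.array_equal(a.permuted_mig, b.permuted_mig)

    def test_bound_sandwich(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            n = int(rng.integers(4, 20))
            labels = [f"t{i}" for i in range(n)]
            tree = random_binary_tree(rng, labels)
            fo = random_fo_table(rng, labels)
            null = sc.permutation_null(tree, fo, reps=50, seed=int(rng.integers(2**31)))
            assert sc.g_min(fo) <= null.gt_min <= null.observed_mig
            assert null.observed_mig <= null.gt_max <= sc.g_max(fo)

    def test_reps_validation(self, ages4, t_mid):
        with pytest.raises(ValueError):
            sc.permutation_null(t_mid, ages4, reps=0)


class TestGERtAndGERstar:
    def test_gert_exhaustive_exceeds_ger(self, ages4, t_mid):
        null = sc.permutation_null(t_mid, ages4, exhaustive=True)
        assert sc.ger_t(null) == 1.0  # observed MIG equals Gtmin on this topology
        assert sc.ger(t_mid, ages4) == pytest.approx(0.8)

    def test_gert_extremes(self, ages4, t_bad, t_good):
        null_bad = sc.permutation_null(t_bad, ages4, exhaustive=True)
        assert sc.ger_t(null_bad) == 0.0  # observed equals Gtmax
        null_good = sc.permutation_null(t_good, ages4, exhaustive=True)
        assert sc.ger_t(null_good) == 1.0

    def test_gerstar_tie_rules(self, ages4, t_mid):
        null = sc.permutation_null(t_mid, ages4, exhaustive=True)
        assert sc.ger_star(null) == pytest.approx(20 / 24)  # (16 + 8/2)/24
        assert sc.ger_star(null, ties="strict") == pytest.approx(16 / 24)

    def test_gerstar_extremes(self, ages4, t_bad, t_good):
        null = sc.permutation_null(t_bad, ages4, exhaustive=True)
        # observed is the exhaustive maximum; only ties above it
        assert sc.ger_star(null, ties="strict") == 0.0
        null = sc.permutation_null(t_good, ages4, exhaustive=True)
        assert sc.ger_star(null, ties="strict") > 0.9

    def test_gert_undefined_on_degenerate_null(self):
        fo = sc.FOTable.from_ages({"A": 5, "B": 5, "C": 5, "D": 5})
        null = sc.permutation_null(sc.parse_newick("((A,B),(C,D));"), fo, reps=5, seed=0)
        with pytest.raises(sc.UndefinedIndexError):
            sc.ger_t(null)


class TestTopologyArraysKernel:
    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(9)
        n = 12
        labels = [f"t{i}" for i in range(n)]
        tree = random_binary_tree(rng, labels)
        arrays = TopologyArrays(tree)
        for _ in range(10):
            ages = rng.integers(0, 30, n).astype(float)
            fo = sc.FOTable.from_ages(dict(zip(arrays.tip_labels, ages)))
            assert arrays.mig(ages) == sc.mig(tree, fo).mig
            assert arrays.sci(ages) == sc.sci(tree, fo)

    def test_broadcasts_over_rows(self, ages4, t_mid):
        arrays = TopologyArrays(t_mid)
        ages = ages4.ages_for(arrays.tip_labels)
        stacked = np.tile(ages, (5, 1))
        assert np.all(arrays.mig(stacked) == 7)
        assert np.all(arrays.sci(stacked) == 0.5)


class TestIndexReport:
    def test_intermediate_fixture(self, ages4, t_mid):
        report = sc.index_report(t_mid, ages4, reps=200, seed=1)
        assert report.sci == 0.5
        assert report.ger == pytest.approx(0.8)
        assert report.msm_star == pytest.approx(6 / 7)
        assert report.ger_t == 1.0  # Gtmin = 7 is reachable and reached
        assert report.mig == 7 and report.g_min == 6 and report.g_max == 11
        assert report.undefined == {}
        assert report.seed == 1 and report.reps == 200

    def test_star_tree_hard_vs_soft(self, ages4):
        star = sc.parse_newick("(A,B,C,D);")
        hard = sc.index_report(star, ages4, polytomy_mode="hard", reps=50, seed=0)
        soft = sc.index_report(star, ages4, polytomy_mode="soft", reps=50, seed=0)
        assert hard.ger == 0.0
        assert soft.ger == 1.0

    def test_undefined_carried_not_fabricated(self):
        fo = sc.FOTable.from_ages({"A": 5, "B": 5, "C": 5, "D": 5})
        report = sc.index_report(sc.parse_newick("((A,B),(C,D));"), fo, reps=20, seed=0)
        assert report.ger is None and report.msm_star is None and report.ger_t is None
        assert report.undefined["ger"] == "all_fo_equal"

    def test_missing_tip_raises(self, ages4):
        tree = sc.parse_newick("((A,B),(C,Z));")
        with pytest.raises(sc.FOTableError, match="Z"):
            sc.index_report(tree, ages4)
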