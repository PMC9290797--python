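import numpy as np
import pytest
from scipy import stats as sps

from admixscan.core_io import MISSING, WindowSpec
from admixscan.topoweights import (
    GroupAssignment,
    PhasingError,
    TopologyWeights,
    ancestry_correlation,
    ancestry_score,
    classify_window,
    nj_tree,
    quartet_topology,
    topology_weights,
    window_distance_matrix,
    windows_topology_weights,
)
from oracles import four_point_oracle


def window(start, end):
    return WindowSpec("scaf1", start, end, 0, 0, "coordinate")


def random_additive_quartet(rng):
    """Random additive 4-taxon distances with known topology.

    Taxon order is (o, w, e, i); returns (D, true_topology_id).
    """
    topo = int(rng.integers(1, 4))
    ext = rng.uniform(0.05, 1.0, size=4)  # o, w, e, i
    internal = rng.uniform(0.05, 0.5)
    pairs = {1: ((0, 2), (1, 3)), 2: ((0, 1), (2, 3)), 3: ((0, 3), (1, 2))}[topo]
    D = np.zeros((4, 4))
    for a in range(4):
        for b in range(a + 1, 4):
            same_side = any(a in pr and b in pr for pr in pairs)
            d = ext[a] + ext[b] + (0 if same_side else internal)
            D[a, b] = D[b, a] = d
    return D, topo


class TestWindowDistance:
    def test_identical_haplotypes_zero(self, make_hm):
        hm = make_hm(np.array([[0, 1, 0], [0, 1, 0], [1, 0, 1], [1, 1, 1]], np.int8))
        D = window_distance_matrix(hm, window(0, 10), [0, 1, 2, 3])
        assert D[0, 1] == 0.0
        assert np.allclose(np.diag(D), 0.0)
        assert np.allclose(D, D.T)

    def test_counting_example(self, make_hm):
        # 0101 vs 0011 differ at 2 of 4 sites -> 0.5
        hm = make_hm(
            np.array(
                [[0, 1, 0, 1], [0, 0, 1, 1], [0, 0, 0, 0], [1, 1, 1, 1]], np.int8
            )
        )
        D = window_distance_matrix(hm, window(0, 10), [0, 1, 2, 3])
        assert D[0, 1] == pytest.approx(0.5)

    def test_missing_excluded_per_pair(self, make_hm):
        hm = make_hm(
            np.array(
                [
                    [0, 1, MISSING],
                    [0, 0, 1],
                    [1, 1, 1],
                    [0, 0, 0],
                ],
                np.int8,
            )
        )
        D = window_distance_matrix(hm, window(0, 10), [0, 1, 2, 3])
        assert D[0, 1] == pytest.approx(1 / 2)  # 2 comparable sites, 1 diff
        assert D[1, 2] == pytest.approx(2 / 3)  # full 3-site comparison

    def test_zero_comparable_pair_named(self, make_hm):
        hm = make_hm(
            np.array(
                [
                    [0, MISSING],
                    [MISSING, 1],
                    [0, 0],
                    [1, 1],
                ],
                np.int8,
            )
        )
        with pytest.raises(ValueError, match="s0__1.*s0__2"):
            window_distance_matrix(hm, window(0, 10), [0, 1, 2, 3])


class TestNjTree:
    def test_additive_four_taxon_split(self):
        D = np.array(
            [
                [0, 2, 3, 3],
                [2, 0, 3, 3],
                [3, 3, 0, 2],
                [3, 3, 2, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(D, names=["a", "b", "c", "d"])
        # split {a,b}|{c,d}: with roles (o=a, w=b, e=c, i=d) that is {O,W}|{E,I}
        assert quartet_topology(tree, "a", "b", "c", "d") == 2
        # NJ is exact on additive data
        T = tree.leaf_distance_matrix()
        assert np.allclose(T, D, atol=1e-12)

    def test_tie_determinism(self):
        D = np.ones((5, 5)) - np.eye(5)
        t1 = nj_tree(D)
        t2 = nj_tree(D)
        assert t1.to_newick() == t2.to_newick()

    def test_three_taxa_error(self):
        with pytest.raises(ValueError, match="4"):
            nj_tree(np.zeros((3, 3)))

    def test_asymmetric_error(self):
        D = np.array([[0, 1, 2, 3], [1, 0, 1, 2], [2, 1, 0, 1], [3, 2, 1.5, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(D)

    def test_negative_branch_floored(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = int(rng.integers(4, 9))
            M = rng.uniform(0.0, 1.0, size=(n, n))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0.0)
            tree = nj_tree(D)
            assert all(l >= 0 for _, _, l in tree.edges)


class TestQuartetTopology:
    def caterpillar(self, inner_pair):
        """Additive distances for the quartet grouping *inner_pair* together.

        Taxa: o=0, w=1, e=2, i=3.
        """
        D = np.zeros((4, 4))
        for a in range(4):
            for b in range(a + 1, 4):
                same = {a, b} == set(inner_pair) or {a, b} == {0, 1, 2, 3} - set(inner_pair)
                D[a, b] = D[b, a] = 2.0 if same else 3.0
        return D

    def test_west_focal_sister_is_topo1(self):
        tree = nj_tree(self.caterpillar((1, 3)), names=["o", "w", "e", "i"])
        assert quartet_topology(tree, "o", "w", "e", "i") == 1

    def test_west_east_sister_is_topo3(self):
        tree = nj_tree(self.caterpillar((1, 2)), names=["o", "w", "e", "i"])
        assert quartet_topology(tree, "o", "w", "e", "i") == 3

    def test_missing_leaf_errors(self):
        tree = nj_tree(self.caterpillar((1, 3)), names=["o", "w", "e", "i"])
        with pytest.raises(KeyError, match="zzz"):
            quartet_topology(tree, "o", "w", "e", "zzz")

    def test_random_additive_vs_four_point_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            D, truth = random_additive_quartet(rng)
            assert four_point_oracle(D, 0, 1, 2, 3) == truth  # oracle agrees with construction
            tree = nj_tree(D, names=["o", "w", "e", "i"])
            assert quartet_topology(tree, "o", "w", "e", "i") == truth


def sorted_tree_matrix():
    """Haplotype matrix whose NJ tree is perfectly sorted:
    ((west+focal), east), outgroup."""
    hap = {
        "o1": [1, 1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0],
        "o2": [1, 1, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0],
        "w1": [0, 0, 1, 1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0],
        "w2": [0, 0, 1, 1, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0],
        "i1": [0, 0, 1, 0, 1, 0, 0, 0, 0, 0, 1, 0, 0, 0],
        "i2": [0, 0, 1, 0, 1, 0, 0, 0, 0, 0, 0, 1, 0, 0],
        "e1": [0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 1, 0],
        "e2": [0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 1],
    }
    names = list(hap)
    return np.array([hap[n] for n in names], dtype=np.int8), names


class TestTopologyWeights:
    def build_tree(self):
        alleles, names = sorted_tree_matrix()
        n = alleles.shape[1]
        D = np.zeros((8, 8))
        for a in range(8):
            for b in range(8):
                D[a, b] = (alleles[a] != alleles[b]).mean()
        return nj_tree(D, names=names)

    def groups(self):
        return GroupAssignment(
            outgroup=["o1", "o2"], west=["w1", "w2"], east=["e1", "e2"],
            focal=["i1", "i2"],
        )

    def test_perfectly_sorted_weights(self):
        tw = topology_weights(self.build_tree(), self.groups(), n_subtrees=600)
        assert tw.exhaustive  # 2*2*2*2 = 16 <= 600
        assert tw.weights == (1.0, 0.0, 0.0)
        assert tw.unresolved_frac == 0.0

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            D, _ = None, None
            n = 8
            M = rng.uniform(0, 1, (n, n))
            D = (M + M.T) / 2
            np.fill_diagonal(D, 0)
            names = ["o1", "o2", "w1", "w2", "e1", "e2", "i1", "i2"]
            tree = nj_tree(D, names=names)
            tw = topology_weights(tree, self.groups(), n_subtrees=600)
            if not np.isnan(tw.w1):
                assert tw.w1 + tw.w2 + tw.w3 == pytest.approx(1.0, abs=1e-9)

    def test_exhaustive_invariant_to_seed_and_order(self):
        tree = self.build_tree()
        g1 = self.groups()
        g2 = GroupAssignment(
            outgroup=["o2", "o1"], west=["w2", "w1"], east=["e2", "e1"],
            focal=["i2", "i1"],
        )
        a = topology_weights(tree, g1, n_subtrees=600, seed=1)
        b = topology_weights(tree, g1, n_subtrees=600, seed=999)
        c = topology_weights(tree, g2, n_subtrees=600, seed=5)
        assert a.weights == b.weights == c.weights

    def test_sampled_close_to_enumerated(self):
        # larger groups so that sampling kicks in at 600
        rng = np.random.default_rng(7)
        n_per = 5  # 5^4 = 625 > 600
        names = [f"{r}{k}" for r in "owei" for k in range(n_per)]
        M = rng.uniform(0, 1, (len(names), len(names)))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0)
        tree = nj_tree(D, names=names)
        groups = GroupAssignment(
            outgroup=[f"o{k}" for k in range(n_per)],
            west=[f"w{k}" for k in range(n_per)],
            east=[f"e{k}" for k in range(n_per)],
            focal=[f"i{k}" for k in range(n_per)],
        )
        exact = topology_weights(tree, groups, n_subtrees=10**6)
        assert exact.exhaustive
        sampled = topology_weights(tree, groups, n_subtrees=600, seed=0)
        assert not sampled.exhaustive
        for ws, we in zip(sampled.weights, exact.weights):
            bound = 3 * np.sqrt(we * (1 - we) / 600) + 0.01
            assert abs(ws - we) <= bound

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="empty"):
            GroupAssignment(outgroup=[], west=["w"], east=["e"], focal=["i"])


class TestClassifyAndScore:
    def make(self, w1, w2, w3):
        return TopologyWeights(
            w1=w1, w2=w2, w3=w3, unresolved_frac=0.0, n_subtrees=600,
            exhaustive=False,
        )

    def test_majority_classification(self):
        assert classify_window(self.make(0.6, 0.3, 0.1)) == "topo1"
        assert classify_window(self.make(0.2, 0.2, 0.6)) == "topo3"

    def test_strict_boundary_is_ambiguous(self):
        assert classify_window(self.make(0.5, 0.4, 0.1)) == "ambiguous"

    def test_scores(self):
        assert ancestry_score(self.make(1, 0, 0)) == 1
        assert ancestry_score(self.make(0, 1, 0)) == -1
        third = 1 / 3
        assert ancestry_score(self.make(third, third, third)) == 0


class TestAncestryCorrelation:
    def test_identical_is_one(self):
        x = [0.1, 0.5, -0.2, 0.9, 0.0]
        rho, p = ancestry_correlation(x, x)
        assert rho == pytest.approx(1.0)

    def test_reversed_is_minus_one(self):
        x = [1.0, 2.0, 3.0, 4.0]
        rho, _ = ancestry_correlation(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        rho, _ = ancestry_correlation(a, b)
        ra, rb = sps.rankdata(a), sps.rankdata(b)
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError):
            ancestry_correlation([1, 2], [2, 1])

    def test_nan_pairs_dropped(self):
        a = [1.0, np.nan, 2.0, 3.0, 4.0]
        b = [1.0, 5.0, 2.0, 3.0, 4.0]
        rho, _ = ancestry_correlation(a, b)
        assert rho == pytest.approx(1.0)


def test_unphased_input_rejected(make_hm, make_popmap):
    alleles = np.zeros((8, 10), dtype=np.int8)
    hm = make_hm(alleles)
    hm.unphased_het = np.zeros((4, 10), dtype=bool)
    hm.unphased_het[0, 0] = True
    groups = GroupAssignment(
        outgroup=["s0__1", "s0__2"], west=["s1__1", "s1__2"],
        east=["s2__1", "s2__2"], focal=["s3__1", "s3__2"],
    )
    wins = [WindowSpec("scaf1", 0, 10, 0, 10, "snp_count")]
    with pytest.raises(PhasingError):
        windows_topology_weights(hm, wins, groups)
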