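import math
import random

import numpy as np
import pytest

from cspfam.phylo import (
    DistanceMatrix,
    PhyloError,
    bipartitions,
    is_monophyletic,
    leaf_labels,
    nj_tree,
    p_distance,
    poisson_distance,
    split_distance_to_monophyly,
    split_lengths,
)
from cspfam.seqio import read_newick
from cspfam.synthetic_data import random_binary_tree, tree_distance_matrix

from oracles import edge_cut_splits, monophyletic_by_enumeration


class TestPDistance:
    def test_identical_rows(self):
        assert p_distance("MKAV", "MKAV") == 0.0

    def test_forced_count(self):
        assert p_distance("AAAA", "AAAV") == 0.25

    def test_gaps_excluded_from_comparison(self):
        assert p_distance("A-AV", "AKAA") == pytest.approx(1 / 3)

    def test_errors(self):
        with pytest.raises(PhyloError):
            p_distance("AA", "AAA")
        with pytest.raises(PhyloError):
            p_distance("--", "AA")

    def test_scan_oracle_random_pairs(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 40))
            a = "".join(rng.choice(list("AK-"), size=n))
            b = "".join(rng.choice(list("AK-"), size=n))
            pairs = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
            if not pairs:
                continue
            expected = sum(x != y for x, y in pairs) / len(pairs)
            assert p_distance(a, b) == pytest.approx(expected)


class TestPoissonDistance:
    # high-precision values of -ln(1-p)
    @pytest.mark.parametrize(
        "p,expected",
        [
            (0.0, 0.0),
            (0.1, 0.10536051565782631),
            (0.5, 0.6931471805599453),
            (0.9, 2.302585092994046),
        ],
    )
    def test_reference_values(self, p, expected):
        assert poisson_distance(p) == pytest.approx(expected, abs=1e-12)

    def test_monotone(self):
        grid = np.linspace(0, 0.9, 50)
        vals = [poisson_distance(p) for p in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_saturated_pair_capped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            capped = poisson_distance(0.99)
        assert capped == pytest.approx(-math.log(1 - 0.95))


class TestNjTree:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["a", "b", "c"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float))
        tree = nj_tree(dm)
        lengths = {lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(1.0)
        assert lengths["b"] == pytest.approx(2.0)
        assert lengths["c"] == pytest.approx(3.0)

    def test_too_few_taxa(self):
        with pytest.raises(PhyloError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_additive_recovery_exact(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            true = random_binary_tree(6, rng)
            est = nj_tree(tree_distance_matrix(true))
            assert bipartitions(est) == bipartitions(true)
            sl_t, sl_e = split_lengths(true), split_lengths(est)
            assert set(sl_t) == set(sl_e)
            for key in sl_t:
                assert abs(sl_t[key] - sl_e[key]) < 1e-9

    def test_label_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            true = random_binary_tree(7, rng)
            dm = tree_distance_matrix(true)
            perm = rng.permutation(len(dm.labels))
            dm_perm = DistanceMatrix(
                [dm.labels[i] for i in perm], dm.d[np.ix_(perm, perm)]
            )
            assert bipartitions(nj_tree(dm)) == bipartitions(nj_tree(dm_perm))

    def test_matches_independent_nj_on_noisy_matrices(self):
        """Cross-check topology against scikit-bio's neighbor joining."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(31)
        for _ in range(10):
            true = random_binary_tree(8, rng)
            dm = tree_distance_matrix(true)
            noisy = dm.d * rng.uniform(0.95, 1.05, size=dm.d.shape)
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 0.0)
            ours = nj_tree(DistanceMatrix(dm.labels, noisy))
            ref = skbio.tree.nj(skbio.DistanceMatrix(noisy, ids=dm.labels))
            ref_tree = read_newick(str(ref).strip())
            assert bipartitions(ours) == bipartitions(ref_tree)


class TestBipartitions:
    def test_quartet(self):
        assert bipartitions(read_newick("(a,b,(c,d));")) == {frozenset({"c", "d"})}

    def test_caterpillar_split_count(self):
        n = 8
        nw = "((((((t0,t1),t2),t3),t4),t5),(t6,t7));"
        assert len(bipartitions(read_newick(nw))) == n - 3

    def test_matches_edge_cut_enumeration(self):
        rng = np.random.default_rng(41)
        for _ in range(50):
            t = random_binary_tree(int(rng.integers(4, 11)), rng)
            assert bipartitions(t) == edge_cut_splits(t)


class TestIsMonophyletic:
    def test_singleton_true(self):
        t = read_newick("(a,b,(c,d));")
        assert is_monophyletic(t, {"a"})

    def test_quartet_cases(self):
        t = read_newick("(a,b,(c,d));")
        assert is_monophyletic(t, {"c", "d"})
        assert not is_monophyletic(t, {"b", "c"})

    def test_complement_invariance(self):
        rng = np.random.default_rng(43)
        for _ in range(30):
            t = random_binary_tree(8, rng)
            leaves = leaf_labels(t)
            k = int(rng.integers(1, len(leaves)))
            taxa = set(rng.choice(leaves, size=k, replace=False))
            assert is_monophyletic(t, taxa) == is_monophyletic(t, set(leaves) - taxa)

    def test_unknown_leaf(self):
        with pytest.raises(PhyloError):
            is_monophyletic(read_newick("(a,b,(c,d));"), {"z"})

    def test_agrees_with_brute_force(self):
        rng = np.random.default_rng(47)
        for _ in range(200):
            t = random_binary_tree(int(rng.integers(4, 11)), rng)
            leaves = leaf_labels(t)
            k = int(rng.integers(1, len(leaves) + 1))
            taxa = set(rng.choice(leaves, size=k, replace=False))
            assert is_monophyletic(t, taxa) == monophyletic_by_enumeration(t, taxa)


class TestSplitDistance:
    def test_zero_iff_monophyletic(self):
        t = read_newick("(a,b,(c,d));")
        assert split_distance_to_monophyly(t, {"c", "d"}) == 0
        assert split_distance_to_monophyly(t, {"b", "c"}) == 1

    def test_consistency_with_monophyly(self):
        rng = np.random.default_rng(53)
        for _ in range(50):
            t = random_binary_tree(7, rng)
            leaves = leaf_labels(t)
            k = int(rng.integers(1, len(leaves) + 1))
            taxa = set(rng.choice(leaves, size=k, replace=False))
            dist = split_distance_to_monophyly(t, taxa)
            assert (dist == 0) == is_monophyletic(t, taxa)
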