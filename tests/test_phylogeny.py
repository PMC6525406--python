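import itertools

import numpy as np
import pandas as pd
import pytest

import radpop as rp
from radpop.phylogeny import (
    CalibrationPoint,
    bootstrap_support,
    calibrate_ages,
    ml_search,
    nei_distance,
    neighbor_joining,
    population_consensus,
    pruning_loglik,
    upgma,
)
from radpop.snp_matrix import MISSING, PopulationAlleleFrequencies
from radpop.trees import Tree, same_unrooted_topology

from conftest import make_matrix


def freqs_from_array(p, pops):
    p = np.asarray(p, dtype=float)
    sites = pd.DataFrame(
        {
            "chrom": ["chr1"] * len(p),
            "pos": 1 + np.arange(len(p)),
            "ref": ["A"] * len(p),
            "alt": ["C"] * len(p),
        }
    )
    n_alleles = np.where(np.isnan(p), 0, 16).astype(int)
    return PopulationAlleleFrequencies(sites, list(pops), p, n_alleles)


def path_length_matrix(tree: Tree) -> dict[tuple[str, str], float]:
    depths = tree.depths()
    leaves = {n.label: n for n in tree.leaves()}
    out = {}
    for a, b in itertools.combinations(sorted(leaves), 2):
        mrca = tree.mrca([a, b])
        out[(a, b)] = depths[leaves[a]] + depths[leaves[b]] - 2 * depths[mrca]
    return out


class TestNeiDistance:
    def test_identical_frequencies_give_zero(self):
        p = np.column_stack([np.linspace(0.1, 0.9, 20)] * 2)
        d = nei_distance(freqs_from_array(p, ["a", "b"]))
        assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_alleles_capped(self):
        p = np.column_stack(
            [np.ones(10), np.zeros(10), np.full(10, 0.4), np.full(10, 0.6)]
        )
        d = nei_distance(freqs_from_array(p, list("abcd")), cap_factor=2.0)
        finite = [d.loc["a", "c"], d.loc["a", "d"], d.loc["c", "d"], d.loc["b", "c"], d.loc["b", "d"]]
        assert d.loc["a", "b"] == pytest.approx(2.0 * max(finite))

    def test_matches_sitewise_reference_implementation(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.05, 0.95, size=(40, 3))
        d = nei_distance(freqs_from_array(p, list("abc")), unbiased=False)
        for a, b in itertools.combinations(range(3), 2):
            jab = jaa = jbb = 0.0
            for i in range(40):
                pa, pb = p[i, a], p[i, b]
                jab += pa * pb + (1 - pa) * (1 - pb)
                jaa += pa**2 + (1 - pa) ** 2
                jbb += pb**2 + (1 - pb) ** 2
            expected = -np.log(jab / np.sqrt(jaa * jbb))
            assert d.iloc[a, b] == pytest.approx(expected, abs=1e-12)


ADDITIVE = pd.DataFrame(
    [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
    index=list("ABCD"),
    columns=list("ABCD"),
    dtype=float,
)


class TestNeighborJoining:
    def test_exact_on_additive_distances(self):
        # distances from the tree ((A:1,B:2):1,(C:3,D:4))
        tree = neighbor_joining(ADDITIVE)
        truth = Tree.from_newick("((A:1,B:2):1,(C:3,D:4):0);")
        assert same_unrooted_topology(tree, truth)
        paths = path_length_matrix(tree)
        for (a, b), d in paths.items():
            assert d == pytest.approx(ADDITIVE.loc[a, b])

    def test_three_taxa_closed_form(self):
        d = pd.DataFrame(
            [[0, 3, 4], [3, 0, 5], [4, 5, 0]], index=list("ABC"), columns=list("ABC"), dtype=float
        )
        tree = neighbor_joining(d)
        paths = path_length_matrix(tree)
        assert paths[("A", "B")] == pytest.approx(3)
        assert paths[("A", "C")] == pytest.approx(4)
        assert paths[("B", "C")] == pytest.approx(5)

    def test_taxon_order_permutation_invariant(self):
        order = ["C", "A", "D", "B"]
        permuted = ADDITIVE.loc[order, order]
        t1, t2 = neighbor_joining(ADDITIVE), neighbor_joining(permuted)
        assert same_unrooted_topology(t1, t2)
        p1, p2 = path_length_matrix(t1), path_length_matrix(t2)
        for key in p1:
            assert p1[key] == pytest.approx(p2[key])

    def test_asymmetric_input_rejected(self):
        bad = ADDITIVE.copy()
        bad.iloc[0, 1] += 0.1
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(bad)

    def test_agrees_with_skbio_on_random_distances(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(13)
        labels = list("ABCDEF")
        for _ in range(5):
            pts = rng.normal(size=(6, 4))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            dist = pd.DataFrame(d, index=labels, columns=labels)
            ours = neighbor_joining(dist)
            theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
            theirs = Tree.from_newick(str(theirs))
            assert same_unrooted_topology(ours, theirs)


class TestUpgma:
    def test_exact_on_ultrametric_distances(self):
        d = pd.DataFrame(
            [[0, 2, 6], [2, 0, 6], [6, 6, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        tree = upgma(d)
        depths = tree.depths()
        leaves = {n.label: n for n in tree.leaves()}
        height = depths[leaves["A"]]
        assert height == pytest.approx(3.0)  # root at half of max distance
        ab = tree.mrca(["A", "B"])
        assert height - depths[ab] == pytest.approx(1.0)
        paths = path_length_matrix(tree)
        for (a, b), v in paths.items():
            assert v == pytest.approx(d.loc[a, b])


def enumerate_loglik(tree: Tree, gm, site: int) -> float:
    """Oracle: sum over all internal-node state assignments."""
    nodes = list(tree.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    col = {s: i for i, s in enumerate(gm.samples)}

    def tip_states(node):
        d = gm.dosage[site, col[node.label]]
        if d == 0:
            return [0]
        if d == 2:
            return [1]
        return [0, 1]

    def p_change(t):
        return 0.5 * (1 - np.exp(-2 * t))

    total = 0.0
    for assign in itertools.product([0, 1], repeat=len(internal)):
        states = dict(zip(map(id, internal), assign))
        for leaf_states in itertools.product(
            *[tip_states(n) for n in nodes if n.is_leaf]
        ):
            leafs = [n for n in nodes if n.is_leaf]
            s = dict(states)
            s.update({id(n): st for n, st in zip(leafs, leaf_states)})
            prob = 0.5  # stationary at root
            for n in nodes:
                if n.parent is None:
                    continue
                pc = p_change(n.length)
                prob *= pc if s[id(n)] != s[id(n.parent)] else 1 - pc
            total += prob
    return np.log(total)


class TestPruningLikelihood:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(3)
        for rep in range(3):
            newick = "((A:{}, B:{}):{} ,(C:{},D:{}):{});".format(
                *rng.uniform(0.05, 0.5, 6)
            )
            tree = Tree.from_newick(newick)
            dosage = rng.choice([0, 1, 2, MISSING], size=(4, 4))
            gm = make_matrix(dosage, samples=list("ABCD"))
            expected = sum(enumerate_loglik(tree, gm, i) for i in range(4))
            assert pruning_loglik(tree, gm) == pytest.approx(expected, abs=1e-9)

    def test_five_tip_enumeration(self):
        rng = np.random.default_rng(4)
        tree = Tree.from_newick(
            "(((A:0.1,B:0.2):0.1,C:0.3):0.1,(D:0.2,E:0.1):0.15);"
        )
        dosage = rng.choice([0, 2], size=(6, 5))
        gm = make_matrix(dosage, samples=list("ABCDE"))
        expected = sum(enumerate_loglik(tree, gm, i) for i in range(6))
        assert pruning_loglik(tree, gm) == pytest.approx(expected, abs=1e-9)

    def test_saturation_limit_closed_form(self):
        tree = Tree.from_newick("((A:50,B:50):50,(C:50,D:50):50);")
        dosage = np.array([[0, 2, 0, 2], [0, 0, 1, MISSING]])
        gm = make_matrix(dosage, samples=list("ABCD"))
        # per site: (1/2)^(#unambiguous tips)
        expected = 4 * np.log(0.5) + 2 * np.log(0.5)
        assert pruning_loglik(tree, gm) == pytest.approx(expected, abs=1e-6)

    def test_zero_lengths_identical_tips_give_half(self):
        tree = Tree.from_newick("((A:0,B:0):0,(C:0,D:0):0);")
        gm = make_matrix([[0, 0, 0, 0]], samples=list("ABCD"))
        assert pruning_loglik(tree, gm) == pytest.approx(np.log(0.5))

    def test_missing_tip_raises(self):
        tree = Tree.from_newick("((A:1,B:1):1,(C:1,nope:1):1);")
        gm = make_matrix([[0, 0, 0, 0]], samples=list("ABCD"))
        with pytest.raises(KeyError, match="nope"):
            pruning_loglik(tree, gm)

    def test_ascertainment_correction_increases_loglik(self):
        tree = Tree.from_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        dosage = np.array([[0, 2, 0, 2], [2, 0, 2, 0]])
        gm = make_matrix(dosage, samples=list("ABCD"))
        plain = pruning_loglik(tree, gm)
        corrected = pruning_loglik(tree, gm, asc_correction=True)
        assert corrected > plain  # dividing by P(variable) < 1


class TestMlSearch:
    def test_fixed_point_on_optimal_start(self, small_matrix):
        cons = population_consensus(small_matrix)
        freqs = rp.allele_frequencies(small_matrix)
        start = neighbor_joining(nei_distance(freqs), outgroup="E")
        tree, ll, trace = ml_search(cons, start)
        assert same_unrooted_topology(tree, start)
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    def test_returned_loglik_self_consistent(self, small_matrix):
        cons = population_consensus(small_matrix)
        start = neighbor_joining(
            nei_distance(rp.allele_frequencies(small_matrix)), outgroup="E"
        )
        tree, ll, _ = ml_search(cons, start)
        assert pruning_loglik(tree, cons) == pytest.approx(ll, abs=1e-9)

    def test_escapes_wrong_start_topology(self, small_matrix, five_pop_tree):
        cons = population_consensus(small_matrix)
        wrong = Tree.from_newick(
            "(((A:0.02,C:0.02):0.02,B:0.04):0.02,(D:0.04,E:0.04):0.02);"
        )
        tree, _, _ = ml_search(cons, wrong)
        assert same_unrooted_topology(tree, five_pop_tree)


class TestBootstrap:
    def test_single_replicate_supports_are_binary(self, small_matrix):
        tree = bootstrap_support(small_matrix, n_reps=1, seed=5, outgroup="E")
        sups = [
            n.support
            for n in tree.postorder()
            if n.support is not None
        ]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_strong_divergence_gives_high_support(self, small_matrix, five_pop_tree):
        tree = bootstrap_support(small_matrix, n_reps=100, seed=5, outgroup="E")
        true_splits = five_pop_tree.bipartitions()
        split_support = {}
        from radpop.trees import _subtree_leaves

        all_tips = set(tree.tip_labels())
        anchor = min(all_tips)
        for node in tree.postorder():
            if node.is_leaf or node.parent is None or node.support is None:
                continue
            below = {n.label for n in _subtree_leaves(node)}
            side = below if anchor not in below else all_tips - below
            split_support[frozenset(side)] = node.support
        for split in true_splits:
            assert split_support.get(split, 0.0) >= 90.0


class TestCalibration:
    def test_calibration_node_pinned_to_midpoint(self):
        d = pd.DataFrame(
            [[0, 0.2, 1.0], [0.2, 0, 1.0], [1.0, 1.0, 0]],
            index=["a", "b", "out"], columns=["a", "b", "out"], dtype=float,
        )
        cal = CalibrationPoint("a", "out", 13.60, 13.88)
        tree = calibrate_ages(d, cal)
        assert tree.mrca(["a", "out"]).age == pytest.approx(13.74)

    def test_scale_invariance_of_ages(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(5, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = list("abcde")
        cal = CalibrationPoint("a", "e", 10.0, 12.0)
        d1 = pd.DataFrame(d, index=labels, columns=labels)
        d2 = pd.DataFrame(7.3 * d, index=labels, columns=labels)
        t1, t2 = calibrate_ages(d1, cal), calibrate_ages(d2, cal)
        for n1, n2 in zip(t1.postorder(), t2.postorder()):
            assert n1.age == pytest.approx(n2.age)

    def test_ages_decrease_toward_tips(self):
        rng = np.random.default_rng(10)
        pts = rng.normal(size=(6, 3))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = list("abcdef")
        tree = calibrate_ages(
            pd.DataFrame(d, index=labels, columns=labels),
            CalibrationPoint("a", "f", 5.0, 6.0),
        )
        for node in tree.postorder():
            for child in node.children:
                assert node.age >= child.age - 1e-12
        assert all(leaf.age == 0.0 for leaf in tree.leaves())

    def test_unseparated_calibration_taxa_raise(self):
        d = pd.DataFrame(
            [[0, 0.0, 1.0], [0.0, 0, 1.0], [1.0, 1.0, 0]],
            index=["a", "b", "out"], columns=["a", "b", "out"], dtype=float,
        )
        with pytest.raises(ValueError, match="not separated"):
            calibrate_ages(d, CalibrationPoint("a", "b", 1.0, 2.0))
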