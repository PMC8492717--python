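import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitopop.alignment import from_strings
from mitopop.nj import (
    DistanceMatrix,
    PhyloError,
    _tn93,
    assign_lineage,
    bootstrap_support,
    distance_matrix,
    nj_tree,
)
from tests.conftest import random_alignment


# --- random additive matrices from known trees -----------------------------

def random_tree_distances(rng, n_taxa):
    """Random unrooted binary tree -> (names, distance matrix, bipartitions)."""
    names = [f"t{i}" for i in range(n_taxa)]
    # adjacency with branch lengths; start from a 3-star
    next_id = [n_taxa]
    edges = {}

    def add_edge(u, v, w):
        edges[(u, v)] = w
        edges[(v, u)] = w

    center = next_id[0]
    next_id[0] += 1
    for leaf in range(3):
        add_edge(leaf, center, float(rng.uniform(0.1, 1.0)))
    for leaf in range(3, n_taxa):
        # split a random existing edge
        keys = [k for k in edges if k[0] < k[1]]
        u, v = keys[int(rng.integers(len(keys)))]
        w = edges[(u, v)]
        mid = next_id[0]
        next_id[0] += 1
        del edges[(u, v)], edges[(v, u)]
        f = float(rng.uniform(0.2, 0.8))
        add_edge(u, mid, w * f)
        add_edge(mid, v, w * (1 - f))
        add_edge(leaf, mid, float(rng.uniform(0.1, 1.0)))

    # path distances between leaves
    nodes = set(x for k in edges for x in k)
    dist = np.zeros((n_taxa, n_taxa))
    adj = {}
    for (u, v), w in edges.items():
        adj.setdefault(u, []).append((v, w))
    for src in range(n_taxa):
        d = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in d:
                    d[y] = d[x] + w
                    stack.append(y)
        for dst in range(n_taxa):
            dist[src, dst] = d[dst]

    # true non-trivial bipartitions
    ref = min(names)
    biparts = set()
    for (u, v) in [k for k in edges if k[0] < k[1]]:
        side = set()
        stack = [u]
        seen = {u, v}
        while stack:
            x = stack.pop()
            if x < n_taxa:
                side.add(names[x])
            for y, _ in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        if ref in side:
            side = set(names) - side
        if 1 < len(side) < n_taxa - 1:
            biparts.add(frozenset(side))
    return names, dist, biparts


def nontrivial_bipartitions(tree):
    n = len(tree.leaves)
    return {bp for bp in tree.bipartitions() if 1 < len(bp) < n - 1}


class TestDistanceModels:
    @pytest.mark.parametrize("model", ["p", "k2p", "tn93", "mcl"])
    def test_identical_pair_zero(self, model):
        a = from_strings(["ACGTACGTAC" * 4] * 2)
        d = distance_matrix(a, model)
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_p_distance(self):
        s1 = "A" * 100
        s2 = "T" * 3 + "A" * 97
        d = distance_matrix(from_strings([s1, s2]), "p")
        assert d.values[0, 1] == pytest.approx(0.03)

    def test_k2p_closed_form(self):
        # 2 transitions (A->G), 1 transversion (A->T) over 100 sites
        s1 = "A" * 100
        s2 = "GG" + "T" + "A" * 97
        d = distance_matrix(from_strings([s1, s2]), "k2p")
        P, Q = 0.02, 0.01
        expected = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert d.values[0, 1] == pytest.approx(expected)

    def test_tn93_equal_freqs_reduces_to_k2p(self):
        g = {b"A": 0.25, b"C": 0.25, b"G": 0.25, b"T": 0.25}
        p1 = p2 = 0.01
        q = 0.01
        P, Q = p1 + p2, q
        k2p = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert _tn93(p1, p2, q, g) == pytest.approx(k2p)

    def test_saturated_pair_flagged(self):
        s1 = "AG" * 50
        s2 = "GA" * 50
        d = distance_matrix(from_strings([s1, s2]), "k2p")
        assert d.saturated_pairs
        assert d.values[0, 1] == pytest.approx(5.0)

    @pytest.mark.parametrize("model", ["p", "k2p", "tn93", "mcl"])
    def test_symmetric_zero_diagonal(self, model, rng):
        a = random_alignment(rng, 6, 200)
        d = distance_matrix(a, model)
        assert np.allclose(d.values, d.values.T)
        assert np.allclose(np.diag(d.values), 0.0)
        assert (d.values >= 0).all()


class TestNjTree:
    def test_additive_four_taxon_exact(self):
        # ((A:2,B:3):1,(C:4,D:5))
        names = ["A", "B", "C", "D"]
        d = np.array(
            [
                [0, 5, 7, 8],
                [5, 0, 8, 9],
                [7, 8, 0, 9],
                [8, 9, 9, 0],
            ],
            dtype=float,
        )
        tree = nj_tree(DistanceMatrix(names, d, "p"))
        assert nontrivial_bipartitions(tree) == {frozenset({"C", "D"})}
        leaf_edge = {
            e.u if e.u in names else e.v: e.length
            for e in tree.edges
            if e.u in names or e.v in names
        }
        assert leaf_edge["A"] == pytest.approx(2.0)
        assert leaf_edge["B"] == pytest.approx(3.0)
        assert leaf_edge["C"] == pytest.approx(4.0)
        assert leaf_edge["D"] == pytest.approx(5.0)
        internal = [
            e for e in tree.edges if e.u not in names and e.v not in names
        ]
        assert len(internal) == 1
        assert internal[0].length == pytest.approx(1.0)

    def test_star_tie_deterministic(self):
        names = ["a", "b", "c", "d"]
        d = np.ones((4, 4)) - np.eye(4)
        t1 = nj_tree(DistanceMatrix(names, d, "p"))
        t2 = nj_tree(DistanceMatrix(list(names), d.copy(), "p"))
        assert t1.newick() == t2.newick()

    def test_matches_reference_nj_oracle(self, rng):
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        for _ in range(5):
            names, dist, _ = random_tree_distances(rng, 6)
            noisy = dist + rng.uniform(0, 0.01, size=dist.shape)
            noisy = (noisy + noisy.T) / 2
            np.fill_diagonal(noisy, 0.0)
            mine = nj_tree(DistanceMatrix(names, noisy, "p"))
            sk_tree = sk_nj(SkDM(noisy, ids=names))
            ref = min(names)
            sk_biparts = set()
            for node in sk_tree.non_tips():
                side = frozenset(t.name for t in node.tips())
                if ref in side:
                    side = frozenset(set(names) - side)
                if 1 < len(side) < len(names) - 1:
                    sk_biparts.add(side)
            assert nontrivial_bipartitions(mine) == sk_biparts

    def test_too_few_taxa(self):
        with pytest.raises(PhyloError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2)), "p"))

    def test_newick_parses(self, rng):
        import dendropy

        names, dist, _ = random_tree_distances(rng, 7)
        tree = nj_tree(DistanceMatrix(names, dist, "p"))
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert {l.taxon.label for l in parsed.leaf_node_iter()} == set(names)


@settings(max_examples=20, deadline=None)
@given(st.integers(0, 2**32 - 1), st.integers(4, 8))
def test_nj_exact_on_additive_matrices(seed, n_taxa):
    rng = np.random.default_rng(seed)
    names, dist, true_biparts = random_tree_distances(rng, n_taxa)
    tree = nj_tree(DistanceMatrix(names, dist, "p"))
    assert nontrivial_bipartitions(tree) == true_biparts
    # branch lengths reproduce the additive metric
    for i, a in enumerate(names):
        paths = tree.leaf_path_lengths(a)
        for j, b in enumerate(names):
            assert paths[b] == pytest.approx(dist[i, j], abs=1e-9)


class TestBootstrap:
    @staticmethod
    def _two_clade_alignment():
        left = "A" * 30 + "C" * 30
        right = "T" * 30 + "C" * 30
        seqs = []
        for i in range(4):
            s = list(left)
            s[50 + i] = "G"  # private mutation
            seqs.append("".join(s))
        for i in range(4):
            s = list(right)
            s[54 + i] = "G"
            seqs.append("".join(s))
        return from_strings(seqs)

    def test_clear_clades_full_support(self):
        a = self._two_clade_alignment()
        tree = bootstrap_support(a, B=50, seed=1)
        clade = frozenset({"s4", "s5", "s6", "s7"})
        supports = {
            bp: e.support for bp, e in tree.bipartitions().items() if e.support is not None
        }
        assert supports[clade] > 95

    def test_single_replicate_binary_support(self):
        a = self._two_clade_alignment()
        tree = bootstrap_support(a, B=1, seed=7)
        for e in tree.edges:
            if e.support is not None:
                assert e.support in (0.0, 100.0)

    def test_deterministic_with_seed(self, rng):
        a = random_alignment(rng, 6, 80)
        t1 = bootstrap_support(a, B=100, seed=42)
        t2 = bootstrap_support(a, B=100, seed=42)
        s1 = sorted(e.support for e in t1.edges if e.support is not None)
        s2 = sorted(e.support for e in t2.edges if e.support is not None)
        assert s1 == s2

    def test_invalid_b(self, rng):
        a = random_alignment(rng, 5, 30)
        with pytest.raises(PhyloError):
            bootstrap_support(a, B=0, seed=1)


class TestAssignLineage:
    @staticmethod
    def _refs():
        ref_a = "A" * 40
        ref_b = "T" * 20 + "A" * 20
        return from_strings(
            [ref_a, ref_b], sample_ids=["ref_A", "ref_B"], pops=["A", "B"]
        )

    def test_copy_of_reference_gets_own_label(self):
        refs = self._refs()
        samples = from_strings(["A" * 40], sample_ids=["q1"])
        for method in ("min_distance", "nj_clade"):
            res = assign_lineage(samples, refs, method=method)
            assert res.labels["q1"] == "A"

    def test_one_vs_twenty_mutations(self):
        refs = self._refs()
        near_a = "C" + "A" * 39  # 1 from A, 20 from B
        res = assign_lineage(
            from_strings([near_a], sample_ids=["q1"]), refs, method="min_distance"
        )
        assert res.labels["q1"] == "A"
        assert "q1" not in res.ambiguous

    def test_equidistant_flagged_ambiguous(self):
        refs = self._refs()
        mid = "T" * 10 + "A" * 30  # 10 from both
        res = assign_lineage(
            from_strings([mid], sample_ids=["q1"]), refs, method="min_distance"
        )
        assert "q1" in res.ambiguous

    def test_methods_agree_on_clear_data(self, rng):
        refs = self._refs()
        seqs, ids = [], []
        truth = {}
        for i in range(6):
            base = list("A" * 40 if i % 2 == 0 else "T" * 20 + "A" * 20)
            j = int(rng.integers(0, 40))
            base[j] = "G"
            seqs.append("".join(base))
            ids.append(f"q{i}")
            truth[f"q{i}"] = "A" if i % 2 == 0 else "B"
        samples = from_strings(seqs, sample_ids=ids)
        r1 = assign_lineage(samples, refs, method="min_distance")
        r2 = assign_lineage(samples, refs, method="nj_clade")
        assert r1.labels == truth
        assert r2.labels == truth

    def test_length_mismatch(self):
        refs = self._refs()
        with pytest.raises(PhyloError):
            assign_lineage(from_strings(["AAA"], sample_ids=["q"]), refs)
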