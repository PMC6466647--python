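"""Divergence arithmetic, JC dating, modality profiles and NJ trees
(with exhaustive and skbio oracles)."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tedyn import evodate
from tedyn.evodate import (
    DatingConfig,
    SaturationError,
    date_from_k,
    divergence_profile,
    jc_correct,
    nj_tree,
    p_distance,
    star_shape_score,
)


class TestPDistance:
    def test_identical_sequences(self):
        assert p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_five_substitutions_in_twenty(self):
        a = "ACGTACGTACGTACGTACGT"
        b = "TCGTTCGTCCGTACGAACGA"  # 5 substitutions
        assert p_distance(a, b) == pytest.approx(0.25)

    def test_gap_columns_excluded(self):
        # deletion of one base: optimal alignment gaps it out; remaining
        # columns match perfectly
        a = "ACGTACGTACGT"
        b = "ACGTCGTACGT"
        assert p_distance(a, b) == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            p_distance("", "ACGT")


class TestJukesCantor:
    def test_zero(self):
        assert jc_correct(0.0) == 0.0

    def test_quarter(self):
        assert jc_correct(0.25) == pytest.approx(0.304099, abs=1e-6)

    def test_saturation_boundary(self):
        with pytest.raises(SaturationError):
            jc_correct(0.75)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=0.74))
    def test_monotone_and_at_least_p(self, p):
        k = jc_correct(p)
        assert k >= p or math.isclose(k, p, rel_tol=1e-12)  # 1-ulp slack at tiny p
        assert jc_correct(min(p + 0.005, 0.745)) >= k


class TestDating:
    def test_published_rate_conversion(self):
        t = date_from_k(0.26, DatingConfig())
        assert t == pytest.approx(0.26 / (2 * 5.62e-9))
        assert t / 1e6 == pytest.approx(23.13, abs=0.01)

    def test_formula_at_point_45(self):
        assert date_from_k(0.45) == pytest.approx(4.0036e7, rel=1e-4)

    def test_zero(self):
        assert date_from_k(0.0) == 0.0

    def test_linearity(self):
        assert date_from_k(0.4) == pytest.approx(2 * date_from_k(0.2))

    def test_rate_is_twice_coding_rate(self):
        cfg = DatingConfig(coding_rate=2.81e-9)
        assert cfg.rate == pytest.approx(5.62e-9)


def _mutate_copies(rng, seed, d, n):
    out = []
    L = len(seed)
    for _ in range(n):
        arr = np.array(list(seed))
        m = rng.binomial(L, d)
        sites = rng.choice(L, size=m, replace=False)
        for s in sites:
            arr[s] = rng.choice([c for c in "ACGT" if c != arr[s]])
        out.append("".join(arr))
    return out


def _expected_pairwise_k(d, L, rng, reps=300):
    """Direct simulation oracle for the expected pairwise JC distance of two
    copies independently mutated at per-copy divergence d."""
    seed = "".join(rng.choice(list("ACGT"), size=L))
    ks = []
    for _ in range(reps):
        a, b = _mutate_copies(rng, seed, d, 2)
        ks.append(jc_correct(p_distance(a, b)))
    return float(np.mean(ks))


class TestDivergenceProfile:
    def test_single_burst_unimodal_peak_position(self, rng):
        seed = "".join(rng.choice(list("ACGT"), size=300))
        members = _mutate_copies(rng, seed, 0.13, 30)
        prof = divergence_profile(members, "fam")
        assert prof.modality == "unimodal"
        expected = _expected_pairwise_k(0.13, 300, np.random.default_rng(9))
        assert len(prof.peak_positions) == 1
        assert abs(prof.peak_positions[0] - expected) <= 0.02  # one bin

    def test_two_bursts_multimodal(self, rng):
        seed = "".join(rng.choice(list("ACGT"), size=300))
        members = _mutate_copies(rng, seed, 0.01, 15) + _mutate_copies(rng, seed, 0.25, 15)
        prof = divergence_profile(members, "fam")
        assert prof.modality == "multimodal"
        assert len(prof.peak_positions) >= 2

    def test_two_identical_members(self):
        prof = divergence_profile(["ACGTACGT" * 10, "ACGTACGT" * 10])
        assert prof.modality == "unimodal"
        assert prof.mean_k == 0.0

    def test_single_member_rejected(self):
        with pytest.raises(evodate.InsufficientDataError):
            divergence_profile(["ACGTACGT"])


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _leaf_path_lengths(tree):
    """Leaf-to-leaf path-length matrix from the tree (clamping none)."""
    dists = {}

    def walk(node, path):
        if node.is_leaf():
            dists[node.name] = dict(path)
            return
        for child, length in node.children:
            walk(child, [(n, d + length) for n, d in path] + [(child, 0)])

    # easier: accumulate distances from root to every node, then combine
    depths = {}

    def depth_walk(node, depth):
        depths[id(node)] = depth
        if node.is_leaf():
            depths[node.name] = depth
        for child, length in node.children:
            depth_walk(child, depth + length)

    depth_walk(tree, 0.0)

    # lowest common ancestor via parent maps
    parents = {}

    def parent_walk(node):
        for child, _ in node.children:
            parents[id(child)] = node
            parent_walk(child)

    parent_walk(tree)

    leaves = []

    def collect(node):
        if node.is_leaf():
            leaves.append(node)
        for child, _ in node.children:
            collect(child)

    collect(tree)

    def ancestors(node):
        out = [id(node)]
        while id(node) in parents:
            node = parents[id(node)]
            out.append(id(node))
        return out

    n = len(leaves)
    mat = {}
    for a, b in itertools.combinations(leaves, 2):
        anc_a = ancestors(a)
        anc_b = set(ancestors(b))
        lca = next(x for x in anc_a if x in anc_b)
        d = depths[id(a)] + depths[id(b)] - 2 * depths[lca]
        mat[(a.name, b.name)] = mat[(b.name, a.name)] = d
    return mat


def _random_additive_tree(rng, n):
    """Random unrooted binary tree with positive branch lengths, returned as
    a leaf distance matrix (additive by construction)."""
    # start from a 3-star, insert remaining leaves on random edges
    import collections

    edges = {}  # node -> dict(neighbor -> length)

    def add_edge(u, v, w):
        edges.setdefault(u, {})[v] = w
        edges.setdefault(v, {})[u] = w

    internal = ["i0"]
    for i, leaf in enumerate(["t0", "t1", "t2"]):
        add_edge("i0", leaf, float(rng.uniform(0.5, 3.0)))
    next_internal = 1
    for i in range(3, n):
        # pick a random edge
        all_edges = [(u, v) for u in edges for v in edges[u] if u < v]
        u, v = all_edges[int(rng.integers(len(all_edges)))]
        w = edges[u].pop(v)
        edges[v].pop(u)
        mid = f"i{next_internal}"
        next_internal += 1
        split = float(rng.uniform(0.2, 0.8))
        add_edge(u, mid, w * split)
        add_edge(mid, v, w * (1 - split))
        add_edge(mid, f"t{i}", float(rng.uniform(0.5, 3.0)))
    # BFS distances between leaves
    leaves = [f"t{i}" for i in range(n)]
    dm = np.zeros((n, n))
    for i, leaf in enumerate(leaves):
        dist = {leaf: 0.0}
        q = collections.deque([leaf])
        while q:
            x = q.popleft()
            for y, w in edges[x].items():
                if y not in dist:
                    dist[y] = dist[x] + w
                    q.append(y)
        for j, other in enumerate(leaves):
            dm[i, j] = dist[other]
    return dm, leaves


class TestNeighborJoining:
    def test_two_taxa_split_edge(self):
        tree = nj_tree(np.array([[0.0, 2.0], [2.0, 0.0]]), ["a", "b"])
        lengths = sorted(l for _c, l in tree.children)
        assert lengths == [1.0, 1.0]

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], float)
        tree = nj_tree(d, ["a", "b", "c"])
        # v_i = (d_ij + d_ik - d_jk)/2 -> a:2, b:3, c:7
        got = {c.name: l for c, l in tree.children}
        assert got == pytest.approx({"a": 2.0, "b": 3.0, "c": 7.0})

    def test_four_taxon_additive_matrix_recovered(self):
        d = np.array(
            [[0, 3, 8, 9], [3, 0, 9, 10], [8, 9, 0, 9], [9, 10, 9, 0]], float
        )
        tree = nj_tree(d, ["A", "B", "C", "D"])
        paths = _leaf_path_lengths(tree)
        for i, a in enumerate("ABCD"):
            for j, b in enumerate("ABCD"):
                if i < j:
                    assert paths[(a, b)] == pytest.approx(d[i, j])

    def test_random_additive_trees_recovered_exactly(self):
        """NJ is consistent on additive distances: the induced leaf path
        lengths reproduce the input matrix (n <= 8)."""
        rng = np.random.default_rng(11)
        for n in (4, 5, 6, 8):
            dm, names = _random_additive_tree(rng, n)
            tree = nj_tree(dm, names)
            paths = _leaf_path_lengths(tree)
            for i, j in itertools.combinations(range(n), 2):
                assert paths[(names[i], names[j])] == pytest.approx(dm[i, j], abs=1e-9)

    def test_agrees_with_skbio_on_noisy_matrix(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(12)
        base, names = _random_additive_tree(rng, 6)
        noisy = base + rng.uniform(0, 0.05, base.shape)
        noisy = (noisy + noisy.T) / 2
        np.fill_diagonal(noisy, 0)
        ours = nj_tree(noisy, names)
        theirs = skbio_nj(DistanceMatrix(noisy, names))
        ours_paths = _leaf_path_lengths(ours)
        for a, b in itertools.combinations(names, 2):
            assert ours_paths[(a, b)] == pytest.approx(
                theirs.find(a).distance(theirs.find(b)), abs=1e-6
            )

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(np.array([[0, 1.0], [2.0, 0]]), ["a", "b"])


class TestStarShape:
    def test_perfect_star_scores_zero(self):
        d = np.full((5, 5), 2.0)
        np.fill_diagonal(d, 0.0)
        tree = nj_tree(d, list("abcde"))
        assert star_shape_score(tree) == pytest.approx(0.0, abs=1e-9)

    def test_two_clade_tree_scores_higher(self, rng):
        seed = "".join(rng.choice(list("ACGT"), size=240))
        one_burst = _mutate_copies(rng, seed, 0.08, 8)
        # second clade descends from a diverged ancestor: a long internal edge
        (ancestor,) = _mutate_copies(rng, seed, 0.30, 1)
        two_burst = _mutate_copies(rng, seed, 0.02, 4) + _mutate_copies(
            rng, ancestor, 0.02, 4
        )

        def score(members):
            dm = evodate.family_distance_matrix(members)
            return star_shape_score(nj_tree(dm, [f"m{i}" for i in range(len(members))]))

        assert score(one_burst) < score(two_burst)
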