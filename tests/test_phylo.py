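"""Distances, neighbor joining and bootstrap against independent oracles."""

import math
import random

import numpy as np
import pytest

from trbannot.phylo import (
    DistanceMatrix,
    SATURATION_CEILING,
    Tree,
    bootstrap_supports,
    compute_distances,
    nj_tree,
)


# --- independent random additive-tree generator -----------------------------


def random_additive_tree(n, rng):
    """Random binary tree with positive branch lengths; returns
    (ids, distance matrix, set of non-trivial bipartitions)."""
    nodes = [(f"t{i}", None) for i in range(n)]  # (label, children)
    active = list(range(n))
    children = {i: None for i in range(n)}
    lengths = {}
    next_id = n
    parent_of = {}
    while len(active) > 2:
        i, j = sorted(rng.sample(range(len(active)), 2))
        a, b = active[i], active[j]
        children[next_id] = (a, b)
        lengths[a] = rng.uniform(0.05, 1.0)
        lengths[b] = rng.uniform(0.05, 1.0)
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    a, b = active
    root = next_id
    children[root] = (a, b)
    lengths[a] = rng.uniform(0.05, 1.0)
    lengths[b] = rng.uniform(0.05, 1.0)

    def leaves_of(x):
        if x < n:
            return {x}
        l, r = children[x]
        return leaves_of(l) | leaves_of(r)

    # path distances
    def depth_paths(x, acc, out):
        if x < n:
            out[x] = acc
            return
        for c in children[x]:
            depth_paths(c, acc + [(c, lengths[c])], out)

    paths = {}
    depth_paths(root, [], paths)
    ids = [f"t{i}" for i in range(n)]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi = {e for e, _ in paths[i]}
            pj = {e for e, _ in paths[j]}
            d = sum(l for e, l in paths[i] if e not in pj) + sum(
                l for e, l in paths[j] if e not in pi
            )
            D[i, j] = D[j, i] = d
    all_leaves = frozenset(ids)
    anchor = min(all_leaves)
    bips = set()
    for x in children:
        if x < n or x == root:
            continue
        clade = frozenset(f"t{i}" for i in leaves_of(x))
        side = clade if anchor not in clade else all_leaves - clade
        if 1 < len(side) < n - 1:
            bips.add(side)
    return ids, D, bips


class TestDistances:
    def test_identical_zero(self):
        d = compute_distances({"a": "ACGTACGT", "b": "ACGTACGT", "c": "ACGTACGA"})
        assert d.values[0, 1] == 0.0

    def test_p_distance_direct_count(self):
        d = compute_distances({"a": "AAAA", "b": "AAAT", "c": "TTTT"})
        assert d.values[0, 1] == pytest.approx(0.25)
        assert d.values[0, 2] == pytest.approx(1.0)

    def test_pairwise_deletion_skips_gapped_sites(self):
        d = compute_distances({"a": "A-GT", "b": "ACGA", "c": "ACGT"})
        # a vs b compares 3 sites, 1 differs
        assert d.values[0, 1] == pytest.approx(1 / 3)

    def test_complete_deletion_drops_columns_globally(self):
        d = compute_distances(
            {"a": "A-GT", "b": "ACGA", "c": "ACGT"}, deletion="complete"
        )
        # column 2 dropped everywhere: 3 sites compared for b vs c
        assert d.values[1, 2] == pytest.approx(1 / 3)

    def test_poisson_saturation_flagged(self):
        d = compute_distances({"a": "AAAA", "b": "TTTT", "c": "AAAA"}, model="poisson")
        assert d.values[0, 1] == SATURATION_CEILING
        assert d.saturated[0, 1]

    def test_k2p_transitions_vs_transversions(self):
        # A<->G is a transition, A<->T a transversion
        a, b = "A" * 100, "G" * 10 + "A" * 90
        d = compute_distances({"a": a, "b": b, "c": a}, model="k2p")
        P, Q = 0.1, 0.0
        want = -0.5 * math.log(1 - 2 * P - Q) - 0.25 * math.log(1 - 2 * Q)
        assert d.values[0, 1] == pytest.approx(want)

    def test_matches_site_loop_oracle(self):
        rng = np.random.default_rng(0)
        seqs = {
            f"s{i}": "".join(rng.choice(list("ACGT-"), size=100, p=[0.23, 0.23, 0.23, 0.23, 0.08]))
            for i in range(6)
        }
        d = compute_distances(seqs, model="p")
        ids = list(seqs)
        for i in range(6):
            for j in range(i + 1, 6):
                a, b = seqs[ids[i]], seqs[ids[j]]
                diffs = comp = 0
                for x, y in zip(a, b):
                    if x == "-" or y == "-":
                        continue
                    comp += 1
                    diffs += x != y
                assert d.values[i, j] == pytest.approx(diffs / comp)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            compute_distances({"a": "ACGT", "b": "ACG"})


class TestNJ:
    def test_three_taxon_closed_form(self):
        D = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = nj_tree(DistanceMatrix(["a", "b", "c"], D))
        lengths = {c.name: c.length for c in tree.root.children}
        assert lengths == {"a": 1.0, "b": 1.0, "c": 3.0}

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["a", "b"], np.zeros((2, 2))))

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            DistanceMatrix(["a", "b", "c"], m)

    def test_recovers_random_additive_trees_exactly(self):
        rng = random.Random(42)
        for rep in range(50):
            n = rng.randint(4, 10)
            ids, D, want = random_additive_tree(n, rng)
            tree = nj_tree(DistanceMatrix(ids, D))
            assert tree.bipartitions() == want, f"rep {rep} n={n}"
            # additive matrices are reproduced by the tree's path lengths
            got = _tree_distances(tree, ids)
            assert np.allclose(got, D, atol=1e-9)

    def test_all_equal_distances_resolved_deterministically(self):
        n = 5
        D = np.ones((n, n)) - np.eye(n)
        ids = [f"x{i}" for i in range(n)]
        t1 = nj_tree(DistanceMatrix(ids, D.copy()))
        t2 = nj_tree(DistanceMatrix(ids, D.copy()))
        assert t1.newick() == t2.newick()
        assert len(t1.bipartitions()) == n - 3  # fully resolved

    def test_cross_check_against_dendropy_nj(self):
        import dendropy

        rng = random.Random(7)
        ids, D, _ = random_additive_tree(8, rng)
        # perturb slightly so the matrix is non-additive (generic case)
        noise = np.array([[rng.uniform(0, 0.01) for _ in ids] for _ in ids])
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        D2 = D + noise
        mine = nj_tree(DistanceMatrix(ids, D2))
        csv = "," + ",".join(ids) + "\n"
        for i, a in enumerate(ids):
            csv += a + "," + ",".join(str(D2[i, j]) for j in range(len(ids))) + "\n"
        pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
            src=__import__("io").StringIO(csv), delimiter=","
        )
        dtree = pdm.nj_tree()
        all_leaves = frozenset(ids)
        anchor = min(all_leaves)
        want = set()
        for node in dtree.preorder_node_iter():
            if node.parent_node is None or node.is_leaf():
                continue
            clade = frozenset(l.taxon.label for l in node.leaf_iter())
            side = clade if anchor not in clade else all_leaves - clade
            if 1 < len(side) < len(ids) - 1:
                want.add(side)
        assert mine.bipartitions() == want


def _tree_distances(tree: Tree, ids):
    n = len(ids)
    idx = {name: i for i, name in enumerate(ids)}
    D = np.zeros((n, n))

    def walk(node, acc):
        if node.is_leaf:
            return {node.name: acc}
        out = {}
        for c in node.children:
            out.update(walk(c, acc + c.length))
        return out

    # distances via root paths + subtraction of shared path
    paths = {}

    def collect(node, path):
        if node.is_leaf:
            paths[node.name] = path
            return
        for c in node.children:
            collect(c, path + [(id(c), c.length)])

    collect(tree.root, [])
    for a in ids:
        for b in ids:
            if a == b:
                continue
            ea = {e for e, _ in paths[a]}
            eb = {e for e, _ in paths[b]}
            D[idx[a], idx[b]] = sum(l for e, l in paths[a] if e not in eb) + sum(
                l for e, l in paths[b] if e not in ea
            )
    return D


class TestBootstrap:
    def test_two_clear_clades_high_support(self):
        rng = np.random.default_rng(1)
        base1 = "".join(rng.choice(list("ACGT"), size=200))
        base2 = "".join(rng.choice(list("ACGT"), size=200))

        def mutate(s, k):
            s = list(s)
            for p in rng.choice(len(s), size=k, replace=False):
                s[p] = str(rng.choice([b for b in "ACGT" if b != s[p]]))
            return "".join(s)

        aln = {
            "a1": base1, "a2": mutate(base1, 2), "a3": mutate(base1, 2),
            "b1": base2, "b2": mutate(base2, 2), "b3": mutate(base2, 2),
        }
        tree = bootstrap_supports(aln, n_replicates=100, seed=5)
        split = frozenset({"b1", "b2", "b3"})
        assert tree.supports[split] >= 95

    def test_same_seed_identical_supports(self):
        rng = np.random.default_rng(2)
        aln = {
            f"s{i}": "".join(rng.choice(list("ACGT"), size=80)) for i in range(5)
        }
        t1 = bootstrap_supports(aln, n_replicates=50, seed=9)
        t2 = bootstrap_supports(aln, n_replicates=50, seed=9)
        assert t1.supports == t2.supports
        assert t1.newick() == t2.newick()

    def test_invariant_alignment_full_support(self):
        aln = {"a": "AAAA", "b": "AAAA", "c": "AAAA", "d": "AAAA"}
        tree = bootstrap_supports(aln, n_replicates=20, seed=0)
        assert all(v == 100.0 for v in tree.supports.values()) or tree.supports == {}

    def test_bad_replicate_count(self):
        with pytest.raises(ValueError):
            bootstrap_supports({"a": "AC", "b": "AC", "c": "AC"}, n_replicates=0)

    def test_newick_contains_supports_and_leaves(self):
        rng = np.random.default_rng(3)
        aln = {f"s{i}": "".join(rng.choice(list("ACGT"), size=60)) for i in range(5)}
        t = bootstrap_supports(aln, n_replicates=10, seed=1)
        nwk = t.newick()
        for name in aln:
            assert name in nwk
        assert nwk.endswith(";")
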