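"""p-distance, neighbor joining, bootstrap, Newick serialization.

The NJ implementation is checked against independent oracles: closed-form
3-taxon lengths, path-length reconstruction on additive matrices, and an
exhaustive least-squares search over all unrooted topologies (3 for four
taxa, 15 for five).  dendropy serves as the Newick round-trip oracle.
"""

import itertools

import dendropy
import numpy as np
import pytest

from akhtrace.phylo import (
    DistanceMatrix,
    PhyloError,
    bootstrap,
    neighbor_joining,
    nj_tree,
    p_distance,
)
from akhtrace.simulate import GeneratorConfig, generate_alignment


def dm(taxa, rows):
    return DistanceMatrix(tuple(taxa), np.array(rows, dtype=float))


# ---------------------------------------------------------------------------
# oracle helpers (independent of the package's tree code)


def tree_path_distances(edges, taxa):
    """All-pairs leaf path lengths of a tree given as (u, v, length) edges."""
    import collections

    adj = collections.defaultdict(list)
    for u, v, w in edges:
        adj[u].append((v, w))
        adj[v].append((u, w))
    out = {}
    for a in taxa:
        dist = {a: 0.0}
        stack = [a]
        while stack:
            x = stack.pop()
            for y, w in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + w
                    stack.append(y)
        for b in taxa:
            out[(a, b)] = dist[b]
    return out


def enumerate_unrooted_topologies(taxa):
    """All unrooted binary topologies as edge lists with symbolic internals.

    Built by inserting each taxon into every edge of every smaller tree:
    yields 3 topologies for 4 taxa, 15 for 5.
    """
    first = [(taxa[0], "i0", None), (taxa[1], "i0", None), (taxa[2], "i0", None)]
    trees = [first]
    counter = [0]
    for leaf in taxa[3:]:
        nxt = []
        for tree in trees:
            for k in range(len(tree)):
                counter[0] += 1
                new_int = f"i{counter[0]}"
                u, v, _ = tree[k]
                rest = tree[:k] + tree[k + 1 :]
                nxt.append(
                    rest
                    + [(u, new_int, None), (v, new_int, None), (leaf, new_int, None)]
                )
        trees = nxt
    return trees


def best_fit_topology(taxa, d):
    """Least-squares branch-length fit over every topology; return splits of
    the best-fitting one (zero residual on additive input)."""
    pairs = list(itertools.combinations(range(len(taxa)), 2))
    best = None
    for tree in enumerate_unrooted_topologies(taxa):
        edges = [(u, v) for u, v, _ in tree]
        # path incidence matrix
        import collections

        adj = collections.defaultdict(list)
        for idx, (u, v) in enumerate(edges):
            adj[u].append((v, idx))
            adj[v].append((u, idx))

        def path_edges(a, b):
            stack = [(a, None, [])]
            seen = {a}
            while stack:
                x, _, used = stack.pop()
                if x == b:
                    return used
                for y, idx in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append((y, None, used + [idx]))
            raise AssertionError

        A = np.zeros((len(pairs), len(edges)))
        y = np.zeros(len(pairs))
        for r, (i, j) in enumerate(pairs):
            for idx in path_edges(taxa[i], taxa[j]):
                A[r, idx] = 1.0
            y[r] = d[i][j]
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = float(np.sum((A @ coef - y) ** 2))
        if best is None or resid < best[0]:
            best = (resid, tree)
    _, tree = best
    return topology_splits(tree, taxa)


def topology_splits(edge_list, taxa):
    """Nontrivial bipartitions of a topology, anchored away from taxa[0]."""
    import collections

    adj = collections.defaultdict(list)
    for u, v, _ in edge_list:
        adj[u].append(v)
        adj[v].append(u)
    leaves = set(taxa)
    splits = set()
    internals = [n for n in adj if n not in leaves]
    for u in internals:
        for v in adj[u]:
            if v in leaves:
                continue
            # leaves on v's side of edge (u, v)
            side = set()
            stack, seen = [v], {u, v}
            while stack:
                x = stack.pop()
                if x in leaves:
                    side.add(x)
                for y in adj[x]:
                    if y not in seen:
                        seen.add(y)
                        stack.append(y)
            if 1 < len(side) < len(leaves) - 1:
                key = frozenset(side) if taxa[0] not in side else frozenset(leaves - side)
                splits.add(key)
    return splits


# ---------------------------------------------------------------------------
# p-distance


def test_p_distance_identical_and_simple():
    d = p_distance({"a": "AAAA", "b": "AAAA"})
    assert d.d[0, 1] == 0.0
    d = p_distance({"a": "AAAA", "b": "AAAT"})
    assert d.d[0, 1] == pytest.approx(0.25)


def test_p_distance_pairwise_deletion_hand_computed():
    # 5 columns; pair (a,b) compares cols 1,2,5 -> 1 mismatch / 3
    rows = {"a": "AC-GT", "b": "AG-XT", "c": "AAAAA"}
    d = p_distance(rows)
    i, j = 0, 1
    assert d.d[i, j] == pytest.approx(1 / 3)
    # (a,c): cols 1,2,4,5 comparable -> mismatches at 2,4,5? A=A,C!=A,G!=A,T!=A
    assert d.d[0, 2] == pytest.approx(3 / 4)


def test_p_distance_zero_comparable_sites_errors():
    with pytest.raises(PhyloError):
        p_distance({"a": "--AA", "b": "AA--"})


def test_p_distance_rejects_unequal_rows():
    with pytest.raises(PhyloError):
        p_distance({"a": "AAA", "b": "AAAA"})


# ---------------------------------------------------------------------------
# neighbor joining


def test_three_taxon_closed_form():
    d12, d13, d23 = 0.3, 0.5, 0.6
    tree = neighbor_joining(dm("ABC", [[0, d12, d13], [d12, 0, d23], [d13, 0.6, 0]]))
    lengths = {c.name: l for c, l in tree.root.children}
    assert lengths["A"] == pytest.approx((d12 + d13 - d23) / 2)
    assert lengths["B"] == pytest.approx((d12 + d23 - d13) / 2)
    assert lengths["C"] == pytest.approx((d13 + d23 - d12) / 2)
    assert tree.n_edges() == 3
    assert tree.splits() == set()


def test_nj_requires_three_taxa():
    with pytest.raises(PhyloError):
        neighbor_joining(dm("AB", [[0, 1], [1, 0]]))


def additive_matrix_4():
    # tree: (A:2,B:3)-x-(C:4,D:5), internal edge x-y length 1
    edges = [("A", "x", 2), ("B", "x", 3), ("x", "y", 1), ("C", "y", 4), ("D", "y", 5)]
    taxa = ["A", "B", "C", "D"]
    paths = tree_path_distances(edges, taxa)
    d = [[paths[(a, b)] for b in taxa] for a in taxa]
    return taxa, d


def additive_matrix_5():
    edges = [
        ("A", "x", 2), ("B", "x", 3), ("x", "y", 1),
        ("C", "y", 4), ("y", "z", 2), ("D", "z", 5), ("E", "z", 6),
    ]
    taxa = ["A", "B", "C", "D", "E"]
    paths = tree_path_distances(edges, taxa)
    d = [[paths[(a, b)] for b in taxa] for a in taxa]
    return taxa, d


def test_additive_four_taxa_exact_topology_and_path_lengths():
    taxa, d = additive_matrix_4()
    tree = neighbor_joining(dm(taxa, d))
    assert tree.splits() == {frozenset({"C", "D"})}
    # leaf-to-leaf path lengths in the NJ tree reproduce the input distances
    nwk = tree.newick()
    dt = dendropy.Tree.get(data=nwk, schema="newick")
    pdm = dt.phylogenetic_distance_matrix()
    taxon = {t.label: t for t in dt.taxon_namespace}
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i < j:
                assert pdm.distance(taxon[a], taxon[b]) == pytest.approx(d[i][j])


def test_additive_four_and_five_taxa_match_exhaustive_oracle():
    for taxa, d in (additive_matrix_4(), additive_matrix_5()):
        tree = neighbor_joining(dm(taxa, d))
        assert tree.splits() == best_fit_topology(taxa, d)
        assert tree.n_edges() == 2 * len(taxa) - 3


def test_branch_lengths_nonnegative_after_clamping():
    taxa, d = additive_matrix_5()
    tree = neighbor_joining(dm(taxa, d))

    def walk(node):
        for c, l in node.children:
            assert l >= 0
            walk(c)

    walk(tree.root)


def test_distance_matrix_validation():
    with pytest.raises(PhyloError):
        dm("AB", [[0, 1], [2, 0]])  # asymmetric
    with pytest.raises(PhyloError):
        dm("AA", [[0, 1], [1, 0]])  # duplicate taxa
    with pytest.raises(PhyloError):
        dm("AB", [[0, -1], [-1, 0]])  # negative


# ---------------------------------------------------------------------------
# Newick round-trip (dendropy oracle)


def test_newick_round_trips_topology_lengths_supports():
    aset = generate_alignment(GeneratorConfig(n_taxa=7, aln_len=250, seed=21))
    tree = bootstrap(aset.rows, n_reps=30, seed=5)
    nwk = tree.newick()
    dt = dendropy.Tree.get(data=nwk, schema="newick")
    assert {l.taxon.label for l in dt.leaf_node_iter()} == set(aset.rows)
    dt.encode_bipartitions()
    ours = tree.splits()
    taxa = sorted(aset.rows)
    theirs = set()
    for edge in dt.preorder_edge_iter():
        if edge.bipartition.is_trivial() or edge.head_node is dt.seed_node:
            continue
        side = frozenset(
            t.label for t in edge.bipartition.leafset_taxa(dt.taxon_namespace)
        )
        if len(side) in (0, 1, len(taxa), len(taxa) - 1):
            continue
        key = side if tree.taxa[0] not in side else frozenset(set(aset.rows) - side)
        theirs.add(key)
    assert ours == theirs
    # supports survive serialization as internal-node labels
    supports = {
        float(n.label)
        for n in dt.preorder_node_iter()
        if n.label not in (None, "") and not n.is_leaf()
    }
    assert supports and all(0 <= s <= 100 for s in supports)


# ---------------------------------------------------------------------------
# bootstrap


def test_bootstrap_separating_split_strongly_supported():
    # two well-separated clades simulated from the generator
    rng = np.random.default_rng(17)
    base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))
    other = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=120))

    def mutate(s, k, rng):
        s = list(s)
        for i in rng.choice(len(s), size=k, replace=False):
            s[i] = "W" if s[i] != "W" else "Y"
        return "".join(s)

    rows = {
        "a1": base, "a2": mutate(base, 3, rng), "a3": mutate(base, 5, rng),
        "b1": other, "b2": mutate(other, 3, rng), "b3": mutate(other, 5, rng),
    }
    tree = bootstrap(rows, n_reps=100, seed=23)
    supports = tree.edge_supports()
    sep = frozenset({"b1", "b2", "b3"})
    assert sep in supports
    assert supports[sep] >= 95


def test_bootstrap_deterministic_under_seed():
    aset = generate_alignment(GeneratorConfig(n_taxa=6, aln_len=150, seed=8))
    t1 = bootstrap(aset.rows, n_reps=40, seed=99)
    t2 = bootstrap(aset.rows, n_reps=40, seed=99)
    assert t1.newick() == t2.newick()


def test_bootstrap_identical_sequences_warns_star_like():
    rows = {t: "ACDEFGHIKL" * 5 for t in ("a", "b", "c", "d")}
    with pytest.warns(UserWarning, match="star-like"):
        bootstrap(rows, n_reps=5, seed=1)


def test_nj_invariant_to_taxon_reordering_up_to_relabeling():
    taxa, d = additive_matrix_5()
    tree1 = neighbor_joining(dm(taxa, d))
    order = [3, 1, 4, 0, 2]
    taxa2 = [taxa[i] for i in order]
    d2 = [[d[i][j] for j in order] for i in order]
    tree2 = neighbor_joining(dm(taxa2, d2))

    def norm(tree):
        # anchor-free normalization: store each split as the min-sorted pair
        out = set()
        leaves = frozenset(tree.taxa)
        for s in tree.splits():
            out.add(frozenset({s, leaves - s}))
        return out

    assert norm(tree1) == norm(tree2)
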