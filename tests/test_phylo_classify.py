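"""Neighbor joining, bootstrap semantics, collapsing, and clade assignment."""

import itertools

import numpy as np
import pytest

from madswalk.align import MultipleAlignment, pairwise_distance_matrix
from madswalk.phylo_classify import (
    CladeTree,
    DistanceMatrix,
    TreeNode,
    assign_clade,
    bootstrap_support,
    collapse_low_support,
    nj_tree,
)
from madswalk.records import SequenceRecord


def random_additive_tree(rng, n_taxa):
    """A random unrooted binary tree + its additive distance matrix."""
    labels = [f"t{i}" for i in range(n_taxa)]
    nodes = [TreeNode(label=l) for l in labels]
    lengths = {}
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        a.length = float(rng.uniform(0.1, 2.0))
        b.length = float(rng.uniform(0.1, 2.0))
        parent = TreeNode(children=[b, a])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    for n in nodes:
        n.length = float(rng.uniform(0.1, 2.0))
    tree = CladeTree(root=TreeNode(children=nodes))

    # path-length distances: sum branch lengths below the last shared node
    def depths(node, acc, out):
        if node.is_leaf:
            out[node.label] = acc + [node]
        for c in node.children:
            depths(c, acc + [node], out)

    chains = {}
    depths(tree.root, [], chains)

    def dist(u, v):
        cu, cv = chains[u], chains[v]
        shared = 0
        for a, b in zip(cu, cv):
            if a is b:
                shared += 1
            else:
                break
        total = 0.0
        for node in cu[shared:]:
            total += node.length
        for node in cv[shared:]:
            total += node.length
        return total

    D = np.zeros((n_taxa, n_taxa))
    for i, j in itertools.combinations(range(n_taxa), 2):
        D[i, j] = D[j, i] = dist(labels[i], labels[j])
    return tree, DistanceMatrix(labels, D)


def splits(tree):
    return set(tree.bipartitions())


def test_three_taxon_closed_form():
    d = DistanceMatrix(["A", "B", "C"], np.array([[0, 2, 3], [2, 0, 4], [3, 4, 0]], float))
    tree = nj_tree(d)
    lengths = {c.label: c.length for c in tree.root.children}
    assert lengths == {"A": 0.5, "B": 1.5, "C": 2.5}


def test_four_taxon_additive_split_and_lengths():
    # tree ((A:1,B:1):1,(C:1,D:1)) -> additive distances
    D = np.array([[0, 2, 3, 3], [2, 0, 3, 3], [3, 3, 0, 2], [3, 3, 2, 0]], float)
    tree = nj_tree(DistanceMatrix(list("ABCD"), D))
    assert splits(tree) == {frozenset({"C", "D"})}
    lengths = {l.label: l.length for l in tree.root.leaves()}
    assert all(v == pytest.approx(1.0) for v in lengths.values())


def test_nj_recovers_additive_topologies(rng):
    for _ in range(20):
        true_tree, d = random_additive_tree(rng, 5)
        assert splits(nj_tree(d)) == splits(true_tree)


def brute_force_minimum_evolution(d):
    """OLS branch fit over the 3 unrooted 4-taxon topologies; shortest wins."""
    a, b, c, e = range(4)
    topologies = [((a, b), (c, e)), ((a, c), (b, e)), ((a, e), (b, c))]
    best = None
    for (i, j), (k, l) in topologies:
        # 5 branches: i, j, k, l leaves + internal; 6 path equations
        A, y = [], []
        pairs = list(itertools.combinations(range(4), 2))
        for (u, v) in pairs:
            row = [0.0] * 5
            row[u] = 1.0
            row[v] = 1.0
            same_side = {u, v} in ({i, j}, {k, l})
            if not same_side:
                row[4] = 1.0
            A.append(row)
            y.append(d.matrix[u, v])
        x, *_ = np.linalg.lstsq(np.array(A), np.array(y), rcond=None)
        total = x.sum()
        split = frozenset({d.ids[k], d.ids[l]})
        if best is None or total < best[0]:
            best = (total, split)
    return best[1]


def test_nj_four_taxa_agrees_with_minimum_evolution(rng):
    for _ in range(20):
        _, d = random_additive_tree(rng, 4)
        nj_splits = splits(nj_tree(d))
        me_split = brute_force_minimum_evolution(d)
        ref = min(d.ids)
        canonical = me_split if ref not in me_split else frozenset(d.ids) - me_split
        assert nj_splits == {canonical}


def test_nj_agrees_with_skbio_on_additive_matrices(rng):
    """Independent cross-check: same splits as scikit-bio's NJ."""
    import skbio
    from skbio.tree import nj as skbio_nj

    for _ in range(10):
        _, d = random_additive_tree(rng, 6)
        ours = splits(nj_tree(d))
        sk_tree = skbio_nj(skbio.DistanceMatrix(d.matrix, ids=d.ids))
        taxa = frozenset(d.ids)
        ref = min(taxa)
        theirs = set()
        for node in sk_tree.non_tips(include_self=False):
            below = frozenset(t.name for t in node.tips())
            side = below if ref not in below else taxa - below
            if 1 < len(side) < len(taxa) - 1:
                theirs.add(side)
        assert ours == theirs


def test_nj_all_equal_distances_is_deterministic():
    D = np.ones((4, 4)) - np.eye(4)
    t1 = nj_tree(DistanceMatrix(list("ABCD"), D))
    t2 = nj_tree(DistanceMatrix(list("ABCD"), D))
    assert t1.newick() == t2.newick()


def test_nj_rejects_fewer_than_three_taxa():
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], float)))


def _planted_msa():
    rows = {
        "A": "AAAAAAAAAACCCCCCCCCC",
        "B": "AAAAAAAAAACCCCCCCCCG",
        "C": "TTTTTTTTTTGGGGGGGGGG",
        "D": "TTTTTTTTTTGGGGGGGGGC",
    }
    return MultipleAlignment(
        [SequenceRecord(k, v, "protein") for k, v in rows.items()]
    )


def test_bootstrap_planted_signal_high_support():
    tree = bootstrap_support(_planted_msa(), n_reps=100, seed=1)
    (support,) = [n.support for n in tree.bipartitions().values()]
    assert support >= 95


def test_bootstrap_single_replicate_supports_binary():
    tree = bootstrap_support(_planted_msa(), n_reps=1, seed=2)
    for node in tree.bipartitions().values():
        assert node.support in (0.0, 100.0)


def test_bootstrap_seed_reproducible():
    t1 = bootstrap_support(_planted_msa(), n_reps=50, seed=9)
    t2 = bootstrap_support(_planted_msa(), n_reps=50, seed=9)
    assert t1.newick() == t2.newick()


def test_bootstrap_invariant_to_row_order():
    msa = _planted_msa()
    shuffled = MultipleAlignment(list(reversed(msa.records)))
    s1 = {s: n.support for s, n in bootstrap_support(msa, 50, seed=4).bipartitions().items()}
    s2 = {s: n.support for s, n in bootstrap_support(shuffled, 50, seed=4).bipartitions().items()}
    assert set(s1) == set(s2)


def _supported_tree(support):
    a, b = TreeNode("A", 1.0), TreeNode("B", 1.0)
    c, d = TreeNode("C", 1.0), TreeNode("D", 1.0)
    inner = TreeNode(children=[c, d])
    inner.length, inner.support = 1.0, support
    return CladeTree(root=TreeNode(children=[a, b, inner]))


def test_collapse_below_threshold():
    out = collapse_low_support(_supported_tree(49.0), threshold=50.0)
    assert len(out.root.children) == 4  # polytomy: edge contracted
    assert out.bipartitions() == {}


def test_collapse_keeps_edge_at_threshold():
    out = collapse_low_support(_supported_tree(50.0), threshold=50.0)
    assert splits(out) == {frozenset({"C", "D"})}


def test_collapse_full_support_unchanged():
    tree = _supported_tree(100.0)
    out = collapse_low_support(tree, threshold=50.0)
    assert out.newick() == tree.newick()


def test_assign_clade_sister_reference():
    tree = _supported_tree(80.0)
    out = assign_clade(tree, {"C": "SVP-like", "A": "TM3-like"})
    by_query = {a.query_id: a for a in out}
    assert by_query["D"].clade == "SVP-like"
    assert by_query["D"].supporting_references == ["C"]
    assert by_query["B"].clade == "TM3-like"


def test_assign_clade_conflicting_references_unresolved():
    a, b, q = TreeNode("A", 1.0), TreeNode("B", 1.0), TreeNode("Q", 1.0)
    tree = CladeTree(root=TreeNode(children=[a, b, q]))  # single polytomy
    out = assign_clade(tree, {"A": "X", "B": "Y"})
    assert out[0].query_id == "Q" and out[0].clade == "unresolved"


def test_assign_clade_requires_reference_vocabulary():
    with pytest.raises(ValueError):
        assign_clade(_supported_tree(80.0), {})


def test_assignment_recovers_planted_clades(small_family):
    """Family + labeled references: every gene gets its planted clade."""
    from madswalk.align import crop_to_conserved, progressive_align

    msa = progressive_align(small_family.proteins + small_family.reference_proteins)
    cropped = crop_to_conserved(msa, 0.5)
    tree = nj_tree(pairwise_distance_matrix(cropped))
    out = assign_clade(tree, small_family.reference_labels)
    assigned = {a.query_id: a.clade for a in out}
    for gid, clade in small_family.clade_labels.items():
        assert assigned[gid] == clade, gid


def test_negative_branch_lengths_retained_and_flagged(rng):
    """Additive inputs yield no negatives; any computed negative is flagged."""
    for _ in range(5):
        _, d = random_additive_tree(rng, 5)
        tree = nj_tree(d)
        assert not tree.has_negative_branch
    # a strongly non-additive matrix (violates the triangle inequality)
    D = np.array([[0, 10, 1, 1], [10, 0, 1, 1], [1, 1, 0, 10], [1, 1, 10, 0]], float)
    tree = nj_tree(DistanceMatrix(list("ABCD"), D))

    def all_lengths(node):
        out = [] if node.label is None and node.length == 0 else [node.length]
        for c in node.children:
            out.extend(all_lengths(c))
        return out

    lengths = []
    for c in tree.root.children:
        lengths.extend(all_lengths(c))
    assert tree.has_negative_branch == any(x < 0 for x in lengths)
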