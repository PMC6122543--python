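"""Neighbor-joining trees, bootstrap support, branch collapsing, and
reference-guided clade assignment.

NJ is the classical Saitou-Nei algorithm (Q criterion, standard branch-length
formulas). It recovers the generating topology exactly on additive distance
matrices, which is what the correctness tests exploit. Negative branch
lengths are retained (classical behaviour) and flagged on the tree.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .align import MultipleAlignment, pairwise_distance_matrix
from .records import SequenceRecord


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with a zero diagonal."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match taxon count")
        if not np.allclose(self.matrix, self.matrix.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if not np.isfinite(self.matrix).all():
            raise ValueError("distances must be finite")

    def to_phylip(self) -> str:
        lines = [f" {len(self.ids)}"]
        for name, row in zip(self.ids, self.matrix):
            lines.append(name + "  " + "  ".join(f"{x:.6f}" for x in row))
        return "\n".join(lines) + "\n"


@dataclass
class TreeNode:
    label: str | None = None
    length: float = 0.0  # branch above this node
    support: float | None = None  # bootstrap percentage on the branch above
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_labels(self) -> frozenset[str]:
        return frozenset(l.label for l in self.leaves())


@dataclass
class CladeTree:
    """Unrooted tree stored with an arbitrary basal multifurcation."""

    root: TreeNode
    has_negative_branch: bool = False

    @property
    def taxa(self) -> frozenset[str]:
        return self.root.leaf_labels()

    def internal_nodes(self) -> list[TreeNode]:
        """Non-root internal nodes; each corresponds to one internal edge."""
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            for c in node.children:
                if not c.is_leaf:
                    out.append(c)
                    walk(c)

        walk(self.root)
        return out

    def bipartitions(self) -> dict[frozenset[str], TreeNode]:
        """Canonical internal splits: the side NOT containing the reference
        taxon (lexicographically smallest leaf), keyed per internal edge."""
        ref = min(self.taxa)
        out: dict[frozenset[str], TreeNode] = {}
        for node in self.internal_nodes():
            below = node.leaf_labels()
            side = below if ref not in below else self.taxa - below
            if 1 < len(side) < len(self.taxa) - 1:
                out[side] = node
        return out

    def groups(self) -> list[frozenset[str]]:
        """Candidate monophyletic groups: every edge's below-side, the far
        side of internal edges (clades under re-rooting), and the full set."""
        taxa = self.taxa
        sets = {taxa}

        def walk(node: TreeNode) -> None:
            for c in node.children:
                below = c.leaf_labels()
                sets.add(below)
                if not c.is_leaf:
                    sets.add(taxa - below)
                walk(c)

        walk(self.root)
        return [s for s in sets if s]

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.label}:{node.length:.6g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:g}"
            return f"({inner}){label}:{node.length:.6g}"

        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"


def nj_tree(d: DistanceMatrix) -> CladeTree:
    """Classical neighbor joining; deterministic tie-break by smallest (i, j)."""
    n = len(d.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = d.matrix.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(label=t) for t in d.ids]
    negative = False
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        # first minimum in row-major upper-triangle order = smallest (i, j)
        k = int(np.argmin(Q[iu]))
        i, j = int(iu[0][k]), int(iu[1][k])
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        negative |= li < 0 or lj < 0
        ci, cj = nodes[i], nodes[j]
        ci.length, cj.length = float(li), float(lj)
        parent = TreeNode(children=[ci, cj])
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [x for x in range(m) if x not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep][None, :]])
        last = np.append(dnew[keep], 0.0)
        D = np.hstack([D, last[:, None]])
        nodes = [nodes[x] for x in keep] + [parent]
    # final star join of the remaining three nodes (closed form)
    a, b, c = nodes
    dab, dac, dbc = D[0, 1], D[0, 2], D[1, 2]
    a.length = float((dab + dac - dbc) / 2)
    b.length = float((dab + dbc - dac) / 2)
    c.length = float((dac + dbc - dab) / 2)
    negative |= min(a.length, b.length, c.length) < 0
    return CladeTree(root=TreeNode(children=[a, b, c]), has_negative_branch=negative)


def bootstrap_support(
    msa: MultipleAlignment, n_reps: int = 1000, seed: int = 0
) -> CladeTree:
    """Felsenstein column bootstrap: p-distance + NJ per replicate, support =
    percentage of replicates containing each original internal split."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    tree = nj_tree(pairwise_distance_matrix(msa))
    splits = tree.bipartitions()
    counts = {s: 0 for s in splits}
    rng = np.random.default_rng(seed)
    n_cols = msa.n_columns
    for _ in range(n_reps):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep = MultipleAlignment(
            [
                SequenceRecord(r.id, "".join(r.seq[j] for j in cols), r.alphabet)
                for r in msa.records
            ]
        )
        rep_tree = nj_tree(pairwise_distance_matrix(rep))
        rep_splits = set(rep_tree.bipartitions())
        for s in splits:
            if s in rep_splits:
                counts[s] += 1
    for s, node in splits.items():
        node.support = 100.0 * counts[s] / n_reps
    return tree


def collapse_low_support(tree: CladeTree, threshold: float = 50.0) -> CladeTree:
    """Contract internal edges with support strictly below ``threshold``."""
    out = copy.deepcopy(tree)

    def walk(node: TreeNode) -> None:
        new_children: list[TreeNode] = []
        for c in node.children:
            walk(c)
            if (
                not c.is_leaf
                and c.support is not None
                and c.support < threshold
            ):
                new_children.extend(c.children)  # polytomy: splice grandchildren
            else:
                new_children.append(c)
        node.children = new_children

    walk(out.root)
    return out


@dataclass
class CladeAssignment:
    query_id: str
    clade: str
    supporting_references: list[str]


def assign_clade(
    tree: CladeTree, reference_labels: dict[str, str]
) -> list[CladeAssignment]:
    """Label each unlabeled leaf by the smallest edge-delimited group that
    contains it and at least one reference; conflicting reference labels
    within that group yield "unresolved"."""
    if not reference_labels:
        raise ValueError("reference label vocabulary is empty")
    taxa = tree.taxa
    refs = {t for t in taxa if t in reference_labels}
    groups = sorted(tree.groups(), key=lambda s: (len(s), tuple(sorted(s))))
    out: list[CladeAssignment] = []
    for query in sorted(taxa - refs):
        chosen = next(
            (g for g in groups if query in g and g & refs), None
        )
        if chosen is None:
            out.append(CladeAssignment(query, "unresolved", []))
            continue
        members = sorted(chosen & refs)
        labels = {reference_labels[r] for r in members}
        clade = labels.pop() if len(labels) == 1 else "unresolved"
        out.append(CladeAssignment(query, clade, members))
    return out
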