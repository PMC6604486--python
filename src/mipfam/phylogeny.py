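"""Distance-based phylogenetics: p/Poisson distances from an alignment,
Saitou-Nei neighbor joining, nonparametric bootstrap supports, midpoint
rooting and monophyly checks.

NJ is exact on additive distance matrices: the returned topology and branch
lengths then reproduce the input distances via tree path lengths. Negative
branch-length estimates are clamped to zero and flagged, matching common
presentation conventions. Supports are percentages of bootstrap replicate
trees containing each internal bipartition of the point-estimate tree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .seqio import SequenceRecord

_GAPLIKE = {"-", ".", "X", "N", "?"}


@dataclass
class TreeNode:
    """A node in a phylogenetic tree (leaves carry names)."""

    name: str = ""
    children: list = field(default_factory=list)
    branch_length: float = 0.0
    support: int | None = None
    clamped: bool = False  # negative NJ length estimate clamped to zero

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self):
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self):
        return [l.name for l in self.leaves()]

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def to_newick(self, include_support: bool = True) -> str:
        def fmt(node, is_root=False):
            if node.is_leaf:
                body = node.name
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = ""
                if include_support and node.support is not None:
                    label = str(int(node.support))
                body = f"({inner}){label}"
            if is_root:
                return body
            return f"{body}:{node.branch_length:.10g}"

        return fmt(self, is_root=True) + ";"


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if d.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.all(np.isfinite(d)):
            raise ValueError("non-finite distances")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("nonzero diagonal")
        if (d < -1e-12).any():
            raise ValueError("negative distances")
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "d", d)

    def reorder(self, labels):
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.d[np.ix_(idx, idx)])


# ---------------------------------------------------------------------------
# Distances from an alignment


def _char_matrix(msa):
    length = len(msa[0].sequence)
    for rec in msa:
        if len(rec.sequence) != length:
            raise ValueError("aligned sequences must have equal length")
    return np.array([list(r.sequence) for r in msa])


def distance_from_alignment(msa, model: str = "p-distance") -> DistanceMatrix:
    """Pairwise distances with per-pair deletion of gap/ambiguous columns.

    ``p-distance`` is mismatches over valid columns; ``poisson`` applies
    d = -ln(1 - p). A pair with zero valid columns is an error naming the
    pair.
    """
    if model not in ("p-distance", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    chars = _char_matrix(msa)
    valid = ~np.isin(chars, list(_GAPLIKE))
    n = len(msa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            nvalid = int(both.sum())
            if nvalid == 0:
                raise ValueError(
                    f"no valid columns between {msa[i].id} and {msa[j].id}"
                )
            p = float((chars[i][both] != chars[j][both]).sum()) / nvalid
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"Poisson distance undefined at p=1 for "
                        f"{msa[i].id}/{msa[j].id}"
                    )
                dist = -math.log(1.0 - p)
            else:
                dist = p
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(tuple(r.id for r in msa), d)


# ---------------------------------------------------------------------------
# Neighbor joining


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing
    Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k), with ties broken by
    the smallest (i, j) index pair in the current matrix. Returns an unrooted
    tree (trifurcating root for n > 2); negative branch-length estimates are
    clamped to 0 and flagged on the node.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.d.copy()
    nodes = [TreeNode(name=l) for l in dm.labels]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))          # row-major: smallest (i, j) on ties
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        child_i, child_j = nodes[i], nodes[j]
        child_i.branch_length, child_i.clamped = max(li, 0.0), li < 0
        child_j.branch_length, child_j.clamped = max(lj, 0.0), lj < 0
        parent = TreeNode(children=[child_i, child_j])

        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)], new_row[keep]])
        D = np.hstack([D, np.append(new_row[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # resolve the final three nodes as a star (standard unrooted NJ root)
    a, b, c = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    for node, l in zip((a, b, c), (la, lb, lc)):
        node.branch_length, node.clamped = max(l, 0.0), l < 0
    return TreeNode(children=[a, b, c])


# ---------------------------------------------------------------------------
# Bipartitions, rooting, monophyly


def bipartitions(tree: TreeNode) -> set:
    """Nontrivial bipartitions as canonical frozensets (the side not
    containing the lexicographically smallest leaf)."""
    all_leaves = frozenset(tree.leaf_names())
    anchor = min(all_leaves)
    parts = set()
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        clade = frozenset(node.leaf_names())
        side = all_leaves - clade if anchor in clade else clade
        if 2 <= len(side) <= len(all_leaves) - 2:
            parts.add(side)
    return parts


def _adjacency(tree: TreeNode):
    adj = {}
    for node in tree.walk():
        for child in node.children:
            adj.setdefault(id(node), []).append((id(child), child.branch_length))
            adj.setdefault(id(child), []).append((id(node), child.branch_length))
    index = {id(n): n for n in tree.walk()}
    return adj, index


def _leaf_distances(adj, start):
    dist = {start: 0.0}
    stack = [start]
    while stack:
        u = stack.pop()
        for v, w in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + w
                stack.append(v)
    return dist


def midpoint_root(tree: TreeNode) -> TreeNode:
    """Root the tree at the midpoint of its longest leaf-to-leaf path."""
    adj, index = _adjacency(tree)
    leaves = [id(l) for l in tree.leaves()]
    # double sweep: farthest leaf from an arbitrary leaf, then farthest from it
    d0 = _leaf_distances(adj, leaves[0])
    far_a = max(leaves, key=lambda l: (d0[l], index[l].name))
    da = _leaf_distances(adj, far_a)
    far_b = max(leaves, key=lambda l: (da[l], index[l].name))
    total = da[far_b]

    # walk the a->b path to find the midpoint edge
    parent_on_path = {far_a: None}
    stack = [far_a]
    while stack:
        u = stack.pop()
        for v, _ in adj[u]:
            if v not in parent_on_path:
                parent_on_path[v] = u
                stack.append(v)
    path = [far_b]
    while path[-1] != far_a:
        path.append(parent_on_path[path[-1]])
    path.reverse()

    half = total / 2.0
    acc = 0.0
    for u, v in zip(path, path[1:]):
        w = next(w for t, w in adj[u] if t == v)
        if acc + w >= half - 1e-12:
            offset = half - acc  # distance from u into edge (u, v)
            return _reroot_on_edge(tree, index[u], index[v], offset, w)
        acc += w
    return tree


def _reroot_on_edge(tree, node_u, node_v, offset, edge_len):
    """Build a new rooted tree with the root placed on edge (u, v) at
    ``offset`` from u."""
    parent_map = {}
    for node in tree.walk():
        for c in node.children:
            parent_map[id(c)] = node

    # orient: v must be the child end of the edge
    if parent_map.get(id(node_v)) is node_u:
        child, toward_u = node_v, True
    elif parent_map.get(id(node_u)) is node_v:
        child, toward_u = node_u, False
        offset = edge_len - offset
    else:
        raise AssertionError("nodes do not share an edge")

    def rehang(node, exclude):
        """node re-rooted away from ``exclude``: children = original children
        minus exclude, plus original parent (recursively re-hung)."""
        new = TreeNode(name=node.name, support=node.support)
        for c in node.children:
            if c is exclude:
                continue
            cc = _copy_down(c)
            new.children.append(cc)
        parent = parent_map.get(id(node))
        if parent is not None:
            up = rehang(parent, node)
            up.branch_length = node.branch_length
            up.clamped = node.clamped
            new.children.append(up)
        return new

    root = TreeNode()
    below = _copy_down(child)
    below.branch_length = edge_len - offset
    above = rehang(parent_map[id(child)], child)
    above.branch_length = offset
    root.children = [above, below]
    # drop degree-2 internal nodes introduced by re-hanging the old root
    _suppress_unifurcations(root)
    return root


def _copy_down(node):
    new = TreeNode(name=node.name, branch_length=node.branch_length,
                   support=node.support, clamped=node.clamped)
    new.children = [_copy_down(c) for c in node.children]
    return new


def _suppress_unifurcations(root):
    for node in list(root.walk()):
        new_children = []
        for c in node.children:
            while len(c.children) == 1:
                only = c.children[0]
                only.branch_length += c.branch_length
                c = only
            new_children.append(c)
        node.children = new_children


def check_monophyly(tree: TreeNode, label_groups: dict, rooted: bool = False) -> dict:
    """True per group iff its labels form a clade on the (midpoint-rooted)
    tree. Labels absent from the tree raise an error."""
    work = tree if rooted else midpoint_root(tree)
    present = set(work.leaf_names())
    clades = {frozenset(n.leaf_names()) for n in work.walk()}
    out = {}
    for name, labels in label_groups.items():
        labels = frozenset(labels)
        missing = labels - present
        if missing:
            raise ValueError(f"group {name!r}: labels not in tree: {sorted(missing)}")
        out[name] = labels in clades
    return out


# ---------------------------------------------------------------------------
# Bootstrap


def tree_path_distances(tree: TreeNode) -> DistanceMatrix:
    """Leaf-to-leaf path-length distances on the tree."""
    adj, index = _adjacency(tree)
    leaves = sorted(tree.leaves(), key=lambda l: l.name)
    labels = tuple(l.name for l in leaves)
    n = len(leaves)
    d = np.zeros((n, n))
    for i, leaf in enumerate(leaves):
        dist = _leaf_distances(adj, id(leaf))
        for j in range(n):
            d[i, j] = dist[id(leaves[j])]
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return DistanceMatrix(labels, d)


def bootstrap_supports(msa, n_reps: int = 1000, seed: int = 0,
                       model: str = "p-distance") -> TreeNode:
    """NJ point-estimate tree with bootstrap supports on internal nodes.

    Alignment columns are resampled with replacement ``n_reps`` times; each
    internal bipartition's support is the percentage of replicate NJ trees
    containing it. Reproducible given the seed; the point-estimate topology
    itself does not depend on the seed. ``n_reps=0`` returns the tree without
    supports.
    """
    point = nj_tree(distance_from_alignment(msa, model=model))
    if n_reps == 0:
        return point
    rng = np.random.default_rng(seed)
    length = len(msa[0].sequence)
    counts: dict = {}
    target = {}
    all_leaves = frozenset(r.id for r in msa)
    anchor = min(all_leaves)
    for node in point.walk():
        if node is point or node.is_leaf:
            continue
        clade = frozenset(node.leaf_names())
        side = all_leaves - clade if anchor in clade else clade
        if 2 <= len(side) <= len(all_leaves) - 2:
            target[id(node)] = side
            counts[side] = 0

    chars = _char_matrix(msa)
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        rep = [SequenceRecord(r.id, "".join(chars[k][cols]), moltype=r.moltype)
               for k, r in enumerate(msa)]
        try:
            rep_tree = nj_tree(distance_from_alignment(rep, model=model))
        except ValueError:
            continue  # replicate with an undefined pair distance
        rep_parts = bipartitions(rep_tree)
        for side in counts:
            if side in rep_parts:
                counts[side] += 1
    for node in point.walk():
        side = target.get(id(node))
        if side is not None:
            node.support = int(round(100.0 * counts[side] / n_reps))
    return point
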