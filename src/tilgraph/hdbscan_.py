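"""Hierarchical density-based clustering with noise, with cluster stability.

Implements the Campello-Moulavi-Sander algorithm: mutual-reachability
distances, single-linkage hierarchy over their minimum spanning tree, a
condensed cluster tree at a minimum cluster size, and excess-of-mass cluster
selection. Exposes per-cluster *persistence* (the stability value summed over
the condensed tree), which the scikit-learn estimator does not surface.

Conventions match ``sklearn.cluster.HDBSCAN``: the core distance of a point
is the distance to its ``min_samples``-th nearest neighbor counting the point
itself, and the root of the cluster tree is never selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import cKDTree


@dataclass(frozen=True)
class HdbscanResult:
    labels: np.ndarray            # (n,) int, -1 = noise
    persistence: np.ndarray       # (k,) stability of each selected cluster
    probabilities: np.ndarray     # (n,) membership strength in [0, 1]

    @property
    def n_clusters(self) -> int:
        return len(self.persistence)


def hdbscan(points: np.ndarray, min_cluster_size: int,
            min_samples: int | None = None,
            allow_single_cluster: bool = False) -> HdbscanResult:
    """Cluster planar points; returns labels, per-cluster persistence, and
    membership probabilities. Points in no cluster get label -1.

    With ``allow_single_cluster`` the cluster-tree root is selected as one
    cluster whenever excess-of-mass selection (which normally excludes the
    root) selects nothing — a point set that is one dense aggregate then
    counts as a single cluster instead of all noise.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be at least 2")
    if min_samples is None:
        min_samples = min_cluster_size
    if n < max(min_cluster_size, min_samples, 2):
        return HdbscanResult(np.full(n, -1), np.empty(0), np.zeros(n))

    core = cKDTree(pts).query(pts, k=min_samples)[0][:, -1]
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.sqrt((diff ** 2).sum(-1))
    mreach = np.maximum(dist, np.maximum(core[:, None], core[None, :]))
    np.fill_diagonal(mreach, 0.0)

    mst = minimum_spanning_tree(csr_matrix(mreach)).tocoo()
    order = np.argsort(mst.data, kind="stable")
    edges = np.column_stack([mst.row[order], mst.col[order]]).astype(np.intp)
    weights = mst.data[order]

    linkage = _single_linkage(n, edges, weights)
    condensed = _condense(linkage, n, min_cluster_size)
    return _extract_eom(condensed, n, allow_single_cluster=allow_single_cluster)


def _single_linkage(n, edges, weights):
    """Union-find dendrogram: rows (left, right, distance, size) as in
    :func:`scipy.cluster.hierarchy.linkage`."""
    parent = np.arange(2 * n - 1, dtype=np.intp)
    size = np.ones(2 * n - 1, dtype=np.intp)
    out = np.empty((n - 1, 4))

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:   # path compression
            parent[x], x = root, parent[x]
        return root

    nxt = n
    for t, ((a, b), w) in enumerate(zip(edges, weights)):
        ra, rb = find(a), find(b)
        out[t] = (ra, rb, w, size[ra] + size[rb])
        parent[ra] = parent[rb] = nxt
        size[nxt] = size[ra] + size[rb]
        nxt += 1
    return out


def _condense(linkage, n, min_cluster_size):
    """Condensed tree rows (parent, child, lambda, size); cluster ids start
    at n (the root), leaves are original point indices < n."""
    root = 2 * n - 2
    num_points = n
    relabel = {root: n}
    next_label = n + 1
    rows = []  # (parent, child, lambda_val, child_size)
    ignore = np.zeros(2 * n - 1, dtype=bool)

    def children_of(node):
        row = linkage[node - num_points]
        return int(row[0]), int(row[1]), row[2]

    def node_size(node):
        return 1 if node < num_points else int(linkage[node - num_points][3])

    def leaves(node):
        stack, out = [node], []
        while stack:
            v = stack.pop()
            if v < num_points:
                out.append(v)
            else:
                l, r, _ = children_of(v)
                stack.extend((l, r))
        return out

    for node in _bfs(linkage, num_points, root):
        if ignore[node] or node < num_points:
            continue
        left, right, dist = children_of(node)
        lam = 1.0 / dist if dist > 0 else np.inf
        lsz, rsz = node_size(left), node_size(right)
        cluster = relabel[node]

        if lsz >= min_cluster_size and rsz >= min_cluster_size:
            for child, csz in ((left, lsz), (right, rsz)):
                relabel[child] = next_label
                rows.append((cluster, next_label, lam, csz))
                next_label += 1
        elif lsz < min_cluster_size and rsz < min_cluster_size:
            for child in (left, right):
                for p in leaves(child):
                    rows.append((cluster, p, lam, 1))
                ignore[leaves_mask_nodes(child, children_of, num_points)] = True
        else:
            keep, drop = (left, right) if lsz >= min_cluster_size else (right, left)
            relabel[keep] = cluster
            for p in leaves(drop):
                rows.append((cluster, p, lam, 1))
            ignore[leaves_mask_nodes(drop, children_of, num_points)] = True

    return np.array(rows, dtype=[("parent", np.intp), ("child", np.intp),
                                 ("lam", float), ("size", np.intp)])


def leaves_mask_nodes(node, children_of, num_points):
    """All dendrogram node ids in the subtree rooted at ``node``."""
    stack, out = [node], []
    while stack:
        v = stack.pop()
        out.append(v)
        if v >= num_points:
            l, r, _ = children_of(v)
            stack.extend((l, r))
    return np.asarray(out, dtype=np.intp)


def _bfs(linkage, num_points, root):
    order, frontier = [], [root]
    while frontier:
        order.extend(frontier)
        nxt = []
        for v in frontier:
            if v >= num_points:
                row = linkage[v - num_points]
                nxt.extend((int(row[0]), int(row[1])))
        frontier = nxt
    return order


def _extract_eom(tree, n, allow_single_cluster=False):
    if len(tree) == 0:
        return HdbscanResult(np.full(n, -1), np.empty(0), np.zeros(n))

    cluster_ids = np.unique(tree["parent"])
    birth = {int(c): np.inf for c in cluster_ids}
    birth[n] = 0.0
    for row in tree:
        child = int(row["child"])
        if child >= n:
            birth[child] = row["lam"]

    lam_cap = _max_finite(tree)
    stability = {int(c): 0.0 for c in cluster_ids}
    for row in tree:
        parent = int(row["parent"])
        lam = min(row["lam"], lam_cap)
        stability[parent] += (lam - birth[parent]) * row["size"]

    children = {int(c): [] for c in cluster_ids}
    for row in tree:
        if int(row["child"]) >= n:
            children.setdefault(int(row["parent"]), []).append(int(row["child"]))

    # excess of mass, bottom-up; the root (id n) is never selectable
    selected: set[int] = set()
    subtree_stab: dict[int, float] = {}
    for c in sorted(set(birth), reverse=True):
        child_sum = sum(subtree_stab.get(ch, 0.0) for ch in children.get(c, []))
        if c == n:
            subtree_stab[c] = child_sum
            continue
        if stability[c] < child_sum:
            subtree_stab[c] = child_sum
        else:
            subtree_stab[c] = stability[c]
            selected.add(c)
            selected -= _descendants(c, children)

    if not selected and allow_single_cluster:
        selected = {n}
    chosen = sorted(selected)
    cluster_index = {c: i for i, c in enumerate(chosen)}

    # map every condensed cluster to its selected ancestor (if any)
    parent_of = {int(row["child"]): int(row["parent"]) for row in tree if int(row["child"]) >= n}
    owner = {}
    for c in set(birth):
        cur = c
        while cur is not None and cur not in cluster_index:
            cur = parent_of.get(cur)
        owner[c] = cluster_index.get(cur, -1) if cur is not None else -1

    labels = np.full(n, -1, dtype=int)
    max_lam = np.zeros(len(chosen))
    point_lam = np.zeros(n)
    for row in tree:
        child = int(row["child"])
        if child < n:
            lab = owner[int(row["parent"])]
            labels[child] = lab
            point_lam[child] = row["lam"]
            if lab >= 0:
                max_lam[lab] = max(max_lam[lab], row["lam"] if np.isfinite(row["lam"]) else 0.0)

    probs = np.zeros(n)
    for i in range(n):
        if labels[i] >= 0 and max_lam[labels[i]] > 0:
            lam = point_lam[i] if np.isfinite(point_lam[i]) else max_lam[labels[i]]
            probs[i] = min(1.0, lam / max_lam[labels[i]])
        elif labels[i] >= 0:
            probs[i] = 1.0

    persistence = np.array([stability[c] for c in chosen])
    return HdbscanResult(labels, persistence, probs)


def _descendants(c, children):
    out, stack = set(), list(children.get(c, []))
    while stack:
        v = stack.pop()
        out.add(v)
        stack.extend(children.get(v, []))
    return out


def _max_finite(tree):
    finite = tree["lam"][np.isfinite(tree["lam"])]
    return finite.max() if len(finite) else 1.0
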