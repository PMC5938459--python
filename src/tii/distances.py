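"""Distances between unrooted topologies on a shared leaf set.

Implements the comparator metrics (Robinson-Foulds, branch-score) and the
similarity-aware influence distance: the SPR excess, an SPR rearrangement
distance scaled by the size of the maximum agreement subtree (MAST).  RF
and BSD work on arbitrary (possibly multifurcating) topologies; SPR and
MAST are defined here for binary trees only.

Exact SPR distance is NP-hard in general, so the contract distinguishes
certified values from upper bounds.  Exact values come from a
meet-in-the-middle breadth-first search over the SPR graph with canonical
bipartition-set deduplication; the heuristic is a deterministic greedy
RF-descent whose stall fallback is the always-valid bound
``n_leaves - MAST`` (the leaves outside an agreement subtree can each be
regrafted into place with one SPR move).

Internally trees are rewritten as integer adjacency maps with leaf
bitmasks, so bipartitions are machine ints and RF tests inside the search
are set operations on small frozensets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ArgumentError, CapabilityError, ValidationError
from .trees_io import Topology

__all__ = [
    "DistanceSpec",
    "rf_distance",
    "branch_score_distance",
    "mast_size",
    "spr_distance",
    "spr_excess",
    "spr_neighbors",
    "tree_distance",
]

_METRICS = ("rf", "bsd", "spr", "mast", "spr_excess")
_SPR_MODES = ("exact", "heuristic", "auto")


@dataclass(frozen=True)
class DistanceSpec:
    """Which metric to compute and how hard to try for exact SPR.

    In mode ``auto`` the meet-in-the-middle search certifies distances up
    to ``exact_max_distance`` and the greedy bound covers the rest.  Mode
    ``exact`` runs the unbounded search for trees with up to
    ``exact_max_leaves`` leaves (beyond that, only up to
    ``exact_max_distance``) and raises :class:`CapabilityError` instead of
    falling back.  ``state_cap`` bounds the number of distinct topologies
    any search may hold.
    """

    metric: str = "spr_excess"
    spr_mode: str = "auto"
    exact_max_leaves: int = 9
    exact_max_distance: int = 2
    state_cap: int = 200_000

    def __post_init__(self):
        if self.metric not in _METRICS:
            raise ArgumentError(f"metric must be one of {_METRICS}, got {self.metric!r}")
        if self.spr_mode not in _SPR_MODES:
            raise ArgumentError(
                f"spr_mode must be one of {_SPR_MODES}, got {self.spr_mode!r}"
            )
        if self.exact_max_leaves < 4 or self.exact_max_distance < 1 or self.state_cap < 1:
            raise ArgumentError("exact limits must be positive (and max leaves >= 4)")


# ---------------------------------------------------------------------------
# validation helpers


def _check_pair(t1: Topology, t2: Topology, need_binary: bool = False) -> None:
    if t1.leaf_labels != t2.leaf_labels:
        raise ValidationError(
            "trees must share one leaf set; differing taxa: "
            f"{sorted(t1.leaf_labels ^ t2.leaf_labels)}"
        )
    if t1.n_leaves < 4:
        raise ValidationError("distance computations need at least 4 leaves")
    if need_binary and not (t1.is_binary() and t2.is_binary()):
        raise ArgumentError("this operation requires binary (fully resolved) trees")


# ---------------------------------------------------------------------------
# Robinson-Foulds and branch-score


def rf_distance(t1: Topology, t2: Topology) -> int:
    """Robinson-Foulds distance: the number of nontrivial bipartitions
    present in exactly one of the two trees."""
    _check_pair(t1, t2)
    return len(t1.splits() ^ t2.splits())


def branch_score_distance(t1: Topology, t2: Topology) -> float:
    """Branch-score distance: sqrt of the summed squared branch-length
    differences over the union of bipartitions (pendant edges included);
    a bipartition absent from a tree contributes length zero."""
    _check_pair(t1, t2)
    if not (t1.has_branch_lengths and t2.has_branch_lengths):
        raise ArgumentError("branch-score distance requires branch lengths on both trees")
    s1, s2 = t1.split_lengths(), t2.split_lengths()
    total = 0.0
    for split in s1.keys() | s2.keys():
        diff = s1.get(split, 0.0) - s2.get(split, 0.0)
        total += diff * diff
    return math.sqrt(total)


# ---------------------------------------------------------------------------
# integer-kernel representation


def _pair_kernels(t1: Topology, t2: Topology):
    """Rewrite two topologies over one leaf set as (adjacency, leaf->bit)
    pairs sharing a label->bit assignment (sorted labels)."""
    labels = sorted(t1.leaf_labels)
    label_bit = {lab: 1 << i for i, lab in enumerate(labels)}
    k1 = _kernel_of(t1, label_bit)
    k2 = _kernel_of(t2, label_bit)
    return k1, k2, label_bit


def _kernel_of(t: Topology, label_bit: dict):
    adj = {n: list(nbrs) for n, nbrs in t.adjacency().items()}
    leafbit = {node: label_bit[lab] for node, lab in t.leaves().items()}
    return adj, leafbit


def _topology_of(adj, leafbit, bit_label) -> Topology:
    return Topology(adj, {node: bit_label[b] for node, b in leafbit.items()})


def _splits_key(adj, leafbit) -> frozenset:
    """Canonical shape key: frozenset of nontrivial bipartition bitmasks,
    each the side not containing bit 1 (tree rooted at that leaf)."""
    n = len(leafbit)
    ref = next(node for node, b in leafbit.items() if b == 1)
    # BFS order from the reference leaf, then accumulate subtree masks in
    # reverse order (each node has one parent in the rooted view)
    order = [ref]
    parent = {ref: -1}
    i = 0
    while i < len(order):
        u = order[i]
        i += 1
        for v in adj[u]:
            if v != parent[u]:
                parent[v] = u
                order.append(v)
    mask: dict[int, int] = {}
    out = []
    for u in reversed(order):
        if u == ref:
            break
        m = leafbit.get(u, 0)
        if not m:
            pu = parent[u]
            for v in adj[u]:
                if v != pu:
                    m |= mask[v]
        mask[u] = m
        c = m.bit_count()
        if 1 < c < n - 1:
            out.append(m)
    return frozenset(out)


# ---------------------------------------------------------------------------
# SPR move enumeration


def _spr_neighbor_adjacencies(adj):
    """All trees one unrooted SPR move away (raw: duplicates possible).

    For each directed edge (u, v) with u internal, the subtree on the v
    side is pruned, u is suppressed, and the subtree is regrafted onto
    every edge of the remaining tree except the merged one (a no-op).
    Enumeration order is deterministic (sorted node ids), which downstream
    tie-breaking relies on.
    """
    out = []
    nodes_sorted = sorted(adj)
    for u in nodes_sorted:
        if len(adj[u]) != 3:
            continue
        for v in adj[u]:
            # nodes on the pruned (v) side
            vside = {v}
            stack = [v]
            while stack:
                w = stack.pop()
                for z in adj[w]:
                    if z != u and z not in vside:
                        vside.add(z)
                        stack.append(z)
            a, b = (x for x in adj[u] if x != v)
            for x in nodes_sorted:
                if x == u or x in vside:
                    continue
                for y in adj[x]:
                    if y <= x or y == u or y in vside:
                        continue
                    new = {n: ns[:] for n, ns in adj.items()}
                    new[a] = [b if z == u else z for z in new[a]]
                    new[b] = [a if z == u else z for z in new[b]]
                    new[x] = [u if z == y else z for z in new[x]]
                    new[y] = [u if z == x else z for z in new[y]]
                    new[u] = [x, y, v]
                    out.append(new)
    return out


def _random_spr_adjacency(adj, rng):
    """One uniformly chosen (prune edge, regraft edge) SPR move; no-op
    regrafts are excluded.  ``rng`` is a numpy Generator."""
    directed = [(u, v) for u in sorted(adj) if len(adj[u]) == 3 for v in adj[u]]
    while True:
        u, v = directed[int(rng.integers(len(directed)))]
        vside = {v}
        stack = [v]
        while stack:
            w = stack.pop()
            for z in adj[w]:
                if z != u and z not in vside:
                    vside.add(z)
                    stack.append(z)
        a, b = (x for x in adj[u] if x != v)
        targets = [
            (x, y)
            for x in sorted(adj)
            if x != u and x not in vside
            for y in adj[x]
            if y > x and y != u and y not in vside
        ]
        if not targets:
            continue
        x, y = targets[int(rng.integers(len(targets)))]
        new = {n: ns[:] for n, ns in adj.items()}
        new[a] = [b if z == u else z for z in new[a]]
        new[b] = [a if z == u else z for z in new[b]]
        new[x] = [u if z == y else z for z in new[x]]
        new[y] = [u if z == x else z for z in new[y]]
        new[u] = [x, y, v]
        return new


def spr_neighbors(t: Topology) -> list:
    """Distinct topologies one SPR move from ``t`` (deterministic order)."""
    if not t.is_binary():
        raise ArgumentError("SPR moves are defined here for binary trees")
    labels = sorted(t.leaf_labels)
    label_bit = {lab: 1 << i for i, lab in enumerate(labels)}
    bit_label = {b: lab for lab, b in label_bit.items()}
    adj, leafbit = _kernel_of(t, label_bit)
    self_key = _splits_key(adj, leafbit)
    seen = {self_key}
    out = []
    for nadj in _spr_neighbor_adjacencies(adj):
        key = _splits_key(nadj, leafbit)
        if key not in seen:
            seen.add(key)
            out.append(_topology_of(nadj, leafbit, bit_label))
    return out


# ---------------------------------------------------------------------------
# maximum agreement subtree


def _rooted_arrays(adj, leafbit, leaf_node):
    """Postorder arrays of the tree rooted at the neighbor of ``leaf_node``
    (the leaf itself excluded): children tuples (None for leaves) and
    leaf-cluster bitmasks.  Root is the last index."""
    children: list = []
    clusters: list = []

    def build(node, parent) -> int:
        kids = [c for c in adj[node] if c != parent]
        if not kids:
            children.append(None)
            clusters.append(leafbit[node])
            return len(children) - 1
        idxs = [build(c, node) for c in kids]
        children.append(tuple(idxs))
        mask = 0
        for i in idxs:
            mask |= clusters[i]
        clusters.append(mask)
        return len(children) - 1

    (root,) = adj[leaf_node]
    build(root, leaf_node)
    return children, clusters


def _rooted_mast_table(c1, cl1, c2, cl2):
    """Classic rooted-MAST dynamic program for binary trees."""
    m1, m2 = len(cl1), len(cl2)
    M = [[0] * m2 for _ in range(m1)]
    for i in range(m1):
        ci = c1[i]
        row = M[i]
        for j in range(m2):
            cj = c2[j]
            if ci is None:
                row[j] = 1 if cl1[i] & cl2[j] else 0
            elif cj is None:
                row[j] = 1 if cl2[j] & cl1[i] else 0
            else:
                a1, a2 = ci
                b1, b2 = cj
                row[j] = max(
                    M[a1][b1] + M[a2][b2],
                    M[a1][b2] + M[a2][b1],
                    row[b1],
                    row[b2],
                    M[a1][j],
                    M[a2][j],
                )
    return M


def _trace_mast(i, j, c1, cl1, c2, cl2, M) -> int:
    """Recover one witness leaf bitmask achieving M[i][j] (first option in a
    fixed order, so the witness is deterministic)."""
    ci, cj = c1[i], c2[j]
    if ci is None:
        return cl1[i] if cl1[i] & cl2[j] else 0
    if cj is None:
        return cl2[j] if cl2[j] & cl1[i] else 0
    a1, a2 = ci
    b1, b2 = cj
    target = M[i][j]
    if M[a1][b1] + M[a2][b2] == target:
        return _trace_mast(a1, b1, c1, cl1, c2, cl2, M) | _trace_mast(
            a2, b2, c1, cl1, c2, cl2, M
        )
    if M[a1][b2] + M[a2][b1] == target:
        return _trace_mast(a1, b2, c1, cl1, c2, cl2, M) | _trace_mast(
            a2, b1, c1, cl1, c2, cl2, M
        )
    if M[i][b1] == target:
        return _trace_mast(i, b1, c1, cl1, c2, cl2, M)
    if M[i][b2] == target:
        return _trace_mast(i, b2, c1, cl1, c2, cl2, M)
    if M[a1][j] == target:
        return _trace_mast(a1, j, c1, cl1, c2, cl2, M)
    return _trace_mast(a2, j, c1, cl1, c2, cl2, M)


def _mast_kernel(adj1, lb1, adj2, lb2, want_witness: bool = False):
    """Unrooted MAST as the max over shared root-leaf choices of the rooted
    MAST (any agreement subtree contains some leaf, so the maximum over
    rootings at each leaf is exact)."""
    bitnode1 = {b: n for n, b in lb1.items()}
    bitnode2 = {b: n for n, b in lb2.items()}
    best = 0
    best_bundle = None
    for b in sorted(bitnode1):
        c1, cl1 = _rooted_arrays(adj1, lb1, bitnode1[b])
        c2, cl2 = _rooted_arrays(adj2, lb2, bitnode2[b])
        M = _rooted_mast_table(c1, cl1, c2, cl2)
        val = 1 + M[-1][-1]
        if val > best:
            best = val
            best_bundle = (b, c1, cl1, c2, cl2, M)
    if not want_witness:
        return best, 0
    b, c1, cl1, c2, cl2, M = best_bundle
    witness = b | _trace_mast(len(cl1) - 1, len(cl2) - 1, c1, cl1, c2, cl2, M)
    return best, witness


def mast_size(t1: Topology, t2: Topology):
    """Size of the maximum agreement subtree, with one witness leaf subset.

    Returns ``(size, frozenset_of_labels)``.  Always >= 3 for binary trees
    on a shared leaf set, since any three leaves induce the single
    unrooted triplet shape.
    """
    _check_pair(t1, t2, need_binary=True)
    k1, k2, label_bit = _pair_kernels(t1, t2)
    size, witness = _mast_kernel(*k1, *k2, want_witness=True)
    bit_label = {b: lab for lab, b in label_bit.items()}
    labels = frozenset(
        lab for b, lab in bit_label.items() if witness & b
    )
    return size, labels


# ---------------------------------------------------------------------------
# SPR distance


def _bfs_meet(adj1, lb1, adj2, lb2, depth_budget, state_cap):
    """Meet-in-the-middle BFS over the SPR graph.  Returns the exact
    distance, or None when the depth budget or state cap is exhausted
    before the value is certified."""
    k1 = _splits_key(adj1, lb1)
    k2 = _splits_key(adj2, lb2)
    if k1 == k2:
        return 0
    dist_a = {k1: 0}
    dist_b = {k2: 0}
    front_a = {k1: adj1}
    front_b = {k2: adj2}
    depth_a = depth_b = 0
    best = None
    while front_a and front_b:
        if best is not None and best <= depth_a + depth_b:
            return best
        if depth_budget is not None and depth_a + depth_b >= depth_budget:
            return best if (best is not None and best <= depth_budget) else None
        if len(front_a) <= len(front_b):
            front, dist, other_dist, lb = front_a, dist_a, dist_b, lb1
            depth_a += 1
            depth = depth_a
        else:
            front, dist, other_dist, lb = front_b, dist_b, dist_a, lb2
            depth_b += 1
            depth = depth_b
        new_front = {}
        for adj in front.values():
            for nadj in _spr_neighbor_adjacencies(adj):
                key = _splits_key(nadj, lb)
                if key in dist:
                    continue
                dist[key] = depth
                new_front[key] = nadj
                if key in other_dist:
                    cand = depth + other_dist[key]
                    if best is None or cand < best:
                        best = cand
        if front is front_a:
            front_a = new_front
        else:
            front_b = new_front
        if len(dist_a) + len(dist_b) > state_cap:
            return best if (best is not None and best <= depth_a + depth_b) else None
    return best


def _greedy_bound(adj1, lb1, adj2, lb2) -> int:
    """Deterministic greedy upper bound: repeatedly take the first SPR move
    that maximally reduces RF to the target; when stalled, add the
    n - MAST bound for the remainder."""
    target = _splits_key(adj2, lb2)
    cur = adj1
    cur_rf = len(_splits_key(adj1, lb1) ^ target)
    moves = 0
    while cur_rf:
        best_adj = None
        best_rf = cur_rf
        for nadj in _spr_neighbor_adjacencies(cur):
            r = len(_splits_key(nadj, lb1) ^ target)
            if r < best_rf:
                best_rf = r
                best_adj = nadj
        if best_adj is None:
            size, _ = _mast_kernel(cur, lb1, adj2, lb2)
            return moves + len(lb1) - size
        cur = best_adj
        cur_rf = best_rf
        moves += 1
    return moves


def spr_distance(t1: Topology, t2: Topology, spec: DistanceSpec | None = None):
    """Unrooted SPR distance with an exactness flag.

    Returns ``(value, flag)`` where flag is ``"exact"`` for a certified
    minimum and ``"bound"`` for a heuristic upper bound.
    """
    spec = spec or DistanceSpec()
    _check_pair(t1, t2, need_binary=True)
    (adj1, lb1), (adj2, lb2), _ = _pair_kernels(t1, t2)
    if _splits_key(adj1, lb1) == _splits_key(adj2, lb2):
        return 0, "exact"
    n = t1.n_leaves
    if spec.spr_mode == "heuristic":
        return _greedy_bound(adj1, lb1, adj2, lb2), "bound"
    if spec.spr_mode == "auto":
        # certify small distances only; anything deeper gets the greedy bound
        value = _bfs_meet(
            adj1, lb1, adj2, lb2, spec.exact_max_distance, spec.state_cap
        )
        if value is not None:
            return value, "exact"
        return _greedy_bound(adj1, lb1, adj2, lb2), "bound"
    depth_budget = None if n <= spec.exact_max_leaves else spec.exact_max_distance
    value = _bfs_meet(adj1, lb1, adj2, lb2, depth_budget, spec.state_cap)
    if value is not None:
        return value, "exact"
    raise CapabilityError(
        f"exact SPR search beyond limits (n={n} leaves, "
        f"certified depth {depth_budget}, state cap {spec.state_cap}); "
        "use spr_mode='heuristic' or raise the limits"
    )


def spr_excess(t1: Topology, t2: Topology, spec: DistanceSpec | None = None) -> float:
    """SPR distance scaled by the size of the shared tree: SPR / MAST.

    Dividing the rearrangement distance by the number of taxa in the
    maximum agreement subtree penalizes disagreement more when the trees
    otherwise share little structure.
    """
    spec = spec or DistanceSpec()
    _check_pair(t1, t2, need_binary=True)
    d, _flag = spr_distance(t1, t2, spec)
    if d == 0:
        return 0.0
    (adj1, lb1), (adj2, lb2), _ = _pair_kernels(t1, t2)
    size, _ = _mast_kernel(adj1, lb1, adj2, lb2)
    return d / size


def tree_distance(t1: Topology, t2: Topology, spec: DistanceSpec) -> float:
    """Dispatch on ``spec.metric``.  For ``mast`` the returned value is the
    dissimilarity ``n_leaves - MAST`` so that every metric satisfies
    d(t, t) = 0."""
    if spec.metric == "rf":
        return float(rf_distance(t1, t2))
    if spec.metric == "bsd":
        return branch_score_distance(t1, t2)
    if spec.metric == "spr":
        return float(spr_distance(t1, t2, spec)[0])
    if spec.metric == "mast":
        size, _ = mast_size(t1, t2)
        return float(t1.n_leaves - size)
    return spr_excess(t1, t2, spec)
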