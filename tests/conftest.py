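"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own split machinery:
bipartitions are recovered from Steiner-subtree disjointness on a
networkx graph, and MAST/restriction checks enumerate leaf subsets
exhaustively.
"""

from __future__ import annotations

import itertools

import networkx as nx
import pytest

from tii import Topology, WeightedTreeSet, build_posterior


def topo(newick: str) -> Topology:
    return Topology.from_newick(newick)


@pytest.fixture
def quartets():
    """The three unrooted quartet shapes on {A, B, C, D}."""
    return (
        topo("((A,B),(C,D));"),
        topo("((A,C),(B,D));"),
        topo("((A,D),(B,C));"),
    )


@pytest.fixture
def five_leaf():
    return topo("((A,B),(C,(D,E)));")


@pytest.fixture
def point_mass():
    def make(newick: str) -> WeightedTreeSet:
        return build_posterior([topo(newick)])

    return make


# ---------------------------------------------------------------------------
# independent oracles


def topology_graph(t: Topology) -> tuple:
    g = nx.Graph()
    for u, nbrs in t.adjacency().items():
        for v in nbrs:
            g.add_edge(u, v)
    return g, t.leaves()


def steiner_nodes(g: nx.Graph, terminals: list) -> set:
    """Nodes of the minimal subtree spanning the terminals (union of
    pairwise paths; exact on trees)."""
    nodes: set = set(terminals)
    for a, b in itertools.combinations(terminals, 2):
        nodes.update(nx.shortest_path(g, a, b))
    return nodes


def oracle_splits(t: Topology) -> frozenset:
    """All nontrivial bipartitions of a topology, found by testing every
    leaf subset for Steiner-subtree disjointness from its complement."""
    g, leaves = topology_graph(t)
    labels = sorted(leaves.values())
    by_label = {lab: node for node, lab in leaves.items()}
    ref = labels[0]
    found = []
    others = labels[1:]
    for r in range(2, len(labels) - 1):
        for side in itertools.combinations(others, r):
            a = steiner_nodes(g, [by_label[x] for x in side])
            b = steiner_nodes(g, [by_label[x] for x in labels if x not in side])
            if not (a & b):
                found.append(frozenset(side))
    assert ref not in {x for s in found for x in s}
    return frozenset(found)


def restricted_splits(t: Topology, subset: frozenset) -> frozenset:
    """Nontrivial splits of the restriction of ``t`` to ``subset``, induced
    from the full tree's edge sides."""
    full = t.leaf_labels
    ref = min(subset)
    sides = set()
    for split in t.splits():
        sides.add(split)
        sides.add(full - split)
    for leaf in full:  # pendant edges
        sides.add(frozenset((leaf,)))
        sides.add(full - {leaf})
    induced = set()
    for side in sides:
        inter = frozenset(side & subset)
        if 1 < len(inter) < len(subset) - 1:
            if ref in inter:
                inter = frozenset(subset - inter)
            induced.add(inter)
    return frozenset(induced)


def oracle_mast(t1: Topology, t2: Topology) -> int:
    """Exhaustive maximum agreement subtree size (use only for n <= 8)."""
    labels = sorted(t1.leaf_labels)
    for size in range(len(labels), 2, -1):
        for subset in itertools.combinations(labels, size):
            s = frozenset(subset)
            if restricted_splits(t1, s) == restricted_splits(t2, s):
                return size
    return 3
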