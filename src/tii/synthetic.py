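"""Seeded synthetic topologies, pseudo-posteriors, and planted-influence
scenarios.

These generators emulate the objects a Bayesian jackknife study produces —
peaked posterior samples of binary trees, and per-taxon jackknifed
posteriors displaced from the full analysis by a known number of SPR
moves — so the whole pipeline is testable with a known ground truth and
no external inference runs.  They emulate topological displacement and
posterior peakedness only, not branch lengths, substitution models, or
MCMC autocorrelation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .distances import (
    DistanceSpec,
    _kernel_of,
    _random_spr_adjacency,
    _splits_key,
    _topology_of,
    spr_distance,
)
from .errors import ArgumentError, GenerationError, ValidationError
from .posterior import WeightedTreeSet
from .trees_io import CharacterMatrix, Topology

__all__ = [
    "SyntheticScenario",
    "random_topology",
    "random_spr_walk",
    "pseudo_posterior",
    "planted_influence_suite",
    "random_character_matrix",
]


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def random_topology(n_taxa: int, seed=0, labels=None) -> Topology:
    """A uniformly random unrooted binary labeled topology.

    Built by sequential random edge attachment: starting from the
    three-leaf star, each new leaf subdivides one of the 2k - 3 existing
    edges chosen uniformly, which yields the uniform distribution over the
    (2n - 5)!! labeled shapes.
    """
    if n_taxa < 4:
        raise ArgumentError(f"need at least 4 taxa, got {n_taxa}")
    if labels is None:
        width = len(str(n_taxa))
        labels = [f"t{i + 1:0{width}d}" for i in range(n_taxa)]
    elif len(labels) != n_taxa:
        raise ArgumentError("labels must match n_taxa")
    rng = _as_rng(seed)
    # nodes 0..2 leaves, 3 the center
    adj = {0: [3], 1: [3], 2: [3], 3: [0, 1, 2]}
    edges = [(0, 3), (1, 3), (2, 3)]
    next_node = 4
    for leaf_i in range(3, n_taxa):
        u, v = edges.pop(int(rng.integers(len(edges))))
        mid, leaf = next_node, next_node + 1
        next_node += 2
        adj[u] = [mid if z == v else z for z in adj[u]]
        adj[v] = [mid if z == u else z for z in adj[v]]
        adj[mid] = [u, v, leaf]
        adj[leaf] = [mid]
        edges.extend([(u, mid), (v, mid), (leaf, mid)])
    leaf_nodes = [n for n, nbrs in adj.items() if len(nbrs) == 1]
    leaf_nodes.sort()
    return Topology(adj, {node: labels[i] for i, node in enumerate(leaf_nodes)})


def random_spr_walk(topology: Topology, n_moves: int, seed=0) -> Topology:
    """Apply ``n_moves`` random SPR moves (no-op regrafts excluded)."""
    if n_moves < 0:
        raise ArgumentError("n_moves must be >= 0")
    if not topology.is_binary():
        raise ArgumentError("SPR walks require a binary topology")
    rng = _as_rng(seed)
    labels = sorted(topology.leaf_labels)
    label_bit = {lab: 1 << i for i, lab in enumerate(labels)}
    bit_label = {b: lab for lab, b in label_bit.items()}
    adj, leafbit = _kernel_of(topology, label_bit)
    for _ in range(n_moves):
        adj = _random_spr_adjacency(adj, rng)
    return _topology_of(adj, leafbit, bit_label)


def pseudo_posterior(
    center: Topology,
    n_unique: int,
    max_moves: int = 2,
    concentration: float = 1.0,
    seed=0,
    weighting: str = "peaked",
    max_proposals_per_tree: int = 200,
) -> WeightedTreeSet:
    """A weighted set of distinct topologies scattered around ``center``.

    Members are obtained by 1..``max_moves`` random SPR moves from the
    center; weights are a symmetric Dirichlet draw (parameter
    ``concentration``) sorted so the center carries the largest weight,
    mimicking a peaked posterior.  ``weighting="flat"`` gives equal
    weights for stress tests.
    """
    if n_unique < 1:
        raise ArgumentError("n_unique must be >= 1")
    if max_moves < 0:
        raise ArgumentError("max_moves must be >= 0")
    if concentration <= 0:
        raise ArgumentError("concentration must be positive")
    if weighting not in ("peaked", "flat"):
        raise ArgumentError(f"unknown weighting {weighting!r}")
    if not center.is_binary():
        raise ArgumentError("the pseudo-posterior center must be binary")
    rng = _as_rng(seed)
    labels = sorted(center.leaf_labels)
    label_bit = {lab: 1 << i for i, lab in enumerate(labels)}
    bit_label = {b: lab for lab, b in label_bit.items()}
    adj0, leafbit = _kernel_of(center, label_bit)
    topologies = [center]
    seen = {_splits_key(adj0, leafbit)}
    if n_unique > 1 and max_moves == 0:
        raise GenerationError(
            f"cannot realize {n_unique} distinct shapes with max_moves=0"
        )
    budget = max_proposals_per_tree * (n_unique - 1)
    proposals = 0
    while len(topologies) < n_unique:
        if proposals >= budget:
            raise GenerationError(
                f"realized only {len(topologies)} of {n_unique} distinct shapes "
                f"after {proposals} proposals (max_moves={max_moves})"
            )
        proposals += 1
        k = int(rng.integers(1, max_moves + 1))
        adj = adj0
        for _ in range(k):
            adj = _random_spr_adjacency(adj, rng)
        key = _splits_key(adj, leafbit)
        if key not in seen:
            seen.add(key)
            topologies.append(_topology_of(adj, leafbit, bit_label))
    if weighting == "flat":
        weights = np.full(n_unique, 1.0 / n_unique)
    else:
        weights = np.sort(rng.dirichlet([concentration] * n_unique))[::-1]
        weights = weights / weights.sum()
    return WeightedTreeSet(topologies=tuple(topologies), weights=tuple(float(w) for w in weights))


@dataclass(frozen=True)
class SyntheticScenario:
    """A planted-influence study design.

    ``displacement`` maps each studied taxon to the number of SPR moves
    separating its jackknifed posterior's center from the pruned base
    tree; zero means the jackknife leaves inference unchanged.
    """

    n_taxa: int
    base: Topology
    displacement: Mapping[str, int]
    n_unique: int = 8
    max_moves: int = 2
    concentration: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 6:
            raise ValidationError("scenarios need at least 6 taxa")
        if self.base.n_leaves != self.n_taxa:
            raise ValidationError("base tree must have n_taxa leaves")
        if not set(self.displacement) <= self.base.leaf_labels:
            raise ValidationError("displacement keys must be taxa of the base tree")
        if any(k < 0 for k in self.displacement.values()):
            raise ValidationError("displacements must be nonnegative")
        if self.n_unique < 1:
            raise ValidationError("n_unique must be >= 1")

    @classmethod
    def random(
        cls,
        n_taxa: int,
        seed: int,
        n_unique: int = 8,
        max_moves: int = 2,
        concentration: float = 1.5,
        displacement_levels=(0, 1, 2, 3, 4),
    ) -> "SyntheticScenario":
        """A random base topology with displacements cycling through
        ``displacement_levels`` assigned to a random taxon order."""
        rng = np.random.default_rng(seed)
        base = random_topology(n_taxa, rng)
        taxa = sorted(base.leaf_labels)
        order = [taxa[i] for i in rng.permutation(n_taxa)]
        displacement = {
            taxon: displacement_levels[i % len(displacement_levels)]
            for i, taxon in enumerate(order)
        }
        return cls(
            n_taxa=n_taxa,
            base=base,
            displacement=displacement,
            n_unique=n_unique,
            max_moves=max_moves,
            concentration=concentration,
            seed=seed,
        )


def planted_influence_suite(scenario: SyntheticScenario):
    """Materialize a scenario: the full pseudo-posterior, one jackknifed
    pseudo-posterior per displaced taxon, and the planted truth.

    Returns ``(full, dropped, truth)`` where ``dropped[taxon]`` is centered
    on ``prune(base, taxon)`` displaced by ``truth[taxon]`` SPR moves.
    """
    n_centers = 1 + len(scenario.displacement)
    child_seeds = np.random.SeedSequence(scenario.seed).generate_state(2 * n_centers) % (
        2**31
    )
    full = pseudo_posterior(
        scenario.base,
        scenario.n_unique,
        max_moves=scenario.max_moves,
        concentration=scenario.concentration,
        seed=int(child_seeds[0]),
    )
    dropped = {}
    spr_spec = DistanceSpec(spr_mode="auto")
    for i, taxon in enumerate(sorted(scenario.displacement), start=1):
        k = scenario.displacement[taxon]
        center = scenario.base.prune(taxon)
        if k:
            # a k-move walk can realize fewer than k: retry so the planted
            # displacement is the actual SPR separation of the centers
            rng = np.random.default_rng(int(child_seeds[2 * i]))
            pruned_base = center
            best, best_sep = None, -1
            for _ in range(50):
                cand = random_spr_walk(pruned_base, k, rng)
                sep, _flag = spr_distance(pruned_base, cand, spr_spec)
                if sep > best_sep:
                    best, best_sep = cand, sep
                if sep >= k:
                    break
            center = best
        dropped[taxon] = pseudo_posterior(
            center,
            scenario.n_unique,
            max_moves=scenario.max_moves,
            concentration=scenario.concentration,
            seed=int(child_seeds[2 * i + 1]),
        )
    return full, dropped, dict(scenario.displacement)


def random_character_matrix(
    taxa,
    n_characters: int = 50,
    missing_range=(0.0, 0.6),
    seed=0,
) -> CharacterMatrix:
    """A synthetic binary (0/1) character matrix with per-taxon missing-data
    proportions drawn uniformly from ``missing_range`` — enough structure
    to exercise missing-data rankings and regressions, with no
    phylogenetic signal implied."""
    taxa = list(taxa)
    if not taxa or n_characters < 1:
        raise ArgumentError("need at least one taxon and one character")
    rng = _as_rng(seed)
    lo, hi = missing_range
    if not 0.0 <= lo <= hi <= 1.0:
        raise ArgumentError("missing_range must satisfy 0 <= lo <= hi <= 1")
    rows = []
    for _ in taxa:
        rate = rng.uniform(lo, hi)
        row = [
            "?" if rng.random() < rate else str(int(rng.integers(2)))
            for _ in range(n_characters)
        ]
        rows.append(tuple(row))
    return CharacterMatrix(taxa=tuple(taxa), rows=tuple(rows), datatype="standard")
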