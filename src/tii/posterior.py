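"""Weighted sets of unique topologies from posterior tree samples.

A Bayesian MCMC run yields an ordered sample of trees; after burn-in the
posterior probability of a topology is estimated as its sample frequency
(the standard approach).  This module builds those weighted sets, prunes a
taxon a posteriori (merging topologies that collapse to the same shape and
summing their weights), and extracts credible subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import ArgumentError, TaxonLookupError, ValidationError
from .trees_io import Topology

__all__ = ["WeightedTreeSet", "build_posterior", "prune_taxon", "credible_set"]

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class WeightedTreeSet:
    """Pairwise-distinct topologies over one leaf set with weights summing to 1."""

    topologies: tuple
    weights: tuple

    def __post_init__(self):
        if not self.topologies:
            raise ValidationError("a weighted tree set needs at least one topology")
        if len(self.topologies) != len(self.weights):
            raise ValidationError("topologies and weights must align")
        leafset = self.topologies[0].leaf_labels
        if any(t.leaf_labels != leafset for t in self.topologies):
            raise ValidationError("all topologies must share one leaf set")
        if len(set(self.topologies)) != len(self.topologies):
            raise ValidationError("topologies must be pairwise shape-distinct")
        if any(w <= 0 for w in self.weights):
            raise ValidationError("weights must be positive")
        if abs(sum(self.weights) - 1.0) > _WEIGHT_TOL:
            raise ValidationError(f"weights sum to {sum(self.weights)}, not 1")

    @property
    def leaf_labels(self) -> frozenset:
        return self.topologies[0].leaf_labels

    def __len__(self) -> int:
        return len(self.topologies)

    def __iter__(self):
        return iter(zip(self.topologies, self.weights))


def build_posterior(trees: Sequence[Topology]) -> WeightedTreeSet:
    """Collapse an ordered tree sample to unique topologies weighted by
    sample frequency.

    The representative of each unique shape keeps the branch lengths of its
    first occurrence; order follows first appearance in the sample.
    """
    if not trees:
        raise ValidationError("empty tree sample")
    leafset = trees[0].leaf_labels
    reps: dict[Topology, int] = {}
    counts: list[int] = []
    order: list[Topology] = []
    for tree in trees:
        if tree.leaf_labels != leafset:
            raise ValidationError(
                "inconsistent leaf sets in sample: "
                f"{sorted(tree.leaf_labels ^ leafset)} differ"
            )
        idx = reps.get(tree)
        if idx is None:
            reps[tree] = len(order)
            order.append(tree)
            counts.append(1)
        else:
            counts[idx] += 1
    total = len(trees)
    return WeightedTreeSet(
        topologies=tuple(order), weights=tuple(c / total for c in counts)
    )


def prune_taxon(tree_set: WeightedTreeSet, taxon: str) -> WeightedTreeSet:
    """Drop one taxon from every topology a posteriori.

    Topologies that become shape-equal after pruning are merged and their
    weights summed, so total weight is conserved.  The TII double sum is
    invariant to this merge.
    """
    if taxon not in tree_set.leaf_labels:
        raise TaxonLookupError(f"taxon {taxon!r} not in the tree set")
    if len(tree_set.leaf_labels) < 4:
        raise ArgumentError("pruning needs at least 4 leaves to keep 3")
    merged: dict[Topology, float] = {}
    order: list[Topology] = []
    for topo, weight in tree_set:
        pruned = topo.prune(taxon)
        if pruned in merged:
            merged[pruned] += weight
        else:
            merged[pruned] = weight
            order.append(pruned)
    return WeightedTreeSet(
        topologies=tuple(order), weights=tuple(merged[t] for t in order)
    )


def credible_set(tree_set: WeightedTreeSet, level: float) -> WeightedTreeSet:
    """Smallest prefix of topologies, in descending weight order, whose
    cumulative weight reaches ``level`` (ties broken by first-seen order).

    The weights of the subset are returned unnormalized relative to the
    full posterior truncated then renormalized to sum to 1, keeping the
    result a valid :class:`WeightedTreeSet`.
    """
    if not 0.0 < level <= 1.0:
        raise ArgumentError(f"credible level must be in (0, 1], got {level}")
    indexed = sorted(
        range(len(tree_set)), key=lambda i: (-tree_set.weights[i], i)
    )
    chosen: list[int] = []
    cum = 0.0
    for i in indexed:
        chosen.append(i)
        cum += tree_set.weights[i]
        if cum >= level - _WEIGHT_TOL:
            break
    chosen.sort()  # preserve first-seen order in the result
    topos = tuple(tree_set.topologies[i] for i in chosen)
    raw = [tree_set.weights[i] for i in chosen]
    total = sum(raw)
    return WeightedTreeSet(topologies=topos, weights=tuple(w / total for w in raw))
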