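"""The taxon influence index (TII).

The influence of taxon *i* is the expected tree distance between the
full-data posterior with *i* pruned a posteriori and the posterior from
re-inference with *i* excluded:

    TII(i) = E[ d(T*_i, T'_i) ] = sum_{T*, T'} w(T*) w(T') d(T*, T')

where the weights are posterior probabilities (sample frequencies of
unique topologies) and d is a tree distance, by default the SPR excess.
The double sum costs |T*| x |T'| distance evaluations, so the index is
also estimated by repeatedly subsampling min(|T*|, |T'|) topologies from
each posterior without replacement (successive draws proportional to
remaining weights), recomputing the double sum on each subsample, and
taking the median across iterations.  Taxa are ranked by median TII.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .distances import DistanceSpec, tree_distance
from .errors import ArgumentError, TaxonLookupError, ValidationError
from .posterior import WeightedTreeSet, prune_taxon

__all__ = [
    "TIIEstimate",
    "Ranking",
    "tii_exact",
    "tii_resampled",
    "flag_outliers",
    "rank_taxa",
    "compute_estimates",
]


@dataclass(frozen=True)
class TIIEstimate:
    """Per-taxon replicate TII values with order-statistic summaries.

    ``median`` and the quartiles ``iqr = (q1, q3)`` are computed from the
    replicates with linear interpolation (numpy's default), fixed so
    estimates are bit-reproducible; ``outliers`` are replicate indices
    outside the Tukey fences.
    """

    taxon: str
    replicates: tuple
    median: float
    iqr: tuple
    outliers: tuple

    @classmethod
    def from_replicates(cls, taxon: str, replicates: Sequence[float]) -> "TIIEstimate":
        reps = tuple(float(r) for r in replicates)
        if any(r < 0 for r in reps):
            raise ValidationError("TII replicates must be nonnegative")
        q1, q3 = (np.percentile(reps, [25, 75]) if len(reps) >= 4 else (min(reps), max(reps)))
        outliers = flag_outliers(reps) if len(reps) >= 4 else ()
        return cls(
            taxon=taxon,
            replicates=reps,
            median=float(np.median(reps)),
            iqr=(float(q1), float(q3)),
            outliers=outliers,
        )


@dataclass(frozen=True)
class Ranking:
    """Taxa ordered by non-increasing score; rank is the 1-based position.

    Ties are broken by taxon name (lexicographic ascending) so rankings
    are deterministic.
    """

    entries: tuple  # tuple of (taxon, score)

    def __post_init__(self):
        taxa = [t for t, _ in self.entries]
        if len(set(taxa)) != len(taxa):
            raise ValidationError("ranking taxa must be unique")
        scores = [s for _, s in self.entries]
        if any(scores[i] < scores[i + 1] for i in range(len(scores) - 1)):
            raise ValidationError("ranking scores must be non-increasing")

    @classmethod
    def from_scores(cls, scores: Mapping[str, float]) -> "Ranking":
        ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        return cls(entries=tuple((t, float(s)) for t, s in ordered))

    @property
    def taxa(self) -> tuple:
        return tuple(t for t, _ in self.entries)

    def rank_of(self, taxon: str) -> int:
        try:
            return self.taxa.index(taxon) + 1
        except ValueError:
            raise TaxonLookupError(f"taxon {taxon!r} not in ranking") from None

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


# ---------------------------------------------------------------------------
# the exact double sum


def _check_tii_inputs(full: WeightedTreeSet, dropped: WeightedTreeSet, taxon: str):
    if taxon not in full.leaf_labels:
        raise TaxonLookupError(f"taxon {taxon!r} not in the full posterior")
    expected = full.leaf_labels - {taxon}
    if dropped.leaf_labels != expected:
        raise ValidationError(
            f"dropped posterior leaf set must equal the full set minus {taxon!r}; "
            f"differing taxa: {sorted(dropped.leaf_labels ^ expected)}"
        )


class _PairDistanceCache:
    """Memoizes tree distances by unordered topology pair.  Distances are
    pure functions of the pair, so memoization never changes results."""

    def __init__(self, spec: DistanceSpec):
        self.spec = spec
        self._store: dict = {}
        self.hits = 0
        self.misses = 0

    def __call__(self, a, b) -> float:
        if a == b:
            return 0.0
        key = frozenset((a, b))
        val = self._store.get(key)
        if val is None:
            val = tree_distance(a, b, self.spec)
            self._store[key] = val
            self.misses += 1
        else:
            self.hits += 1
        return val


def _double_sum(topos_a, weights_a, topos_b, weights_b, dist) -> float:
    total = 0.0
    for ta, wa in zip(topos_a, weights_a):
        for tb, wb in zip(topos_b, weights_b):
            if ta == tb:
                continue
            total += wa * wb * dist(ta, tb)
    return total


def tii_exact(
    full: WeightedTreeSet,
    dropped: WeightedTreeSet,
    taxon: str,
    spec: DistanceSpec | None = None,
    _cache: _PairDistanceCache | None = None,
) -> float:
    """The full double-sum expectation of the tree distance between the
    pruned full posterior and the jackknifed posterior.

    Duplicate topologies arising from pruning are merged first; the sum is
    invariant to that merge.
    """
    spec = spec or DistanceSpec()
    _check_tii_inputs(full, dropped, taxon)
    pruned = prune_taxon(full, taxon)
    dist = _cache if _cache is not None else _PairDistanceCache(spec)
    return _double_sum(
        pruned.topologies, pruned.weights, dropped.topologies, dropped.weights, dist
    )


# ---------------------------------------------------------------------------
# the resampling estimator


def _weighted_draw_without_replacement(weights: np.ndarray, m: int, rng) -> list:
    """Successive draws, each proportional to the remaining weights."""
    avail = list(range(len(weights)))
    w = [float(x) for x in weights]
    out = []
    for _ in range(m):
        total = sum(w)
        r = rng.random() * total
        acc = 0.0
        pick = len(w) - 1
        for i, wi in enumerate(w):
            acc += wi
            if r < acc:
                pick = i
                break
        out.append(avail.pop(pick))
        w.pop(pick)
    return out


def tii_resampled(
    full: WeightedTreeSet,
    dropped: WeightedTreeSet,
    taxon: str,
    spec: DistanceSpec | None = None,
    n_iter: int = 100,
    seed: int = 0,
    weighting: str = "renormalized",
    sample_size: int | None = None,
    _cache: _PairDistanceCache | None = None,
) -> TIIEstimate:
    """Median-of-replicates TII estimate.

    Each iteration draws ``min(|pruned full|, |dropped|)`` topologies from
    each posterior without replacement (successive draws proportional to
    remaining weights) and evaluates the double sum on the subsets.  With
    ``weighting="renormalized"`` (default) each subset keeps its original
    posterior weights renormalized to 1 — so a whole-set draw reproduces
    the exact TII identically; ``weighting="uniform"`` weights draws
    equally.  ``sample_size`` overrides the min-rule subset size.
    Reproducible from ``seed``.
    """
    spec = spec or DistanceSpec()
    if n_iter < 1:
        raise ArgumentError(f"n_iter must be >= 1, got {n_iter}")
    if weighting not in ("renormalized", "uniform"):
        raise ArgumentError(f"unknown weighting {weighting!r}")
    _check_tii_inputs(full, dropped, taxon)
    pruned = prune_taxon(full, taxon)
    m = min(len(pruned), len(dropped)) if sample_size is None else sample_size
    if not 1 <= m <= max(len(pruned), len(dropped)):
        raise ArgumentError(f"sample_size {m} outside [1, {max(len(pruned), len(dropped))}]")
    dist = _cache if _cache is not None else _PairDistanceCache(spec)
    rng = np.random.default_rng(seed)
    wa_full = np.asarray(pruned.weights)
    wb_full = np.asarray(dropped.weights)
    replicates = []
    for _ in range(n_iter):
        ia = _weighted_draw_without_replacement(wa_full, min(m, len(pruned)), rng)
        ib = _weighted_draw_without_replacement(wb_full, min(m, len(dropped)), rng)
        ta = [pruned.topologies[i] for i in ia]
        tb = [dropped.topologies[i] for i in ib]
        if weighting == "renormalized":
            wa = wa_full[ia] / wa_full[ia].sum()
            wb = wb_full[ib] / wb_full[ib].sum()
        else:
            wa = np.full(len(ia), 1.0 / len(ia))
            wb = np.full(len(ib), 1.0 / len(ib))
        replicates.append(_double_sum(ta, wa, tb, wb, dist))
    return TIIEstimate.from_replicates(taxon, replicates)


def flag_outliers(replicates: Sequence[float]) -> tuple:
    """Indices of values outside the Tukey fences
    [q1 - 1.5 IQR, q3 + 1.5 IQR]."""
    if len(replicates) < 4:
        raise ArgumentError("outlier flagging needs at least 4 replicates")
    arr = np.asarray(replicates, dtype=float)
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return tuple(int(i) for i in np.nonzero((arr < lo) | (arr > hi))[0])


def rank_taxa(estimates: Sequence[TIIEstimate]) -> Ranking:
    """Rank taxa by descending median TII (ties: lexicographic by name)."""
    taxa = [e.taxon for e in estimates]
    if len(set(taxa)) != len(taxa):
        raise ValidationError("estimates must cover distinct taxa")
    return Ranking.from_scores({e.taxon: e.median for e in estimates})


# ---------------------------------------------------------------------------
# convenience pipeline


def compute_estimates(
    full: WeightedTreeSet,
    dropped: Mapping[str, WeightedTreeSet],
    spec: DistanceSpec | None = None,
    n_iter: int = 100,
    seed: int = 0,
    weighting: str = "renormalized",
) -> list:
    """TII estimates for every taxon in ``dropped`` (sorted), with one
    distance cache shared across taxa and per-taxon seeds derived from
    ``seed`` so results do not depend on mapping order."""
    spec = spec or DistanceSpec()
    taxa = sorted(dropped)
    child_seeds = np.random.SeedSequence(seed).generate_state(max(len(taxa), 1)) % (2**31)
    cache = _PairDistanceCache(spec)
    return [
        tii_resampled(
            full,
            dropped[taxon],
            taxon,
            spec,
            n_iter=n_iter,
            seed=int(child_seeds[i]),
            weighting=weighting,
            _cache=cache,
        )
        for i, taxon in enumerate(taxa)
    ]
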