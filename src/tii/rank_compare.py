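"""Comparing taxon rankings and relating influence to missing data.

Rank-biased overlap (RBO) is a top-weighted similarity between two
rankings: a geometrically decaying average of the overlap proportions of
matched prefixes.  For conjoint full-depth lists of n taxa,

    rbo(p) = (1 - p) * sum_{d=1..n} p^(d-1) * A_d  +  p^n * A_n

where A_d is the fraction of taxa shared by the two top-d prefixes and
the persistence p in (0, 1) sets how top-heavy the comparison is.
Significance against the null of dissimilar rankings is assessed by
permuting one list; the missing-data utilities rank taxa by their
proportion of "?" cells and regress median influence on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ArgumentError, DegenerateFitError, ValidationError
from .influence import Ranking, TIIEstimate
from .trees_io import CharacterMatrix

__all__ = [
    "RBOResult",
    "rbo",
    "rbo_permutation_test",
    "missing_proportion_ranking",
    "fit_tii_vs_missing",
]


@dataclass(frozen=True)
class RBOResult:
    rbo: float
    persistence: float
    p_value: float
    n_permutations: int
    seed: int


def _rbo_lists(a: Sequence[str], b: Sequence[str], p: float) -> float:
    n = len(a)
    seen_a: set = set()
    seen_b: set = set()
    overlap = 0
    total = 0.0
    weight = 1.0  # p^(d-1)
    a_d = 0.0
    for d in range(1, n + 1):
        xa, xb = a[d - 1], b[d - 1]
        if xa == xb:
            overlap += 1
        else:
            overlap += (xa in seen_b) + (xb in seen_a)
            seen_a.add(xa)
            seen_b.add(xb)
        a_d = overlap / d
        total += weight * a_d
        weight *= p
    # weight is now p^n; conjoint full lists have A_n = 1
    return (1.0 - p) * total + weight * a_d


def rbo(a: Ranking, b: Ranking, persistence: float = 0.9) -> float:
    """Extrapolated rank-biased overlap of two conjoint full-depth rankings."""
    if not 0.0 < persistence < 1.0:
        raise ArgumentError(f"persistence must be in (0, 1), got {persistence}")
    if set(a.taxa) != set(b.taxa):
        raise ValidationError(
            "rankings must cover the same taxa; differing: "
            f"{sorted(set(a.taxa) ^ set(b.taxa))}"
        )
    return _rbo_lists(a.taxa, b.taxa, persistence)


def rbo_permutation_test(
    a: Ranking,
    b: Ranking,
    persistence: float = 0.9,
    n_permutations: int = 9999,
    seed: int = 0,
) -> RBOResult:
    """One-sided permutation test for ranking similarity.

    The null distribution comes from uniformly random permutations of
    ranking ``b``; large observed rbo rejects the null of dissimilar
    rankings.  The add-one rule gives
    p = (1 + #{null rbo >= observed}) / (n_permutations + 1).
    """
    if n_permutations < 1:
        raise ArgumentError(f"n_permutations must be >= 1, got {n_permutations}")
    observed = rbo(a, b, persistence)
    rng = np.random.default_rng(seed)
    b_taxa = list(b.taxa)
    a_taxa = a.taxa
    exceed = 0
    for _ in range(n_permutations):
        perm = [b_taxa[i] for i in rng.permutation(len(b_taxa))]
        if _rbo_lists(a_taxa, perm, persistence) >= observed:
            exceed += 1
    p_value = (1 + exceed) / (n_permutations + 1)
    return RBOResult(
        rbo=observed,
        persistence=persistence,
        p_value=p_value,
        n_permutations=n_permutations,
        seed=seed,
    )


def missing_proportion_ranking(
    matrix: CharacterMatrix, missing_symbols: frozenset = frozenset({"?"})
) -> Ranking:
    """Rank taxa by their proportion of missing cells, descending.

    Only ``?`` counts as missing by default; the gap/inapplicable code
    ``-`` does not (widen ``missing_symbols`` to change that).
    """
    if matrix.n_taxa == 0 or matrix.n_characters == 0:
        raise ArgumentError("cannot rank an empty matrix")
    scores = {
        taxon: sum(s in missing_symbols for s in row) / matrix.n_characters
        for taxon, row in zip(matrix.taxa, matrix.rows)
    }
    return Ranking.from_scores(scores)


def fit_tii_vs_missing(
    estimates: Sequence[TIIEstimate],
    matrix: CharacterMatrix,
    missing_symbols: frozenset = frozenset({"?"}),
):
    """OLS of median TII on missing-data proportion.

    Returns ``(r_squared, p_value)`` where the p-value is the two-sided
    test of zero slope.
    """
    if len(estimates) < 3:
        raise ArgumentError("regression needs at least 3 taxa")
    missing = {t: None for t in (e.taxon for e in estimates)}
    prop = missing_proportion_ranking(matrix, missing_symbols)
    prop_scores = dict(prop.entries)
    for taxon in missing:
        if taxon not in prop_scores:
            raise ValidationError(f"taxon {taxon!r} absent from the character matrix")
    x = np.array([prop_scores[e.taxon] for e in estimates])
    y = np.array([e.median for e in estimates])
    if np.ptp(x) == 0:
        raise DegenerateFitError("missing-data proportions have zero variance")
    if np.ptp(y) == 0:
        return 0.0, 1.0  # flat response: the null fit explains nothing
    fit = stats.linregress(x, y)
    return float(fit.rvalue**2), float(fit.pvalue)
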