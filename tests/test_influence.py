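"""The taxon influence index: exact double sum, resampler, summaries, ranking."""

import numpy as np
import pytest

import tii
from tii import ArgumentError, DistanceSpec, ValidationError, WeightedTreeSet

from conftest import topo

SPEC = DistanceSpec()
EXACT_SPR = DistanceSpec(metric="spr", spr_mode="exact", exact_max_leaves=9)


@pytest.fixture
def full_five(point_mass):
    return point_mass("((A,B),(C,(D,E)));")


def test_exact_zero_when_pruned_equals_dropped(full_five, point_mass):
    dropped = point_mass("((A,B),(C,D));")
    assert tii.tii_exact(full_five, dropped, "E", SPEC) == 0.0


def test_exact_single_pair(full_five, point_mass):
    dropped = point_mass("((A,C),(B,D));")
    assert tii.tii_exact(full_five, dropped, "E", SPEC) == pytest.approx(1 / 3)


def test_exact_two_term_sum(full_five):
    dropped = WeightedTreeSet(
        topologies=(topo("((A,B),(C,D));"), topo("((A,C),(B,D));")),
        weights=(0.6, 0.4),
    )
    assert tii.tii_exact(full_five, dropped, "E", SPEC) == pytest.approx(0.4 / 3)


def test_exact_invariant_to_duplicate_merging(point_mass):
    # two full-posterior topologies that collapse to one shape after pruning:
    # the merged-weight sum must equal the unmerged two-term sum
    a = topo("((A,B),(C,(D,E)));")
    b = topo("((A,B),(D,(C,E)));")
    full = WeightedTreeSet(topologies=(a, b), weights=(0.7, 0.3))
    dropped = point_mass("((A,C),(B,D));")
    merged = tii.tii_exact(full, dropped, "E", SPEC)
    by_hand = 0.7 * tii.spr_excess(a.prune("E"), dropped.topologies[0]) + 0.3 * (
        tii.spr_excess(b.prune("E"), dropped.topologies[0])
    )
    assert merged == pytest.approx(by_hand)


def test_exact_zero_iff_all_cross_pairs_identical(point_mass):
    full = point_mass("((A,B),(C,(D,E)));")
    same = point_mass("((A,B),(C,D));")
    diff = point_mass("((A,D),(B,C));")
    assert tii.tii_exact(full, same, "E", SPEC) == 0.0
    assert tii.tii_exact(full, diff, "E", SPEC) > 0.0


def test_leaf_set_mismatch_rejected(full_five, point_mass):
    with pytest.raises(ValidationError):
        tii.tii_exact(full_five, point_mass("((A,B),(C,E));"), "E", SPEC)


def test_whole_set_draw_reproduces_exact(full_five):
    dropped = WeightedTreeSet(
        topologies=(topo("((A,B),(C,D));"), topo("((A,C),(B,D));")),
        weights=(0.6, 0.4),
    )
    exact = tii.tii_exact(full_five, dropped, "E", SPEC)
    # pruned full has 1 topology -> m = 1; force whole-set draws instead
    est = tii.tii_resampled(
        full_five, dropped, "E", SPEC, n_iter=25, seed=3, sample_size=2
    )
    assert est.replicates == tuple([exact] * 25)
    assert est.median == pytest.approx(exact)
    assert est.iqr[1] - est.iqr[0] == 0.0


def test_point_mass_replicates_constant(full_five, point_mass):
    dropped = point_mass("((A,C),(B,D));")
    est = tii.tii_resampled(full_five, dropped, "E", SPEC, n_iter=10, seed=0)
    assert est.replicates == pytest.approx(tuple([1 / 3] * 10))


def test_resampler_deterministic_from_seed():
    base = tii.random_topology(9, seed=11)
    full = tii.pseudo_posterior(base, 6, max_moves=2, seed=12)
    taxon = sorted(base.leaf_labels)[0]
    dropped = tii.pseudo_posterior(base.prune(taxon), 5, max_moves=2, seed=13)
    a = tii.tii_resampled(full, dropped, taxon, SPEC, n_iter=20, seed=42)
    b = tii.tii_resampled(full, dropped, taxon, SPEC, n_iter=20, seed=42)
    c = tii.tii_resampled(full, dropped, taxon, SPEC, n_iter=20, seed=43)
    assert a.replicates == b.replicates
    assert a.replicates != c.replicates


def test_uniform_weighting_differs_from_renormalized():
    base = tii.random_topology(9, seed=21)
    full = tii.pseudo_posterior(base, 8, max_moves=2, concentration=0.4, seed=22)
    taxon = sorted(base.leaf_labels)[2]
    dropped = tii.pseudo_posterior(
        base.prune(taxon), 8, max_moves=2, concentration=0.4, seed=23
    )
    ren = tii.tii_resampled(full, dropped, taxon, SPEC, n_iter=15, seed=5, sample_size=4)
    uni = tii.tii_resampled(
        full, dropped, taxon, SPEC, n_iter=15, seed=5, sample_size=4, weighting="uniform"
    )
    assert ren.replicates != uni.replicates


def test_resampler_converges_toward_exact():
    """Mean deviation of the resampled median from the exact double sum
    shrinks as the subsample approaches the whole set."""
    base = tii.random_topology(10, seed=31)
    full = tii.pseudo_posterior(base, 10, max_moves=2, seed=32)
    taxon = sorted(base.leaf_labels)[4]
    dropped = tii.pseudo_posterior(base.prune(taxon), 10, max_moves=2, seed=33)
    exact = tii.tii_exact(full, dropped, taxon, SPEC)
    devs = []
    for m in (2, 5, 10):
        ds = [
            abs(
                tii.tii_resampled(
                    full, dropped, taxon, SPEC, n_iter=30, seed=s, sample_size=m
                ).median
                - exact
            )
            for s in range(3)
        ]
        devs.append(np.mean(ds))
    assert devs[-1] == pytest.approx(0.0, abs=1e-12)
    assert devs[0] >= devs[-1]


def test_monotone_in_planted_displacement():
    """Point-mass posteriors displaced by k exact SPR moves give
    nondecreasing TII in k."""
    base = tii.random_topology(8, seed=41)
    taxon = sorted(base.leaf_labels)[0]
    pruned = base.prune(taxon)
    full = tii.build_posterior([base])
    values = []
    for k in (0, 1, 2, 3):
        center = pruned
        if k:
            rng = np.random.default_rng(50 + k)
            # retry walks until the realized exact distance equals k
            for _ in range(100):
                cand = tii.random_spr_walk(pruned, k, rng)
                if tii.spr_distance(pruned, cand, EXACT_SPR)[0] == k:
                    center = cand
                    break
        dropped = tii.build_posterior([center])
        values.append(tii.tii_exact(full, dropped, taxon, EXACT_SPR))
    assert values == sorted(values)
    assert values[0] == 0.0


def test_flag_outliers():
    assert tii.flag_outliers([1.0] * 10) == ()
    assert tii.flag_outliers([1, 1, 1, 1, 1, 1, 1, 1, 1, 100]) == (9,)
    values = [3, 1, 100, 2, 2, 3, 1, 2]
    flagged = {values[i] for i in tii.flag_outliers(values)}
    shuffled = [2, 100, 1, 3, 2, 1, 3, 2]
    assert {shuffled[i] for i in tii.flag_outliers(shuffled)} == flagged
    with pytest.raises(ArgumentError):
        tii.flag_outliers([1.0, 2.0, 3.0])


def test_rank_taxa_order_and_ties():
    ests = [
        tii.TIIEstimate.from_replicates("X", [0.3] * 4),
        tii.TIIEstimate.from_replicates("Y", [0.1] * 4),
        tii.TIIEstimate.from_replicates("Z", [0.2] * 4),
    ]
    assert tii.rank_taxa(ests).taxa == ("X", "Z", "Y")
    tied = [
        tii.TIIEstimate.from_replicates("X", [0.2] * 4),
        tii.TIIEstimate.from_replicates("A", [0.2] * 4),
    ]
    assert tii.rank_taxa(tied).taxa == ("A", "X")
    single = [tii.TIIEstimate.from_replicates("Q", [0.5] * 4)]
    assert tii.rank_taxa(single).rank_of("Q") == 1
    with pytest.raises(ValidationError):
        tii.rank_taxa(tied + [tii.TIIEstimate.from_replicates("A", [0.0] * 4)])
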