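"""Barcode-gap partitioning and the K/theta species criterion."""

import numpy as np
import pytest

from aylacostoma import (
    AbgdConfig,
    DistanceMatrix,
    abgd_partition,
    abgd_prior_ladder,
    abgd_scan,
    ktheta_test,
    watterson_theta_upper,
)
from aylacostoma.delimitation import DelimitationError

PUBLISHED_LADDER = [
    0.001000, 0.001668, 0.002783, 0.004642, 0.007743,
    0.012915, 0.021544, 0.035938, 0.059948, 0.100000,
]


def test_default_ladder_matches_published_priors():
    ladder = abgd_prior_ladder(AbgdConfig())
    assert [round(p, 6) for p in ladder] == PUBLISHED_LADDER


def test_two_step_ladder_is_endpoints():
    ladder = abgd_prior_ladder(AbgdConfig(steps=2))
    assert list(np.round(ladder, 12)) == [0.001, 0.1]


@pytest.mark.parametrize(
    "kwargs", [dict(p_min=0.1, p_max=0.1), dict(p_min=0.2, p_max=0.1),
               dict(steps=1), dict(relative_gap_width=0)],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(DelimitationError):
        AbgdConfig(**kwargs)


def test_lowest_prior_recovers_the_three_species(paper_dm_k2p, species_groups):
    part = abgd_partition(paper_dm_k2p, prior=0.001)
    expected = {tuple(sorted(ids)) for ids in species_groups.values()}
    assert {g for g in part.groups} == expected


def test_high_prior_merges_the_sister_species(paper_dm_k2p, species_groups):
    """At P = 0.035938 the 0.0219 distance is below the prior and the
    0.0402 -> 0.0449 step is far too narrow to be a barcode gap (relative
    width 0.117 < 1.5), so chloroticum and brunneum merge."""
    part = abgd_partition(paper_dm_k2p, prior=0.035938)
    assert part.n_groups == 2
    sizes = sorted(len(g) for g in part.groups)
    assert sizes == [1, 10]


def test_identical_sequences_are_one_group_at_every_prior():
    dm = DistanceMatrix(tuple("abcd"), np.zeros((4, 4)))
    scan = abgd_scan(dm, AbgdConfig())
    assert {p.n_groups for p in scan.partitions} == {1}


def test_scan_has_exactly_seven_three_group_priors(paper_dm_k2p):
    scan = abgd_scan(paper_dm_k2p, AbgdConfig())
    three = scan.priors_with_n_groups(3)
    assert len(three) == 7
    assert [round(p, 6) for p in three] == PUBLISHED_LADDER[:7]


def test_distance_histogram_is_trimodal(paper_dm_k2p):
    scan = abgd_scan(paper_dm_k2p, AbgdConfig())
    values = np.array(scan.pairwise_distances)
    assert values.size == 55
    assert int((values == 0).sum()) == 24
    assert int(((values > 0.01) & (values < 0.03)).sum()) == 21
    assert int(((values >= 0.040) & (values <= 0.045)).sum()) == 10


def test_partition_invariant_to_id_order_and_scaling(paper_dm_k2p):
    part = abgd_partition(paper_dm_k2p, prior=0.001)
    perm = list(reversed(paper_dm_k2p.ids))
    shuffled = paper_dm_k2p.submatrix(perm)
    assert abgd_partition(shuffled, prior=0.001).groups == part.groups
    scaled = DistanceMatrix(
        paper_dm_k2p.ids, paper_dm_k2p.values * 3.0,
        paper_dm_k2p.model, paper_dm_k2p.deletion,
    )
    assert abgd_partition(scaled, prior=0.003).groups == part.groups


def _random_matrix(rng, n=12):
    v = rng.uniform(0.0, 0.2, size=(n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return DistanceMatrix(tuple(f"s{i:02d}" for i in range(n)), v)


def test_group_count_monotone_in_prior_on_random_matrices():
    rng = np.random.default_rng(99)
    cfg = AbgdConfig()
    for _ in range(10):
        dm = _random_matrix(rng)
        counts = [p.n_groups for p in abgd_scan(dm, cfg).partitions]
        assert counts == sorted(counts, reverse=True)


# -- K/theta ------------------------------------------------------------------


@pytest.mark.parametrize(
    "theta, k, ratio",
    [
        (0.0043165, 0.0219333, 5.08),
        (0.0043165, 0.0402002, 9.31),
        (0.0014333, 0.0448731, 31.31),
    ],
)
def test_published_ratios_with_supplied_theta(paper_dm_k2p, species_groups,
                                              theta, k, ratio):
    """The published table's theta values come from another locus and are
    honoured verbatim through the 'supplied' policy."""
    pairs = {
        0.0219333: ("chloroticum", "brunneum"),
        0.0402002: ("brunneum", "stigmaticum"),
        0.0448731: ("chloroticum", "stigmaticum"),
    }
    g1, g2 = pairs[k]
    res = ktheta_test(
        paper_dm_k2p, species_groups[g1], species_groups[g2],
        theta_policy="supplied", theta=theta,
    )
    assert res.k == pytest.approx(k, abs=5e-7)
    assert round(res.ratio, 2) == ratio
    assert res.decision is True
    assert (res.n1, res.n2) == (len(species_groups[g1]), len(species_groups[g2]))


def test_theta_equal_to_k_is_not_distinct(paper_dm_k2p, species_groups):
    res = ktheta_test(
        paper_dm_k2p, species_groups["chloroticum"], species_groups["brunneum"],
        theta_policy="supplied", theta=0.021933341052790892,
    )
    assert res.ratio == pytest.approx(1.0, rel=1e-6)
    assert res.decision is False


def test_ratio_invariant_under_matrix_rescaling(paper_dm_k2p, species_groups):
    scaled = DistanceMatrix(
        paper_dm_k2p.ids, paper_dm_k2p.values * 7.0,
        paper_dm_k2p.model, paper_dm_k2p.deletion,
    )
    a = ktheta_test(paper_dm_k2p, species_groups["chloroticum"],
                    species_groups["brunneum"], "supplied", theta=0.004)
    b = ktheta_test(scaled, species_groups["chloroticum"],
                    species_groups["brunneum"], "supplied", theta=0.028)
    assert a.ratio == pytest.approx(b.ratio)


def test_zero_variation_clades_need_watterson_or_supplied(paper_dm_k2p, species_groups):
    with pytest.raises(DelimitationError, match="theta unresolved"):
        ktheta_test(paper_dm_k2p, species_groups["chloroticum"],
                    species_groups["brunneum"], theta_policy="max_within")


def test_watterson_upper_bound_policy(paper_dm_k2p, species_groups):
    """3/(a_n L): for n=7, a_7 = H_6 = 2.45; for n=3, a_3 = 1.5; the larger
    clade bound is the looser one, max picks 3/(1.5 * 234)."""
    res = ktheta_test(
        paper_dm_k2p, species_groups["chloroticum"], species_groups["brunneum"],
        theta_policy="watterson_upper", seq_length=234,
    )
    assert res.theta == pytest.approx(3 / (1.5 * 234))
    assert watterson_theta_upper(7, 234) == pytest.approx(3 / (2.45 * 234))


def test_simulated_two_clade_data_with_large_k_declared_distinct():
    """On simulated pairs with K/theta >= 4 by construction the decision
    must be 'distinct' in at least 95% of replicates."""
    rng = np.random.default_rng(123)
    hits = 0
    n_rep = 100
    for _ in range(n_rep):
        # theta 0.004, K = 8*theta on average, two clades of 4
        theta, k_true = 0.004, 0.032
        n = 8
        v = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                same = (i < 4) == (j < 4)
                mean = theta if same else k_true
                v[i, j] = v[j, i] = rng.gamma(20.0, mean / 20.0)
        dm = DistanceMatrix(tuple(f"s{i}" for i in range(n)), v)
        res = ktheta_test(dm, [f"s{i}" for i in range(4)],
                          [f"s{i}" for i in range(4, 8)], "max_within")
        hits += res.decision
    assert hits / n_rep >= 0.95
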