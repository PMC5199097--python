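"""Distance models, matrices, group summaries and the column bootstrap."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aylacostoma import (
    MultipleAlignment,
    SiteDiffSummary,
    bootstrap_se,
    distance_matrix,
    group_summary,
    k2p_distance,
    p_distance,
    pairwise_site_diffs,
)

# K2P values recomputed at high precision from the printed substitution
# counts (9, 10, 5 transitions over 233 shared sites); they agree with the
# published 6-decimal matrix.
D_ST_BR = 0.040200212719018885
D_ST_CH = 0.0448731439281377
D_BR_CH = 0.021933341052790892


@pytest.mark.parametrize(
    "summary, expected",
    [
        (SiteDiffSummary(9, 0, 0, 233), 0.038627),
        (SiteDiffSummary(10, 0, 1, 233), 0.042918),
        (SiteDiffSummary(5, 0, 1, 233), 0.021459),
        (SiteDiffSummary(0, 0, 0, 100), 0.0),
    ],
)
def test_p_distance_published_values(summary, expected):
    assert round(p_distance(summary), 6) == expected


@pytest.mark.parametrize(
    "summary, expected",
    [
        (SiteDiffSummary(9, 0, 0, 233), 0.040200),
        (SiteDiffSummary(10, 0, 1, 233), 0.044873),
        (SiteDiffSummary(5, 0, 1, 233), 0.021933),
    ],
)
def test_k2p_distance_published_values(summary, expected):
    assert round(k2p_distance(summary), 6) == expected


def test_k2p_against_extended_precision_formula():
    """Oracle: direct evaluation of Kimura's formula in exact rational/
    arbitrary precision arithmetic via sympy."""
    import sympy

    P, Q = sympy.Rational(3, 100), sympy.Rational(2, 100)
    expected = float(-sympy.log(1 - 2 * P - Q) / 2 - sympy.log(1 - 2 * Q) / 4)
    got = k2p_distance(SiteDiffSummary(3, 2, 0, 100))
    assert math.isclose(got, expected, rel_tol=1e-12)


def test_k2p_saturation_yields_nan():
    assert math.isnan(k2p_distance(SiteDiffSummary(60, 0, 0, 100)))
    assert math.isnan(k2p_distance(SiteDiffSummary(0, 60, 0, 100)))


@given(
    n=st.integers(10, 2000),
    ts=st.integers(0, 300),
    tv=st.integers(0, 150),
)
@settings(max_examples=200, derandomize=True)
def test_k2p_dominates_p_distance(n, ts, tv):
    """K2P >= p for every non-saturated pattern, equal only at zero."""
    if ts + tv > n or 1 - 2 * ts / n - tv / n <= 0 or 1 - 2 * tv / n <= 0:
        return
    s = SiteDiffSummary(ts, tv, 0, n)
    k, p = k2p_distance(s), p_distance(s)
    if ts + tv == 0:
        assert k == p == 0
    else:
        assert k > p


def test_k2p_transitions_only_closed_form():
    s = SiteDiffSummary(7, 0, 0, 200)
    assert math.isclose(
        k2p_distance(s), -0.5 * math.log(1 - 2 * 7 / 200), rel_tol=1e-12
    )


def test_matrix_symmetric_zero_diagonal(paper_dm_k2p):
    v = paper_dm_k2p.values
    assert np.allclose(v, v.T) and np.all(np.diag(v) == 0)


def test_fixture_matrix_unique_species_level_values(paper_dm_k2p):
    got = sorted({round(x, 6) for x in paper_dm_k2p.pair_values()})
    assert got == [0.0, 0.021933, 0.040200, 0.044873]


def test_complete_deletion_matches_pairwise_on_fixture(paper_alignment):
    """Only the single shared-gap region is removed, so both deletion modes
    see the same 233 comparable sites for every pair."""
    pw = distance_matrix(paper_alignment, "k2p", "pairwise")
    cd = distance_matrix(paper_alignment, "k2p", "complete")
    np.testing.assert_allclose(pw.values, cd.values, atol=1e-15)


def test_distances_invariant_under_sequence_reordering(paper_alignment):
    rev = paper_alignment.subset(list(reversed(paper_alignment.ids)))
    dm1 = distance_matrix(paper_alignment)
    dm2 = distance_matrix(rev)
    for i in paper_alignment.ids:
        for j in paper_alignment.ids:
            assert dm1.get(i, j) == dm2.get(i, j)


def test_distances_invariant_under_column_permutation(paper_alignment):
    rng = np.random.default_rng(1)
    perm = rng.permutation(paper_alignment.length)
    shuffled = MultipleAlignment.from_array(
        paper_alignment.ids, paper_alignment.array[:, perm]
    )
    np.testing.assert_allclose(
        distance_matrix(shuffled).values, distance_matrix(paper_alignment).values
    )


def test_tsv_round_trip(paper_dm_k2p, tmp_path):
    path = tmp_path / "dm.tsv"
    paper_dm_k2p.to_tsv(path)
    back = type(paper_dm_k2p).from_tsv(path)
    assert back.ids == paper_dm_k2p.ids
    np.testing.assert_allclose(back.values, paper_dm_k2p.values, atol=5e-7)


# -- group summaries ----------------------------------------------------------


def test_species_group_summary(paper_dm_k2p, species_groups):
    summ = group_summary(paper_dm_k2p, species_groups)
    assert summ.d_within["stigmaticum"] is None  # singleton: undefined, not 0
    assert summ.d_within["brunneum"] == 0.0
    assert summ.d_within["chloroticum"] == 0.0
    assert round(summ.d_between[("brunneum", "chloroticum")], 6) == 0.021933


def test_net_divergence_outer_split(paper_dm_k2p, species_groups):
    """Brute-force oracle: averages of the three distinct pairwise values
    over the 10 cross pairs and 45 within pairs."""
    groups = {
        "X": species_groups["stigmaticum"],
        "Y": species_groups["brunneum"] + species_groups["chloroticum"],
    }
    summ = group_summary(paper_dm_k2p, groups)
    dxy_expected = (3 * D_ST_BR + 7 * D_ST_CH) / 10
    dy_expected = 21 * D_BR_CH / 45
    assert math.isclose(summ.d_between[("X", "Y")], dxy_expected, rel_tol=1e-9)
    assert math.isclose(summ.d_within["Y"], dy_expected, rel_tol=1e-9)
    assert math.isclose(
        summ.da[("X", "Y")], dxy_expected - dy_expected / 2, rel_tol=1e-9
    )
    assert round(summ.da[("X", "Y")], 7) == 0.0383535


def test_da_invariant_definition(paper_dm_k2p, species_groups):
    summ = group_summary(paper_dm_k2p, species_groups)
    for (g1, g2), da in summ.da.items():
        w1 = summ.d_within[g1] or 0.0
        w2 = summ.d_within[g2] or 0.0
        assert math.isclose(da, summ.d_between[(g1, g2)] - (w1 + w2) / 2)
        assert da >= 0


def test_single_group_has_no_between_distances(paper_dm_k2p, paper_alignment):
    summ = group_summary(paper_dm_k2p, {"all": paper_alignment.ids})
    assert summ.d_between == {} and summ.da == {}


def test_borrow_sister_policy(paper_dm_k2p, species_groups):
    z = group_summary(paper_dm_k2p, species_groups, "singleton_zero")
    b = group_summary(paper_dm_k2p, species_groups, "borrow_sister")
    key = ("brunneum", "stigmaticum")
    # brunneum within-mean is 0, so borrowing changes nothing here
    assert z.da[key] == b.da[key]


# -- column bootstrap ---------------------------------------------------------


def test_bootstrap_se_of_constant_statistic_is_zero(paper_alignment):
    se, vals = bootstrap_se(paper_alignment, lambda a: 1.0, replicates=50, seed=0)
    assert se == 0.0 and len(vals) == 50


def test_bootstrap_se_matches_delta_method(paper_alignment, species_reps):
    """For K2P on 9 transitions / 233 sites the binomial delta method gives
    SE = sqrt(P(1-P)/n) / (1-2P); the column bootstrap must land within 15%."""
    st_, br = species_reps["stigmaticum"], species_reps["brunneum"]

    def stat(a):
        return k2p_distance(pairwise_site_diffs(a, st_, br))

    se, _ = bootstrap_se(paper_alignment, stat, replicates=1000, seed=11)
    P = 9 / 233
    delta = math.sqrt(P * (1 - P) / 233) / (1 - 2 * P)
    assert abs(se / delta - 1) < 0.15


def test_bootstrap_se_scales_with_inverse_sqrt_length(paper_alignment, species_reps):
    st_, br = species_reps["stigmaticum"], species_reps["brunneum"]

    def stat(a):
        return k2p_distance(pairwise_site_diffs(a, st_, br))

    doubled = MultipleAlignment.from_array(
        paper_alignment.ids,
        np.hstack([paper_alignment.array, paper_alignment.array]),
    )
    se1, _ = bootstrap_se(paper_alignment, stat, replicates=1000, seed=2)
    se2, _ = bootstrap_se(doubled, stat, replicates=1000, seed=3)
    assert abs(se2 / se1 - 1 / math.sqrt(2)) < 0.1 / math.sqrt(2)


def test_bootstrap_reproducible_under_seed(paper_alignment, species_reps):
    st_, ch = species_reps["stigmaticum"], species_reps["chloroticum"]

    def stat(a):
        return k2p_distance(pairwise_site_diffs(a, st_, ch))

    se_a, vals_a = bootstrap_se(paper_alignment, stat, replicates=100, seed=9)
    se_b, vals_b = bootstrap_se(paper_alignment, stat, replicates=100, seed=9)
    assert se_a == se_b and np.array_equal(vals_a, vals_b)
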