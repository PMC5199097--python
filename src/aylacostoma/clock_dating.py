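"""Clock testing and net-divergence dating.

Tajima's non-parametric relative rate test compares, for two ingroup taxa
against an outgroup, the counts of sites where each ingroup sequence alone
carries a unique state.  Under clock-like evolution the two counts m1, m2
are binomial(m1+m2, 1/2), and (m1-m2)^2/(m1+m2) is approximately
chi-square with 1 degree of freedom.

Divergence dating follows the net-divergence approach T = Da / 2mu, where
Da = dXY - (dX + dY)/2 is the net nucleotide divergence between groups
(K2P, pairwise deletion) and 2mu the divergence rate in
substitutions/site/Myr.  The standard error of Da comes from column
bootstrapping and the 95% CI is Da +/- 1.96 SE, converted to Myr.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
from scipy import stats

from .alignment_io import MultipleAlignment, _GAP_CODE
from .distances import bootstrap_se, distance_matrix, group_summary
from .nj_tree import PhyloTree


@dataclasses.dataclass(frozen=True)
class RateTestResult:
    """Tajima relative rate test: unique-state counts and chi-square."""

    m1: int
    m2: int
    chi_square: float
    p_value: float


def tajima_rrt(
    aln: MultipleAlignment, taxon1: str, taxon2: str, outgroup: str
) -> RateTestResult:
    """Tajima's relative rate test for two ingroup taxa and an outgroup.

    Sites with a gap in any of the three sequences are excluded.  m1 counts
    sites where taxon1 differs while taxon2 agrees with the outgroup; m2 is
    symmetric.  No continuity correction is applied.
    """
    x1, x2, xo = aln.row(taxon1), aln.row(taxon2), aln.row(outgroup)
    ok = (x1 != _GAP_CODE) & (x2 != _GAP_CODE) & (xo != _GAP_CODE)
    m1 = int(((x1 != x2) & (x2 == xo) & ok).sum())
    m2 = int(((x2 != x1) & (x1 == xo) & ok).sum())
    total = m1 + m2
    if total == 0:
        return RateTestResult(0, 0, 0.0, 1.0)
    chi = (m1 - m2) ** 2 / total
    return RateTestResult(m1, m2, float(chi), float(stats.chi2.sf(chi, df=1)))


@dataclasses.dataclass(frozen=True)
class DatingEstimate:
    """Net divergence Da with bootstrap SE and the implied time in Myr."""

    da: float
    se: float
    rate_2mu: float
    time: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.rate_2mu <= 0:
            raise ValueError("rate_2mu must be positive")


def _estimate_from(da: float, se: float, rate_2mu: float) -> DatingEstimate:
    return DatingEstimate(
        da=da,
        se=se,
        rate_2mu=rate_2mu,
        time=da / rate_2mu,
        ci_low=(da - 1.96 * se) / rate_2mu,
        ci_high=(da + 1.96 * se) / rate_2mu,
    )


def net_divergence_time(
    aln: MultipleAlignment,
    group_x: Sequence[str],
    group_y: Sequence[str],
    rate_2mu: float = 0.006,
    replicates: int = 1000,
    seed: int | None = None,
    singleton_policy: str = "singleton_zero",
) -> DatingEstimate:
    """Date the split between two groups of sequences.

    Da uses K2P distances with pairwise deletion; its SE comes from
    ``replicates`` column-bootstrap resamples of the alignment restricted
    to the two groups (``replicates=0`` skips the bootstrap, SE = 0; a
    seed is required whenever the bootstrap runs).
    """
    group_x, group_y = tuple(group_x), tuple(group_y)
    if not group_x or not group_y:
        raise ValueError("both groups must be non-empty")
    if set(group_x) & set(group_y):
        raise ValueError("groups must be disjoint")
    sub = aln.subset(group_x + group_y)
    groups = {"X": group_x, "Y": group_y}

    def da_stat(a: MultipleAlignment) -> float:
        dm = distance_matrix(a, model="k2p", deletion="pairwise")
        return group_summary(dm, groups, singleton_policy).da[("X", "Y")]

    da = da_stat(sub)
    if replicates > 0:
        if seed is None:
            raise ValueError("seed is required for the bootstrap")
        se, _ = bootstrap_se(sub, da_stat, replicates, seed)
    else:
        se = 0.0
    return _estimate_from(da, se, rate_2mu)


def date_all_splits(
    aln: MultipleAlignment,
    groups: Mapping[str, Sequence[str]],
    guide_tree: PhyloTree | str,
    rate_2mu: float = 0.006,
    replicates: int = 1000,
    seed: int | None = None,
    singleton_policy: str = "singleton_zero",
) -> list[tuple[str, DatingEstimate]]:
    """One dating estimate per internal split of a rooted guide tree.

    The guide tree's leaf labels are *group names*; at each internal node
    the two child clades define the groups X (union of ids on one side)
    and Y (union on the other).  Rows are returned in preorder, so the
    outermost split comes first.
    """
    if isinstance(guide_tree, str):
        guide_tree = PhyloTree.from_newick(guide_tree)
    leaf_names = set(guide_tree.leaf_ids)
    unknown = leaf_names - set(groups)
    if unknown:
        raise ValueError(f"guide tree names not in groups: {sorted(unknown)}")

    def clade_ids(node) -> tuple[tuple[str, ...], tuple[str, ...]]:
        names = sorted(l.taxon.label for l in node.leaf_iter())
        ids = tuple(i for name in names for i in groups[name])
        return tuple(names), ids

    results: list[tuple[str, DatingEstimate]] = []
    k = 0
    for node in guide_tree.tree.preorder_node_iter():
        children = node.child_nodes()
        if len(children) < 2:
            continue
        names_x, ids_x = clade_ids(children[0])
        names_y, ids_y = clade_ids(children[1])
        label = "+".join(names_x) + " | " + "+".join(names_y)
        rep_seed = None if seed is None else seed + k
        results.append(
            (
                label,
                net_divergence_time(
                    aln, ids_x, ids_y, rate_2mu, replicates, rep_seed,
                    singleton_policy,
                ),
            )
        )
        k += 1
    return results
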