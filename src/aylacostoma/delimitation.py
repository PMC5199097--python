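"""Species-boundary inference: barcode-gap partitioning and the K/theta test.

Two single-locus criteria are implemented.

*Barcode-gap partitioning* is a deliberately simplified, fully specified
variant of Automatic Barcode Gap Discovery (ABGD): distinct pairwise
distances are sorted; among distances at or above the prior maximum
intraspecific divergence P, the first consecutive pair (d_i, d_{i+1}) with
d_{i+1} - d_i > X * d_i marks the barcode gap and d_i becomes the
clustering threshold (falling back to P itself when no such gap exists);
groups are the connected components of the graph joining pairs at distance
<= threshold, refined recursively within groups until stable.  The prior
is scanned over a geometric ladder, as in the original method.

The *K/theta* test applies the Evolutionary Genetic Species Concept
decision rule: two sister clades with mean between-clade distance K and
within-clade diversity theta are distinct species (with probability
>= 0.95) when K/theta >= 4.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from collections.abc import Sequence

import numpy as np

from .distances import DistanceMatrix


class DelimitationError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class AbgdConfig:
    """Prior ladder and gap-width settings for barcode-gap partitioning."""

    p_min: float = 0.001
    p_max: float = 0.1
    steps: int = 10
    relative_gap_width: float = 1.5

    def __post_init__(self) -> None:
        if not (0 < self.p_min < self.p_max):
            raise DelimitationError("need 0 < p_min < p_max")
        if self.steps < 2:
            raise DelimitationError("need steps >= 2")
        if self.relative_gap_width <= 0:
            raise DelimitationError("relative gap width must be positive")


def abgd_prior_ladder(cfg: AbgdConfig) -> np.ndarray:
    """Geometric series of priors from p_min to p_max inclusive."""
    return np.geomspace(cfg.p_min, cfg.p_max, cfg.steps)


@dataclasses.dataclass(frozen=True)
class Partition:
    """Assignment of sequence IDs to groups at one prior value."""

    prior: float
    groups: tuple[tuple[str, ...], ...]
    stable: bool  # top-level split unchanged by recursive refinement

    @property
    def n_groups(self) -> int:
        return len(self.groups)


def _gap_threshold(values: Sequence[float], prior: float, x: float) -> float:
    """First significant barcode gap at or above the prior, else the prior."""
    cand = sorted({v for v in values if v >= prior})
    for a, b in zip(cand, cand[1:]):
        if b - a > x * a:
            return a
    return prior


def _components(ids: Sequence[str], dm: DistanceMatrix, threshold: float) -> list[list[str]]:
    # union-find over edges with distance <= threshold
    parent = {i: i for i in ids}

    def find(a: str) -> str:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in itertools.combinations(ids, 2):
        if dm.get(a, b) <= threshold:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    comps: dict[str, list[str]] = {}
    for i in ids:
        comps.setdefault(find(i), []).append(i)
    return sorted(comps.values(), key=lambda c: c[0])


def _partition_ids(
    ids: Sequence[str], dm: DistanceMatrix, prior: float, x: float
) -> list[list[str]]:
    if len(ids) == 1:
        return [list(ids)]
    values = [dm.get(a, b) for a, b in itertools.combinations(ids, 2)]
    threshold = _gap_threshold(values, prior, x)
    comps = _components(ids, dm, threshold)
    if len(comps) == 1:
        return comps
    return [
        grp for comp in comps for grp in _partition_ids(comp, dm, prior, x)
    ]


def abgd_partition(
    dm: DistanceMatrix, prior: float, relative_gap_width: float = 1.5
) -> Partition:
    """Partition a distance matrix at one prior value (with recursion)."""
    if prior <= 0:
        raise DelimitationError("prior must be positive")
    top_values = dm.pair_values()
    top_threshold = _gap_threshold(top_values, prior, relative_gap_width)
    top = _components(dm.ids, dm, top_threshold)
    final = _partition_ids(dm.ids, dm, prior, relative_gap_width)
    groups = tuple(tuple(sorted(g)) for g in final)
    groups = tuple(sorted(groups, key=lambda g: g[0]))
    stable = len(top) == len(final)
    return Partition(prior=prior, groups=groups, stable=stable)


@dataclasses.dataclass(frozen=True)
class AbgdScan:
    """Partitions across the prior ladder plus the distance histogram."""

    partitions: tuple[Partition, ...]
    pairwise_distances: tuple[float, ...]
    histogram_bins: tuple[float, ...]
    histogram_counts: tuple[int, ...]

    def priors_with_n_groups(self, n: int) -> list[float]:
        return [p.prior for p in self.partitions if p.n_groups == n]


def abgd_scan(dm: DistanceMatrix, cfg: AbgdConfig, bin_width: float = 0.005) -> AbgdScan:
    """Run the partitioner at every ladder prior and bin all pair distances."""
    ladder = abgd_prior_ladder(cfg)
    partitions = tuple(
        abgd_partition(dm, float(p), cfg.relative_gap_width) for p in ladder
    )
    values = dm.pair_values()
    top = max(values) if values else 0.0
    n_bins = max(1, int(math.ceil((top + 1e-12) / bin_width)))
    counts, edges = np.histogram(values, bins=n_bins, range=(0.0, n_bins * bin_width))
    return AbgdScan(
        partitions=partitions,
        pairwise_distances=tuple(values),
        histogram_bins=tuple(float(e) for e in edges),
        histogram_counts=tuple(int(c) for c in counts),
    )


# -- K/theta ------------------------------------------------------------------

THETA_POLICIES = ("supplied", "max_within", "watterson_upper")


@dataclasses.dataclass(frozen=True)
class KThetaResult:
    """K/theta ratio and the distinct-species decision for one clade pair."""

    theta: float
    k: float
    ratio: float
    n1: int
    n2: int
    theta_policy: str
    decision: bool  # True: distinct species (ratio >= 4)


def _mean_within(dm: DistanceMatrix, ids: Sequence[str]) -> float | None:
    if len(ids) < 2:
        return None
    return float(
        np.mean([dm.get(a, b) for a, b in itertools.combinations(ids, 2)])
    )


def watterson_theta_upper(n: int, seq_length: int) -> float:
    """Upper bound on theta for a zero-variation clade: 3 / (a_n * L),
    with a_n = sum_{i=1}^{n-1} 1/i (requires n >= 2)."""
    if n < 2:
        raise DelimitationError("Watterson upper bound needs clade size >= 2")
    a_n = sum(1.0 / i for i in range(1, n))
    return 3.0 / (a_n * seq_length)


def ktheta_test(
    dm: DistanceMatrix,
    clade_a: Sequence[str],
    clade_b: Sequence[str],
    theta_policy: str = "max_within",
    theta: float | None = None,
    seq_length: int | None = None,
) -> KThetaResult:
    """Evolutionary-genetic-species test: distinct when K/theta >= 4.

    K is the mean pairwise distance across the two clades.  theta comes
    from the chosen policy: ``supplied`` (an explicit value, e.g. taken
    from another locus), ``max_within`` (the larger of the two within-clade
    means), or ``watterson_upper`` (for zero-variation clades, the upper
    bound 3/(a_n L)).  theta must resolve to a positive value.
    """
    clade_a, clade_b = tuple(clade_a), tuple(clade_b)
    if set(clade_a) & set(clade_b):
        raise DelimitationError("clades must be disjoint")
    if not clade_a or not clade_b:
        raise DelimitationError("clades must be non-empty")
    if theta_policy not in THETA_POLICIES:
        raise DelimitationError(f"unknown theta policy {theta_policy!r}")
    k = float(np.mean([dm.get(a, b) for a in clade_a for b in clade_b]))

    if theta_policy == "supplied":
        if theta is None:
            raise DelimitationError("policy 'supplied' needs an explicit theta")
        theta_val = theta
    else:
        withins = [_mean_within(dm, clade_a), _mean_within(dm, clade_b)]
        if theta_policy == "watterson_upper":
            if seq_length is None:
                raise DelimitationError("policy 'watterson_upper' needs seq_length")
            sizes = (len(clade_a), len(clade_b))
            withins = [
                (w if w else (watterson_theta_upper(n, seq_length) if n >= 2 else None))
                for w, n in zip(withins, sizes)
            ]
        candidates = [w for w in withins if w is not None and w > 0]
        if not candidates:
            raise DelimitationError(
                "theta unresolved: no positive within-clade diversity under "
                f"policy {theta_policy!r}"
            )
        theta_val = max(candidates)
    if theta_val <= 0:
        raise DelimitationError("theta unresolved: must be strictly positive")
    ratio = k / theta_val
    return KThetaResult(
        theta=theta_val,
        k=k,
        ratio=ratio,
        n1=len(clade_a),
        n2=len(clade_b),
        theta_policy=theta_policy,
        decision=ratio >= 4.0,
    )
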