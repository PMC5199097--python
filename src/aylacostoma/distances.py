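"""Pairwise genetic distances, group summaries and column-bootstrap errors.

Two models are implemented: the uncorrected proportion of differing sites
(*p*) and Kimura's two-parameter correction (K2P), which distinguishes the
transition proportion P from the transversion proportion Q:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Gap handling follows MEGA's conventions: *pairwise deletion* drops, for
each pair separately, columns gapped in either member; *complete deletion*
first removes every column containing any gap.  Distances are kept at full
precision internally and rounded (6 decimals) only when written.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from collections.abc import Callable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment_io import (
    MultipleAlignment,
    SiteDiffSummary,
    _GAP_CODE,
    pairwise_site_diffs,
)

MODELS = ("p", "k2p")
DELETION_MODES = ("pairwise", "complete")
SINGLETON_POLICIES = ("singleton_zero", "borrow_sister")


class SaturationError(ValueError):
    """K2P logarithm argument non-positive: divergence beyond correction."""


def p_distance(summary: SiteDiffSummary) -> float:
    """Uncorrected distance: mismatches over compared (gap-free) sites."""
    if summary.compared_sites <= 0:
        raise ValueError("no comparable sites")
    return summary.nucleotide_differences / summary.compared_sites


def k2p_distance(summary: SiteDiffSummary) -> float:
    """Kimura two-parameter distance; NaN (with no exception) on saturation.

    Saturation means 1 - 2P - Q <= 0 or 1 - 2Q <= 0, where the corrected
    distance is undefined; callers that need hard failure (matrix
    construction) convert the NaN into :class:`SaturationError`.
    """
    if summary.compared_sites <= 0:
        raise ValueError("no comparable sites")
    P = summary.transitions / summary.compared_sites
    Q = summary.transversions / summary.compared_sites
    a, b = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if a <= 0.0 or b <= 0.0:
        return math.nan
    return -0.5 * math.log(a) - 0.25 * math.log(b) + 0.0  # +0.0 avoids -0.0


@dataclasses.dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with model/deletion provenance."""

    ids: tuple[str, ...]
    values: np.ndarray
    model: str = "k2p"
    deletion: str = "pairwise"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.isfinite(values).all():
            raise ValueError("distance matrix contains non-finite entries")
        if (values < 0).any():
            raise ValueError("distances must be non-negative")
        if not np.allclose(values, values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.abs(np.diag(values)).max(initial=0.0) > 0:
            raise ValueError("distance matrix diagonal must be zero")
        values = values.copy()
        values.setflags(write=False)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "ids", tuple(self.ids))

    def get(self, id1: str, id2: str) -> float:
        i, j = self.ids.index(id1), self.ids.index(id2)
        return float(self.values[i, j])

    def pair_values(self) -> list[float]:
        """All n(n-1)/2 off-diagonal values (one per unordered pair)."""
        iu = np.triu_indices(len(self.ids), k=1)
        return [float(v) for v in self.values[iu]]

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(
            tuple(ids), self.values[np.ix_(idx, idx)], self.model, self.deletion
        )

    # -- serialisation --------------------------------------------------------

    def to_tsv(self, path, lower_triangle: bool = False) -> None:
        with open(path, "w") as fh:
            fh.write("id\t" + "\t".join(self.ids) + "\n")
            for i, rid in enumerate(self.ids):
                cells = []
                for j in range(len(self.ids)):
                    if lower_triangle and j >= i:
                        cells.append("")
                    else:
                        cells.append(f"{self.values[i, j]:.6f}")
                fh.write(rid + "\t" + "\t".join(cells) + "\n")

    @classmethod
    def from_tsv(cls, path, model: str = "k2p", deletion: str = "pairwise") -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        ids = tuple(str(i) for i in df.index)
        if tuple(df.columns) != ids:
            raise ValueError(f"{path}: row and column ids differ (not a square matrix)")
        return cls(ids, df.to_numpy(dtype=float), model, deletion)

    def to_phylip(self, path) -> None:
        """Relaxed square PHYLIP (name <TAB> values)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, rid in enumerate(self.ids):
                fh.write(rid + "\t" + "\t".join(f"{v:.6f}" for v in self.values[i]) + "\n")


def _strip_gap_columns(aln: MultipleAlignment) -> MultipleAlignment:
    keep = ~(aln.array == _GAP_CODE).any(axis=0)
    if not keep.any():
        raise ValueError("complete deletion removed every column")
    return MultipleAlignment.from_array(aln.ids, aln.array[:, keep])


def distance_matrix(
    aln: MultipleAlignment, model: str = "k2p", deletion: str = "pairwise"
) -> DistanceMatrix:
    """Distance matrix over all unordered sequence pairs."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if deletion not in DELETION_MODES:
        raise ValueError(f"unknown deletion mode {deletion!r}")
    if len(aln) < 2:
        raise ValueError("need at least two sequences")
    work = _strip_gap_columns(aln) if deletion == "complete" else aln
    n = len(aln)
    values = np.zeros((n, n))
    dist = p_distance if model == "p" else k2p_distance
    for i, j in itertools.combinations(range(n), 2):
        s = pairwise_site_diffs(work, aln.ids[i], aln.ids[j])
        d = dist(s)
        if math.isnan(d):
            raise SaturationError(
                f"K2P saturated for pair ({aln.ids[i]!r}, {aln.ids[j]!r}): "
                f"P={s.transitions}/{s.compared_sites}, Q={s.transversions}/{s.compared_sites}"
            )
        values[i, j] = values[j, i] = d
    return DistanceMatrix(aln.ids, values, model, deletion)


# -- group summaries ----------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class GroupDistanceSummary:
    """Within/between-group mean distances and net divergence Da.

    ``d_within`` is None for singleton groups (a mean over zero pairs is
    undefined, not 0); the singleton policy chosen for Da is recorded.
    Da(X,Y) = dXY - (dX + dY)/2.
    """

    d_within: dict[str, float | None]
    d_between: dict[tuple[str, str], float]
    da: dict[tuple[str, str], float]
    singleton_policy: str


def _pair_key(g1: str, g2: str) -> tuple[str, str]:
    return (g1, g2) if g1 <= g2 else (g2, g1)


def group_summary(
    dm: DistanceMatrix,
    groups: Mapping[str, Sequence[str]],
    singleton_policy: str = "singleton_zero",
) -> GroupDistanceSummary:
    """Mean within-group, between-group and net divergences from a matrix.

    ``singleton_zero`` treats a singleton group's (undefined) within-mean
    as 0 in Da; ``borrow_sister`` substitutes the partner group's
    within-mean instead.
    """
    if singleton_policy not in SINGLETON_POLICIES:
        raise ValueError(f"unknown singleton policy {singleton_policy!r}")
    covered = [i for ids in groups.values() for i in ids]
    if len(covered) != len(set(covered)):
        raise ValueError("groups overlap")
    missing = set(dm.ids) - set(covered)
    if missing:
        raise ValueError(f"groups do not cover matrix ids: {sorted(missing)}")

    idx = {rid: k for k, rid in enumerate(dm.ids)}
    d_within: dict[str, float | None] = {}
    for g, ids in groups.items():
        if len(ids) < 1:
            raise ValueError(f"group {g!r} is empty")
        if len(ids) == 1:
            d_within[g] = None
        else:
            pairs = [
                dm.values[idx[a], idx[b]] for a, b in itertools.combinations(ids, 2)
            ]
            d_within[g] = float(np.mean(pairs))

    d_between: dict[tuple[str, str], float] = {}
    da: dict[tuple[str, str], float] = {}
    for g1, g2 in itertools.combinations(groups, 2):
        cross = [
            dm.values[idx[a], idx[b]] for a in groups[g1] for b in groups[g2]
        ]
        key = _pair_key(g1, g2)
        dxy = float(np.mean(cross))
        d_between[key] = dxy
        w1, w2 = d_within[g1], d_within[g2]
        if singleton_policy == "borrow_sister":
            w1_eff = w1 if w1 is not None else (w2 if w2 is not None else 0.0)
            w2_eff = w2 if w2 is not None else (w1 if w1 is not None else 0.0)
        else:
            w1_eff = 0.0 if w1 is None else w1
            w2_eff = 0.0 if w2 is None else w2
        da[key] = dxy - (w1_eff + w2_eff) / 2.0
    return GroupDistanceSummary(d_within, d_between, da, singleton_policy)


# -- column bootstrap ---------------------------------------------------------


def bootstrap_se(
    aln: MultipleAlignment,
    statistic: Callable[[MultipleAlignment], float],
    replicates: int,
    seed: int,
) -> tuple[float, np.ndarray]:
    """Standard error of an alignment statistic under column resampling.

    Each replicate draws ``length`` columns with replacement from the full
    alignment and re-evaluates ``statistic``; the SE is the sample standard
    deviation across replicates.  A seed is mandatory for reproducibility.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    arr = aln.array
    length = aln.length
    vals = np.empty(replicates)
    for r in range(replicates):
        cols = rng.integers(0, length, size=length)
        vals[r] = statistic(MultipleAlignment.from_array(aln.ids, arr[:, cols]))
    se = float(vals.std(ddof=1)) if replicates > 1 else 0.0
    return se, vals
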