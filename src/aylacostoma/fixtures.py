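"""Deterministic study fixtures: the published-table alignment and clock simulations.

Two generators live here.

``build_paper_alignment`` reconstructs, exactly, the 11-sequence / 234-column
ingroup alignment of the three High Parana *Aylacostoma* species
(*A. stigmaticum*, *A. brunneum*, *A. chloroticum*) that is implied by the
published polymorphic-site table (13 variable columns with per-species
states and one gap), the per-species base-composition table, and the sample
sizes (1/3/7).  Invariant columns are never printed in such tables, but
every statistic in this pipeline depends only on their base *counts*, which
are uniquely determined by subtracting each species' polymorphic-site
states from its composition totals.  The generator therefore lays down the
unique invariant background multiset (A=78, C=28, G=36, T=79) in a
seed-shuffled order — different seeds give alignments identical up to a
permutation of invariant columns, with identical downstream distances.

``simulate_clock_alignment`` evolves sequences on a 3-taxon strictly
clock-like tree ((A,B),C) under the Kimura two-parameter model, for
parameter-recovery and test-calibration experiments: the expected K2P
distance between tips that split t Myr ago is ``rate_2mu * t``.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Mapping

import numpy as np

from .alignment_io import MultipleAlignment

SPECIES = ("stigmaticum", "brunneum", "chloroticum")

#: GenBank accessions of the sequenced specimens, per species.
ACCESSIONS: dict[str, tuple[str, ...]] = {
    "stigmaticum": ("KU168372",),
    "brunneum": ("KU168373", "KU168374", "KU168375"),
    "chloroticum": tuple(f"KU1683{n}" for n in range(76, 83)),
}

#: Published polymorphic columns (1-based) -> state per species, in
#: SPECIES order.  "-" is an alignment gap.
POLYMORPHIC_COLUMNS: dict[int, tuple[str, str, str]] = {
    27: ("C", "C", "T"),
    28: ("A", "G", "G"),
    42: ("A", "A", "G"),
    67: ("T", "C", "T"),
    68: ("G", "A", "G"),
    102: ("C", "T", "T"),
    104: ("G", "G", "A"),
    123: ("C", "T", "T"),
    163: ("C", "T", "T"),
    164: ("C", "T", "T"),
    177: ("A", "G", "G"),
    214: ("G", "A", "A"),
    225: ("-", "-", "T"),
}

#: Published per-species base totals over the ungapped sequence.
COMPOSITION_TOTALS: dict[str, dict[str, int]] = {
    "stigmaticum": {"A": 81, "C": 33, "G": 39, "T": 80},
    "brunneum": {"A": 81, "C": 30, "G": 39, "T": 83},
    "chloroticum": {"A": 80, "C": 28, "G": 40, "T": 86},
}


class FixtureError(ValueError):
    """Raised when a fixture specification is internally inconsistent."""


@dataclasses.dataclass(frozen=True)
class PaperFixtureSpec:
    """Specification of the published-table alignment reconstruction."""

    n_columns: int = 234
    polymorphic_columns: Mapping[int, tuple[str, str, str]] = dataclasses.field(
        default_factory=lambda: dict(POLYMORPHIC_COLUMNS)
    )
    species_counts: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"stigmaticum": 1, "brunneum": 3, "chloroticum": 7}
    )
    background_counts: Mapping[str, int] = dataclasses.field(
        default_factory=lambda: {"A": 78, "C": 28, "G": 36, "T": 79}
    )
    composition_totals: Mapping[str, Mapping[str, int]] = dataclasses.field(
        default_factory=lambda: {s: dict(c) for s, c in COMPOSITION_TOTALS.items()}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        cols = self.polymorphic_columns
        if len(cols) != 13:
            raise FixtureError(f"expected 13 polymorphic columns, got {len(cols)}")
        if not all(1 <= c <= self.n_columns for c in cols):
            raise FixtureError("polymorphic column outside the alignment")
        bg_total = sum(self.background_counts.values())
        if bg_total != self.n_columns - len(cols):
            raise FixtureError(
                f"background counts sum to {bg_total}, expected "
                f"{self.n_columns - len(cols)}"
            )
        # The background multiset must be the (unique) solution consistent
        # with every species' composition totals; verify rather than trust.
        for k, sp in enumerate(SPECIES):
            poly = {"A": 0, "C": 0, "G": 0, "T": 0}
            for states in cols.values():
                st = states[k]
                if st != "-":
                    poly[st] += 1
            for base in "ACGT":
                expected = self.composition_totals[sp][base]
                got = self.background_counts[base] + poly[base]
                if got != expected:
                    raise FixtureError(
                        f"composition inconsistent for species {sp!r}: "
                        f"background + polymorphic states give {base}={got}, "
                        f"composition table says {expected}"
                    )


def build_paper_alignment(spec: PaperFixtureSpec | None = None) -> MultipleAlignment:
    """Reconstruct the 11 x 234 ingroup alignment from the printed tables.

    Sequence IDs are ``species_accession`` (e.g. ``stigmaticum_KU168372``);
    within each species all sequences are identical (each species carries a
    single haplotype).
    """
    spec = spec or PaperFixtureSpec()
    rng = np.random.default_rng(spec.seed)
    background = [
        base for base in "ACGT" for _ in range(spec.background_counts[base])
    ]
    background = [background[i] for i in rng.permutation(len(background))]

    invariant_cols = sorted(
        set(range(1, spec.n_columns + 1)) - set(spec.polymorphic_columns)
    )
    template = [""] * spec.n_columns
    for col, base in zip(invariant_cols, background):
        template[col - 1] = base

    records: list[tuple[str, str]] = []
    for k, sp in enumerate(SPECIES):
        seq = template[:]
        for col, states in spec.polymorphic_columns.items():
            seq[col - 1] = states[k]
        hap = "".join(seq)
        accessions = ACCESSIONS[sp]
        n = spec.species_counts[sp]
        if len(accessions) != n:
            raise FixtureError(f"species {sp!r}: {n} sequences but {len(accessions)} accessions")
        for acc in accessions:
            records.append((f"{sp}_{acc}", hap))
    return MultipleAlignment(records)


def paper_groups(spec: PaperFixtureSpec | None = None) -> dict[str, tuple[str, ...]]:
    """Species-level group assignment matching build_paper_alignment IDs."""
    spec = spec or PaperFixtureSpec()
    return {
        sp: tuple(f"{sp}_{acc}" for acc in ACCESSIONS[sp]) for sp in SPECIES
    }


# -- clock-like K2P simulation ------------------------------------------------

# transition partner (A<->G, C<->T) and the two transversion targets per base
_TS_PARTNER = np.array([2, 3, 0, 1], dtype=np.uint8)
_TV_FIRST = np.array([1, 0, 1, 0], dtype=np.uint8)
_TV_SECOND = np.array([3, 2, 3, 2], dtype=np.uint8)


@dataclasses.dataclass(frozen=True)
class ClockSimSpec:
    """Three-taxon clock simulation ((A,B):inner, C):outer.

    ``inner`` and ``outer`` are node ages in Myr; ``rate_2mu`` is the
    *divergence* rate in substitutions/site/Myr (i.e. twice the per-lineage
    rate), default 0.006 as used for gastropod mitochondrial rRNA;
    ``ts_tv_ratio`` is the expected transition/transversion ratio.
    """

    inner: float = 3.75
    outer: float = 6.57
    rate_2mu: float = 0.006
    length: int = 1000
    ts_tv_ratio: float = 10.0
    seqs_per_tip: tuple[int, int, int] = (1, 1, 1)
    tip_labels: tuple[str, str, str] = ("A", "B", "C")
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.outer >= self.inner >= 0):
            raise FixtureError("need outer >= inner >= 0")
        if self.rate_2mu <= 0 or self.length <= 0 or self.ts_tv_ratio <= 0:
            raise FixtureError("rate, length and ts/tv ratio must be positive")
        if any(c < 1 for c in self.seqs_per_tip):
            raise FixtureError("seqs_per_tip counts must be >= 1")


def _k2p_branch_probs(alpha: float, beta: float, t: float) -> tuple[float, float]:
    """(P(transition), P(each specific transversion)) after time t."""
    e1 = math.exp(-2.0 * (alpha + beta) * t)
    e2 = math.exp(-4.0 * beta * t)
    p_ts = 0.25 + 0.25 * e2 - 0.5 * e1
    p_tv_each = 0.25 - 0.25 * e2
    return p_ts, p_tv_each


def _evolve(parent: np.ndarray, alpha: float, beta: float, t: float,
            rng: np.random.Generator) -> np.ndarray:
    p_ts, p_tv = _k2p_branch_probs(alpha, beta, t)
    r = rng.random(parent.size)
    child = parent.copy()
    m = r < p_ts
    child[m] = _TS_PARTNER[parent[m]]
    m = (r >= p_ts) & (r < p_ts + p_tv)
    child[m] = _TV_FIRST[parent[m]]
    m = (r >= p_ts + p_tv) & (r < p_ts + 2.0 * p_tv)
    child[m] = _TV_SECOND[parent[m]]
    return child


def simulate_clock_alignment(spec: ClockSimSpec) -> MultipleAlignment:
    """Evolve ((A,B):inner, C):outer under K2P; reproducible under a seed.

    The per-lineage substitution rate is ``rate_2mu / 2`` so that two tips
    separated by t Myr have expected K2P distance ``rate_2mu * t``.  Tips
    with ``seqs_per_tip > 1`` carry identical copies of the tip haplotype
    (each simulated population is a single haplotype, as in the study data).
    """
    rng = np.random.default_rng(spec.seed)
    mu = spec.rate_2mu / 2.0
    R = spec.ts_tv_ratio
    alpha = mu * R / (R + 1.0)
    beta = mu / (2.0 * (R + 1.0))

    root = rng.integers(0, 4, size=spec.length, dtype=np.uint8)
    anc_ab = _evolve(root, alpha, beta, spec.outer - spec.inner, rng)
    tips = {
        spec.tip_labels[0]: _evolve(anc_ab, alpha, beta, spec.inner, rng),
        spec.tip_labels[1]: _evolve(anc_ab, alpha, beta, spec.inner, rng),
        spec.tip_labels[2]: _evolve(root, alpha, beta, spec.outer, rng),
    }
    ids: list[str] = []
    rows: list[np.ndarray] = []
    for label, count in zip(spec.tip_labels, spec.seqs_per_tip):
        for i in range(count):
            ids.append(label if count == 1 else f"{label}_{i + 1}")
            rows.append(tips[label])
    return MultipleAlignment.from_array(ids, np.vstack(rows))
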