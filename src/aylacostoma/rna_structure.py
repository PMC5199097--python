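"""Map variable alignment sites onto an rRNA secondary structure.

A dot-bracket annotation (Vienna convention, with ``-`` allowed for
columns outside the structural model) assigns each alignment column either
a stem partner or loop status.  Variable sites are then classified per
sequence pair as ``unpaired`` (loop change), ``stem_preserving`` (both
sequences still form a canonical pair with the partner column — GU wobble
included, as standard for rRNA) or ``stem_breaking``.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections.abc import Sequence

from .alignment_io import GAP, MultipleAlignment, variable_positions

#: Canonical (and wobble) pairs, with T read as U.
CANONICAL_PAIRS = frozenset(
    {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}
)

UNPAIRED = "unpaired"
STEM_PRESERVING = "stem_preserving"
STEM_BREAKING = "stem_breaking"


class StructureError(ValueError):
    """Raised for malformed dot-bracket annotations."""


@dataclasses.dataclass(frozen=True)
class DotBracketStructure:
    annotation: str
    pair_table: dict[int, int]  # 1-based column -> partner column, symmetric

    def partner(self, column: int) -> int | None:
        return self.pair_table.get(column)


def parse_dot_bracket(text: str, aln_length: int) -> DotBracketStructure:
    """Parse a dot-bracket string; brackets must balance and nest."""
    text = text.strip()
    if len(text) != aln_length:
        raise StructureError(
            f"structure length {len(text)} does not match alignment length {aln_length}"
        )
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for col, ch in enumerate(text, start=1):
        if ch == "(":
            stack.append(col)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at column {col}")
            opener = stack.pop()
            pairs[opener] = col
            pairs[col] = opener
        elif ch not in ".-":
            raise StructureError(f"illegal structure character {ch!r} at column {col}")
    if stack:
        raise StructureError(f"unclosed '(' at column {stack[-1]}")
    return DotBracketStructure(text, pairs)


@dataclasses.dataclass(frozen=True)
class SitePairClass:
    """Classification of one variable column for one sequence pair."""

    column: int
    id1: str
    id2: str
    category: str
    note: str = ""


def _pair_ok(base: str, partner: str) -> bool:
    return (base, partner) in CANONICAL_PAIRS


def classify_variable_sites(
    aln: MultipleAlignment, structure: DotBracketStructure
) -> list[SitePairClass]:
    """Classify every variable column for every differing sequence pair.

    At a paired column, a sequence 'preserves' the stem if its (base,
    partner-base) combination is a canonical or GU pair; the pair of
    sequences is ``stem_preserving`` only if both do.  A gap at the column
    or its partner makes the site ``stem_breaking`` with an
    ``indel-in-stem`` note.  Invariant columns are never classified.
    """
    if len(structure.annotation) != aln.length:
        raise StructureError("structure does not match alignment length")
    out: list[SitePairClass] = []
    for col in variable_positions(aln):
        partner = structure.partner(col)
        for id1, id2 in itertools.combinations(aln.ids, 2):
            s1, s2 = aln.sequence(id1), aln.sequence(id2)
            b1, b2 = s1[col - 1], s2[col - 1]
            if b1 == b2:
                continue
            if partner is None:
                out.append(SitePairClass(col, id1, id2, UNPAIRED))
                continue
            p1, p2 = s1[partner - 1], s2[partner - 1]
            if GAP in (b1, b2, p1, p2):
                out.append(
                    SitePairClass(col, id1, id2, STEM_BREAKING, note="indel-in-stem")
                )
            elif _pair_ok(b1, p1) and _pair_ok(b2, p2):
                out.append(SitePairClass(col, id1, id2, STEM_PRESERVING))
            else:
                out.append(SitePairClass(col, id1, id2, STEM_BREAKING))
    return out


def site_class_summary(
    aln: MultipleAlignment, structure: DotBracketStructure
) -> dict[int, str]:
    """Overall per-column class: worst case over all differing pairs.

    A stem column counts as ``stem_preserving`` only if every differing
    sequence pair preserves pairing; any breaking pair (including an
    indel-in-stem) makes the column ``stem_breaking``.
    """
    per_pair = classify_variable_sites(aln, structure)
    summary: dict[int, str] = {}
    rank = {UNPAIRED: 0, STEM_PRESERVING: 1, STEM_BREAKING: 2}
    for rec in per_pair:
        cur = summary.get(rec.column)
        if cur is None or rank[rec.category] > rank[cur]:
            summary[rec.column] = rec.category
    return summary


def class_counts(summary: dict[int, str]) -> tuple[int, int, int]:
    """(unpaired, stem_preserving, stem_breaking) column counts."""
    vals = list(summary.values())
    return (
        vals.count(UNPAIRED),
        vals.count(STEM_PRESERVING),
        vals.count(STEM_BREAKING),
    )


def write_classification_tsv(records: Sequence[SitePairClass], path) -> None:
    with open(path, "w") as fh:
        fh.write("column\tid1\tid2\tclass\tnote\n")
        for r in records:
            fh.write(f"{r.column}\t{r.id1}\t{r.id2}\t{r.category}\t{r.note}\n")
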