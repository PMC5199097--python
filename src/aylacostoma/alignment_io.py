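"""Alignment container, FASTA / group-file I/O and site-level profiling.

The central object is :class:`MultipleAlignment`, an immutable matrix of
gapped nucleotide sequences over the alphabet ``ACGT-``.  Coordinates are
1-based alignment columns throughout, so positions printed in reports can
be compared directly with published polymorphic-site tables.

Pairwise comparisons follow the conventions of distance-based barcoding
studies: a column where exactly one of the two sequences is gapped is an
*indel event* (maximal runs of such columns count once) and is never a
nucleotide difference; columns gapped in either sequence are excluded from
``compared_sites``.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT-"
GAP = "-"
_CODE = {c: i for i, c in enumerate(ALPHABET)}
_GAP_CODE = 4

_ENCODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _c, _i in _CODE.items():
    _ENCODE_TABLE[ord(_c)] = _i
_DECODE_TABLE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
# A and G are purines; a mismatch within a chemical class is a transition.
_IS_PURINE = np.array([True, False, True, False, False])


class AlignmentError(ValueError):
    """Raised for malformed alignments or alignment files."""


@dataclasses.dataclass(frozen=True)
class SiteDiffSummary:
    """Site-pattern counts for one pair of aligned sequences.

    ``transitions`` are A<->G / C<->T mismatches, ``transversions`` all other
    base mismatches, ``indel_events`` maximal runs of columns gapped in
    exactly one of the two sequences, and ``compared_sites`` the number of
    columns where neither sequence is gapped (the distance denominator).
    """

    transitions: int
    transversions: int
    indel_events: int
    compared_sites: int

    def __post_init__(self) -> None:
        if min(self.transitions, self.transversions, self.indel_events, self.compared_sites) < 0:
            raise ValueError("site-difference counts must be non-negative")
        if self.transitions + self.transversions > self.compared_sites:
            raise ValueError("more mismatches than compared sites")

    @property
    def nucleotide_differences(self) -> int:
        return self.transitions + self.transversions


@dataclasses.dataclass(frozen=True)
class Composition:
    """Base composition of a single (ungapped) sequence."""

    counts: dict[str, int]
    percents: dict[str, float]
    at_content: float
    gc_content: float
    ungapped_length: int


class MultipleAlignment:
    """Ordered, equal-length, gapped nucleotide sequences with unique IDs."""

    __slots__ = ("_ids", "_array", "_index")

    def __init__(self, records: Iterable[tuple[str, str]]):
        records = list(records)
        if not records:
            raise AlignmentError("alignment must contain at least one sequence")
        ids = [rid for rid, _ in records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise AlignmentError(f"duplicate sequence ID {dup!r}")
        rows = []
        length = None
        for rid, seq in records:
            seq = seq.upper()
            if length is None:
                length = len(seq)
            elif len(seq) != length:
                raise AlignmentError(
                    f"sequence {rid!r} has length {len(seq)}, expected {length}"
                )
            row = _ENCODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
            if (row == 255).any():
                bad = sorted({seq[k] for k in np.flatnonzero(row == 255)})
                raise AlignmentError(
                    f"sequence {rid!r} contains illegal residue(s) {bad}; "
                    f"only {ALPHABET!r} are accepted (no ambiguity codes)"
                )
            rows.append(row)
        if length == 0:
            raise AlignmentError("alignment length must be >= 1")
        self._ids = tuple(ids)
        self._array = np.vstack(rows)
        self._array.setflags(write=False)
        self._index = {rid: k for k, rid in enumerate(self._ids)}

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_array(cls, ids: Sequence[str], array: np.ndarray) -> "MultipleAlignment":
        """Build from an encoded uint8 matrix (codes 0..4); used internally
        by column resampling so bootstrap replicates avoid string round-trips."""
        obj = cls.__new__(cls)
        ids = tuple(ids)
        array = np.ascontiguousarray(array, dtype=np.uint8)
        if array.ndim != 2 or array.shape[0] != len(ids) or array.shape[1] < 1:
            raise AlignmentError("array shape does not match ids / minimum length")
        if array.max(initial=0) > _GAP_CODE:
            raise AlignmentError("array contains codes outside the ACGT- alphabet")
        if len(set(ids)) != len(ids):
            raise AlignmentError("duplicate sequence IDs")
        array.setflags(write=False)
        obj._ids = ids
        obj._array = array
        obj._index = {rid: k for k, rid in enumerate(ids)}
        return obj

    # -- basic protocol -------------------------------------------------------

    @property
    def ids(self) -> tuple[str, ...]:
        return self._ids

    @property
    def array(self) -> np.ndarray:
        """Encoded residues, shape (n_sequences, n_columns); read-only."""
        return self._array

    @property
    def length(self) -> int:
        return self._array.shape[1]

    def __len__(self) -> int:
        return self._array.shape[0]

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, MultipleAlignment)
            and self._ids == other._ids
            and np.array_equal(self._array, other._array)
        )

    def __repr__(self) -> str:
        return f"<MultipleAlignment {len(self)} sequences x {self.length} columns>"

    def row(self, seq_id: str) -> np.ndarray:
        try:
            return self._array[self._index[seq_id]]
        except KeyError:
            raise KeyError(f"sequence ID {seq_id!r} not in alignment") from None

    def sequence(self, seq_id: str) -> str:
        return _DECODE_TABLE[self.row(seq_id)].tobytes().decode("ascii")

    def records(self) -> Iterable[tuple[str, str]]:
        for rid in self._ids:
            yield rid, self.sequence(rid)

    def subset(self, ids: Sequence[str]) -> "MultipleAlignment":
        rows = np.vstack([self.row(i) for i in ids])
        return MultipleAlignment.from_array(ids, rows)

    def ungapped_length(self, seq_id: str) -> int:
        return int((self.row(seq_id) != _GAP_CODE).sum())


# -- file I/O -----------------------------------------------------------------


def _header_lines(path: Path) -> list[int]:
    return [
        lineno
        for lineno, line in enumerate(path.read_text().splitlines(), start=1)
        if line.startswith(">")
    ]


def read_fasta(path) -> MultipleAlignment:
    """Read a multi-FASTA alignment; lower-case residues are upper-cased.

    Ragged lengths, duplicate IDs and non-ACGT- residues (including IUPAC
    ambiguity codes) are hard errors reported with the header line number of
    the offending record.
    """
    path = Path(path)
    if not path.exists():
        raise AlignmentError(f"alignment file not found: {path}")
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise AlignmentError(f"{path}: no FASTA records found")
    headers = _header_lines(path)

    def _line(k: int) -> str:
        return str(headers[k]) if k < len(headers) else "?"

    seen: dict[str, int] = {}
    length = len(records[0][1])
    for k, (rid, seq) in enumerate(records):
        if rid in seen:
            raise AlignmentError(f"{path}:{_line(k)}: duplicate sequence ID {rid!r}")
        seen[rid] = k
        if len(seq) != length:
            raise AlignmentError(
                f"{path}:{_line(k)}: sequence {rid!r} has length {len(seq)}, "
                f"expected {length} (alignment is ragged)"
            )
        bad = sorted(set(seq.upper()) - set(ALPHABET))
        if bad:
            raise AlignmentError(
                f"{path}:{_line(k)}: sequence {rid!r} contains illegal residue(s) "
                f"{bad}; ambiguity codes are rejected"
            )
    return MultipleAlignment(records)


def write_fasta(aln: MultipleAlignment, path) -> None:
    recs = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in aln.records()
    ]
    SeqIO.write(recs, str(path), "fasta")


def read_groups(path) -> dict[str, tuple[str, ...]]:
    """Read a two-column TSV (sequence id, group) into group -> ids, keeping
    file order for both groups and members."""
    path = Path(path)
    if not path.exists():
        raise AlignmentError(f"groups file not found: {path}")
    groups: dict[str, list[str]] = {}
    seen: set[str] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise AlignmentError(f"{path}:{lineno}: expected 'id<TAB>group'")
        rid, grp = parts
        if rid in seen:
            raise AlignmentError(f"{path}:{lineno}: sequence {rid!r} assigned twice")
        seen.add(rid)
        groups.setdefault(grp, []).append(rid)
    return {g: tuple(ids) for g, ids in groups.items()}


def write_groups(groups: Mapping[str, Sequence[str]], path) -> None:
    with open(path, "w") as fh:
        for grp, ids in groups.items():
            for rid in ids:
                fh.write(f"{rid}\t{grp}\n")


# -- profiling operations -----------------------------------------------------


def variable_positions(aln: MultipleAlignment) -> list[int]:
    """1-based columns where more than one symbol occurs (gap is a symbol)."""
    arr = aln.array
    var = (arr != arr[0]).any(axis=0)
    return [int(c) + 1 for c in np.flatnonzero(var)]


def composition(aln: MultipleAlignment, seq_id: str) -> Composition:
    """Per-base counts and percentages over the ungapped sequence length."""
    row = aln.row(seq_id)
    row = row[row != _GAP_CODE]
    n = row.size
    if n == 0:
        raise AlignmentError(f"sequence {seq_id!r} is all gaps")
    counts = np.bincount(row, minlength=4)
    count_map = {base: int(counts[_CODE[base]]) for base in "ACGT"}
    pct = {base: 100.0 * count_map[base] / n for base in "ACGT"}
    return Composition(
        counts=count_map,
        percents=pct,
        at_content=pct["A"] + pct["T"],
        gc_content=pct["G"] + pct["C"],
        ungapped_length=n,
    )


def collapse_haplotypes(
    aln: MultipleAlignment, groups: Mapping[str, Sequence[str]]
) -> dict[str, list[tuple[str, int]]]:
    """Unique full-length (gapped) sequences per group with multiplicities,
    in order of first occurrence."""
    out: dict[str, list[tuple[str, int]]] = {}
    for grp, ids in groups.items():
        haps: dict[str, int] = {}
        for rid in ids:
            seq = aln.sequence(rid)
            haps[seq] = haps.get(seq, 0) + 1
        out[grp] = list(haps.items())
    return out


def pairwise_site_diffs(aln: MultipleAlignment, id1: str, id2: str) -> SiteDiffSummary:
    """Transition / transversion / indel-event counts for one sequence pair.

    Gap-vs-base columns never count as nucleotide differences; maximal runs
    of columns gapped in exactly one sequence merge into a single indel
    event.  Columns gapped in either sequence are excluded from
    ``compared_sites``.
    """
    a, b = aln.row(id1), aln.row(id2)
    gap_a, gap_b = a == _GAP_CODE, b == _GAP_CODE
    both_bases = ~gap_a & ~gap_b
    diff = both_bases & (a != b)
    ts = int((diff & (_IS_PURINE[a] == _IS_PURINE[b])).sum())
    tv = int(diff.sum()) - ts
    indel_cols = gap_a ^ gap_b
    # count starts of maximal runs
    events = int(indel_cols[0]) + int((indel_cols[1:] & ~indel_cols[:-1]).sum())
    return SiteDiffSummary(
        transitions=ts,
        transversions=tv,
        indel_events=events,
        compared_sites=int(both_bases.sum()),
    )
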