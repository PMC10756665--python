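"""Split-half YRNA reference handling and exact-match indexing.

Full-length YRNAs (~100 nt) fold their 5' and 3' ends into a double-stranded
stem.  A read that matches one end of the molecule therefore has a cryptic,
reverse-complementary counterpart at the other end.  To keep fragment counts
unambiguous, each homolog is split into a 5' and a 3' half before matching,
and reads are assigned by exact, forward-strand containment in a half.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

from Bio.SeqIO.FastaIO import SimpleFastaParser

__all__ = [
    "Side",
    "YRNASource",
    "HalfReference",
    "MatchIndex",
    "ReferenceLoadError",
    "DuplicateIdError",
    "AlphabetError",
    "load_reference",
    "split_halves",
    "build_match_index",
    "write_half_table",
]

_DNA = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class ReferenceLoadError(ValueError):
    """Malformed or empty reference input."""


class DuplicateIdError(ReferenceLoadError):
    """Two reference records share one id."""


class AlphabetError(ReferenceLoadError):
    """A reference sequence contains a non-nucleotide character."""


class Side(str, Enum):
    """Which half of the source molecule a sequence comes from."""

    FIVE_PRIME = "5p"
    THREE_PRIME = "3p"

    def __str__(self) -> str:  # compact TSV labels
        return self.value


def revcomp(seq: str) -> str:
    """Reverse complement in the DNA alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class YRNASource:
    """One full-length YRNA homolog, stored in the DNA alphabet (sequencing
    readout convention: U -> T, uppercase)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if len(self.seq) < 2:
            raise ReferenceLoadError(
                f"reference {self.id!r}: length {len(self.seq)} < 2"
            )
        bad = set(self.seq) - _DNA
        if bad:
            raise AlphabetError(
                f"reference {self.id!r}: non-nucleotide characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class HalfReference:
    """A 5' or 3' half of a source, with 0-based half-open parent coordinates."""

    parent_id: str
    side: Side
    seq: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


def load_reference(fasta_path: str | Path) -> list[YRNASource]:
    """Read YRNA homolog sequences from a (possibly line-wrapped) FASTA file.

    Sequences are uppercased and U is converted to T.  Raises
    :class:`ReferenceLoadError` for an empty file, :class:`DuplicateIdError`
    for repeated record ids and :class:`AlphabetError` for characters outside
    A/C/G/T/U.
    """
    sources: list[YRNASource] = []
    seen: set[str] = set()
    with open(fasta_path) as handle:
        for title, seq in SimpleFastaParser(handle):
            rec_id = title.split()[0] if title.split() else title
            if rec_id in seen:
                raise DuplicateIdError(f"duplicate reference id {rec_id!r}")
            seen.add(rec_id)
            sources.append(YRNASource(rec_id, seq.upper().replace("U", "T")))
    if not sources:
        raise ReferenceLoadError(f"no FASTA records in {fasta_path}")
    return sources


def split_halves(source: YRNASource) -> tuple[HalfReference, HalfReference]:
    """Split a source at ceil(L/2): the 5' half covers [0, s), the 3' half
    [s, L), so the two halves tile the molecule exactly and the 5' half is
    never the shorter one."""
    length = source.length
    if length < 2:
        raise ReferenceLoadError(f"cannot split {source.id!r}: length {length} < 2")
    s = math.ceil(length / 2)
    five = HalfReference(source.id, Side.FIVE_PRIME, source.seq[:s], 0, s)
    three = HalfReference(source.id, Side.THREE_PRIME, source.seq[s:], s, length)
    return five, three


class MatchIndex:
    """Exact-containment index over all half references.

    Built as a hash map from every substring of every half to its occurrence
    list, which is cheap because halves are ~50 nt.  Queries are strand
    specific: only forward-strand containment is reported, matching the
    stranded small-RNA library chemistry.
    """

    def __init__(self, sources: Sequence[YRNASource]):
        if not sources:
            raise ReferenceLoadError("cannot build an index over zero sources")
        ids = [s.id for s in sources]
        if len(set(ids)) != len(ids):
            raise DuplicateIdError("duplicate source ids in index input")
        self.sources: tuple[YRNASource, ...] = tuple(sources)
        self.halves: tuple[HalfReference, ...] = tuple(
            h for src in sources for h in split_halves(src)
        )
        table: dict[str, list[tuple[str, Side, int]]] = {}
        for half in self.halves:
            hseq = half.seq
            n = len(hseq)
            for i in range(n):
                for j in range(i + 1, n + 1):
                    # occurrence recorded at full-parent coordinates
                    table.setdefault(hseq[i:j], []).append(
                        (half.parent_id, half.side, half.start + i)
                    )
        for occs in table.values():
            occs.sort(key=lambda t: (t[0], t[1].value, t[2]))
        self._table = table

    @property
    def parent_ids(self) -> tuple[str, ...]:
        return tuple(s.id for s in self.sources)

    def __contains__(self, seq: str) -> bool:
        return seq in self._table

    def occurrences(self, seq: str) -> list[tuple[str, Side, int]]:
        """All (parent_id, side, parent_offset) positions at which *seq* is
        exactly contained in a half, sorted by (parent, side, offset)."""
        return list(self._table.get(seq, ()))


def build_match_index(sources: Iterable[YRNASource]) -> MatchIndex:
    """Index both halves of every source for exact-containment queries."""
    return MatchIndex(list(sources))


def write_half_table(sources: Iterable[YRNASource], path: str | Path) -> None:
    """Export the split-half table as TSV (parent_id, side, start, end, seq)."""
    with open(path, "w") as out:
        out.write("parent_id\tside\tstart\tend\tseq\n")
        for src in sources:
            for half in split_halves(src):
                out.write(
                    f"{half.parent_id}\t{half.side}\t{half.start}\t"
                    f"{half.end}\t{half.seq}\n"
                )
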