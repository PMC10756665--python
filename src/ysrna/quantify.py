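"""Exact-match quantification of small-RNA reads against split-half references.

A hit requires the *entire* trimmed read to be exactly contained, on the
forward strand, in one half reference — the 100%-identity, full-read
analogue of a perfect alignment.  This is deliberately stricter than local
alignment so that tabulated hit lengths are read lengths.  Counts are
normalised to reads per million (RPM) of a user-supplied alignable-read
denominator.
"""

from __future__ import annotations

import logging
from collections import Counter
from collections.abc import Iterable
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .reference import MatchIndex, Side
from .simulate import Treatment

__all__ = [
    "HitRecord",
    "CountTable",
    "trim_adapter",
    "match_read",
    "count_sequences",
    "quantify_library",
    "length_profile",
]

logger = logging.getLogger(__name__)

DEFAULT_MIN_LEN = 20
DEFAULT_MAX_LEN = 50
MIN_ADAPTER_OVERLAP = 6

_COLUMNS = ["parent_id", "side", "length", "offset", "raw", "rpm"]


@dataclass(frozen=True)
class HitRecord:
    """One exact full-read containment of a read in a half reference;
    ``parent_offset`` is 0-based in the full parent sequence."""

    read_id: str
    parent_id: str
    side: Side
    parent_offset: int
    length: int


@dataclass
class CountTable:
    """Normalised perfect-hit counts for one library.

    ``counts`` holds one row per occupied (parent_id, side, length, offset)
    cell with raw and RPM values; RPM = raw * 1e6 / denominator.
    """

    sample_id: str
    treatment: Treatment
    denominator: float
    counts: pd.DataFrame
    parent_ids: tuple[str, ...]
    stats: dict = field(default_factory=dict)

    def aggregate(self) -> pd.DataFrame:
        """Aggregate RPM per (parent_id, side), zero-filled for classes with
        no hits."""
        base = pd.MultiIndex.from_product(
            [self.parent_ids, [Side.FIVE_PRIME.value, Side.THREE_PRIME.value]],
            names=["parent_id", "side"],
        )
        if self.counts.empty:
            agg = pd.Series(0.0, index=base, name="rpm")
        else:
            agg = (
                self.counts.groupby(["parent_id", "side"])["rpm"]
                .sum()
                .reindex(base, fill_value=0.0)
            )
        return agg.reset_index()

    def class_rpm(self, parent_id: str, side: Side) -> float:
        sel = self.counts[
            (self.counts["parent_id"] == parent_id)
            & (self.counts["side"] == side.value)
        ]
        return float(sel["rpm"].sum())

    def to_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as out:
            if header_comment:
                out.write(f"# {header_comment}\n")
            out.write(
                f"# sample={self.sample_id} treatment={self.treatment} "
                f"denominator={self.denominator:g}\n"
            )
            df = self.counts.copy()
            df.insert(0, "treatment", str(self.treatment))
            df.insert(0, "sample", self.sample_id)
            df.to_csv(out, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, parent_ids: Iterable[str] | None = None)\
            -> "CountTable":
        meta: dict[str, str] = {}
        with open(path) as handle:
            for line in handle:
                if not line.startswith("#"):
                    break
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
        df = pd.read_csv(path, sep="\t", comment="#")
        sample = meta.get("sample", df["sample"].iloc[0] if len(df) else "sample")
        treatment = Treatment(
            meta.get("treatment", df["treatment"].iloc[0] if len(df) else "NONE")
        )
        denominator = float(meta.get("denominator", 0) or 0)
        counts = df[_COLUMNS] if len(df) else pd.DataFrame(columns=_COLUMNS)
        if parent_ids is None:
            parent_ids = tuple(sorted(counts["parent_id"].unique()))
        return cls(sample, treatment, denominator, counts.reset_index(drop=True),
                   tuple(parent_ids))


def trim_adapter(seq: str, adapter: str, min_overlap: int = MIN_ADAPTER_OVERLAP) -> str:
    """Remove a 3' sequencing adapter.

    The read is truncated at the first full occurrence of the adapter, or at
    the leftmost position where the read's 3' suffix equals a prefix of the
    adapter of at least ``min_overlap`` nt.  Reads without a detectable
    adapter are returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty when trimming is requested")
    pos = seq.find(adapter)
    if pos != -1:
        return seq[:pos]
    max_olap = min(len(adapter), len(seq))
    for olap in range(max_olap, min_overlap - 1, -1):
        if seq.endswith(adapter[:olap]):
            return seq[: len(seq) - olap]
    return seq


def match_read(seq: str, index: MatchIndex, min_len: int = DEFAULT_MIN_LEN,
               read_id: str = "") -> list[HitRecord]:
    """All exact, full-read, forward-strand containments of ``seq`` in any
    half reference, sorted by (parent, side, offset).  Reads shorter than
    ``min_len`` return no hits."""
    if len(seq) < min_len:
        logger.debug("skipping read %s: length %d < %d", read_id, len(seq), min_len)
        return []
    return [
        HitRecord(read_id, parent, side, offset, len(seq))
        for parent, side, offset in index.occurrences(seq)
    ]


def count_sequences(
    seqs: Iterable[str],
    index: MatchIndex,
    denominator: float,
    sample_id: str = "sample",
    treatment: Treatment = Treatment.NONE,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    adapter: str | None = None,
) -> CountTable:
    """Core counting engine over an iterable of read sequences.

    Each read is adapter-trimmed (optional), length-filtered to
    [min_len, max_len] and matched; every hit of a multi-hit read increments
    its own (parent, side, length, offset) cell.
    """
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    stats = Counter(reads_in=0, trimmed=0, length_filtered=0, matched=0, multihit=0)
    seq_multiplicity: Counter[str] = Counter()
    for seq in seqs:
        stats["reads_in"] += 1
        if adapter:
            trimmed = trim_adapter(seq, adapter)
            if len(trimmed) != len(seq):
                stats["trimmed"] += 1
            seq = trimmed
        if not min_len <= len(seq) <= max_len:
            stats["length_filtered"] += 1
            continue
        seq_multiplicity[seq] += 1

    cells: Counter[tuple[str, str, int, int]] = Counter()
    for seq, mult in seq_multiplicity.items():
        occs = index.occurrences(seq)
        if occs:
            stats["matched"] += mult
            if len(occs) > 1:
                stats["multihit"] += mult
        for parent, side, offset in occs:
            cells[(parent, side.value, len(seq), offset)] += mult

    if cells:
        rows = [
            {"parent_id": p, "side": s, "length": l, "offset": o, "raw": raw,
             "rpm": raw * 1e6 / denominator}
            for (p, s, l, o), raw in sorted(cells.items())
        ]
        counts = pd.DataFrame(rows, columns=_COLUMNS)
    else:
        counts = pd.DataFrame(columns=_COLUMNS)
    logger.info(
        "%s [%s]: %d reads in, %d trimmed, %d length-filtered, %d matched "
        "(%d multi-hit)",
        sample_id, treatment, stats["reads_in"], stats["trimmed"],
        stats["length_filtered"], stats["matched"], stats["multihit"],
    )
    return CountTable(
        sample_id, treatment, float(denominator), counts, index.parent_ids,
        dict(stats),
    )


def quantify_library(
    fastq_path: str | Path,
    index: MatchIndex,
    denominator: float,
    sample_id: str | None = None,
    treatment: Treatment = Treatment.NONE,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    adapter: str | None = None,
) -> CountTable:
    """Quantify a FASTQ library against the split-half reference."""
    if sample_id is None:
        sample_id = Path(fastq_path).stem
    with open(fastq_path) as handle:
        seqs = (seq for _title, seq, _qual in FastqGeneralIterator(handle))
        return count_sequences(
            seqs, index, denominator, sample_id=sample_id, treatment=treatment,
            min_len=min_len, max_len=max_len, adapter=adapter,
        )


def length_profile(
    table: CountTable,
    parent_id: str,
    side: Side,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> pd.Series:
    """RPM per hit length for one (homolog, half), summed over start offsets;
    lengths without hits map to 0."""
    if parent_id not in table.parent_ids:
        raise KeyError(f"unknown parent {parent_id!r}")
    if not isinstance(side, Side):
        raise KeyError(f"unknown side {side!r}")
    sel = table.counts[
        (table.counts["parent_id"] == parent_id)
        & (table.counts["side"] == side.value)
    ]
    prof = pd.Series(0.0, index=pd.RangeIndex(min_len, max_len + 1, name="length"),
                     name="rpm")
    if len(sel):
        sums = sel.groupby("length")["rpm"].sum()
        prof.loc[sums.index] = prof.loc[sums.index] + sums
    return prof
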