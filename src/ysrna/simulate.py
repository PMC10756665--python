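"""Seeded simulation of small-RNA libraries with known YRNA fragment origins
and terminal chemistry.

The generator models the steps of a small-RNA sequencing experiment that
determine whether a fragment is *seen* at all:

* fragments are 5'-anchored copies of a source YRNA, 25-35 nt long, starting
  at the first or second base of the source;
* each molecule carries a 5' terminus (hydroxyl, monophosphate or
  triphosphate) and a 3' terminus (hydroxyl, monophosphate, 2',3'-cyclic
  phosphate, or 2'-O-methyl with a free 3'-OH);
* optional chemical/enzymatic treatments (periodate oxidation with
  beta-elimination, T4 PNK, RppH) rewrite those termini;
* two-adapter ligation then admits only molecules with a 5' monophosphate and
  a ligatable 3'-hydroxyl, and size selection drops anything above 50 nt.

Because every read carries its ground-truth origin and terminal state, the
whole downstream pipeline (matching, counting, modification inference) can be
validated by parameter recovery.
"""

from __future__ import annotations

from collections.abc import Iterable, Iterator, Mapping, Sequence
from dataclasses import dataclass
from enum import Enum, IntEnum
from pathlib import Path

import numpy as np

from .reference import YRNASource, revcomp, split_halves

__all__ = [
    "FivePrime",
    "ThreePrime",
    "TerminalState",
    "Treatment",
    "SimRead",
    "SimLibrary",
    "FragmentClassConfig",
    "BACKGROUND",
    "DEFAULT_P_PNK_5P_DEPHOS",
    "generate_reference_set",
    "generate_library",
    "apply_treatment",
    "ligate_and_select",
    "write_library",
    "peaked_length_distribution",
    "sperm_head_config",
    "oocyte_config",
]

MIN_FRAGMENT_LEN = 25
MAX_FRAGMENT_LEN = 35
SIZE_SELECT_MAX = 50
BACKGROUND = "background"
DEFAULT_P_PNK_5P_DEPHOS = 0.8

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class FivePrime(IntEnum):
    OH = 0
    MONO_P = 1
    TRI_P = 2


class ThreePrime(IntEnum):
    OH = 0
    MONO_P = 1
    CYCLIC_P = 2
    OME = 3  # 2'-O-methyl; the 3'-OH itself stays free and ligatable


@dataclass(frozen=True)
class TerminalState:
    five_prime: FivePrime
    three_prime: ThreePrime


class Treatment(str, Enum):
    """Library treatment arms. PNK_RPPH means PNK first, then RppH."""

    NONE = "NONE"
    OXIDATION_BETA_ELIM = "OXIDATION_BETA_ELIM"
    PNK = "PNK"
    RPPH = "RPPH"
    PNK_RPPH = "PNK_RPPH"

    def __str__(self) -> str:
        return self.value


@dataclass
class SimRead:
    """One simulated read with its ground-truth channel."""

    read_id: str
    seq: str
    truth_parent: str  # homolog id, or BACKGROUND
    truth_start: int | None  # 0-based offset in the parent; None for background
    state: TerminalState

    @property
    def ligatable(self) -> bool:
        return self.state.five_prime == FivePrime.MONO_P and self.state.three_prime in (
            ThreePrime.OH,
            ThreePrime.OME,
        )


@dataclass(frozen=True)
class FragmentClassConfig:
    """Truth configuration for one fragment class (one source homolog).

    ``start_distribution`` assigns probability to offsets 0 and 1 (the first
    and second base of the source); ``length_distribution`` to lengths within
    [25, 35] nt; ``state_distribution`` to terminal-chemistry states;
    ``abundance_fraction`` is the class's share of the whole library.
    """

    parent_id: str
    start_distribution: Mapping[int, float]
    length_distribution: Mapping[int, float]
    state_distribution: Mapping[TerminalState, float]
    abundance_fraction: float

    def validate(self) -> None:
        for name, dist in (
            ("start_distribution", self.start_distribution),
            ("length_distribution", self.length_distribution),
            ("state_distribution", self.state_distribution),
        ):
            if not dist:
                raise ValueError(f"{self.parent_id}: empty {name}")
            total = float(sum(dist.values()))
            if any(p < 0 for p in dist.values()) or abs(total - 1.0) > 1e-9:
                raise ValueError(f"{self.parent_id}: {name} must sum to 1, got {total}")
        if any(s not in (0, 1) for s in self.start_distribution):
            raise ValueError(f"{self.parent_id}: start offsets must be 0 or 1")
        if any(
            not (MIN_FRAGMENT_LEN <= l <= MAX_FRAGMENT_LEN)
            for l in self.length_distribution
        ):
            raise ValueError(
                f"{self.parent_id}: lengths must lie in "
                f"[{MIN_FRAGMENT_LEN}, {MAX_FRAGMENT_LEN}]"
            )
        if not 0 <= self.abundance_fraction <= 1:
            raise ValueError(f"{self.parent_id}: abundance_fraction out of [0,1]")


class SimLibrary(Sequence):
    """Array-backed collection of :class:`SimRead`.

    Kept columnar (numpy arrays) so that treatment operators and the ligation
    gate are vectorised; indexing or iterating materialises ``SimRead``
    objects on demand.  Read ids are assigned once at generation and survive
    treatments and selection.
    """

    def __init__(
        self,
        ref: Sequence[YRNASource],
        parent_idx: np.ndarray,  # -1 for background
        start: np.ndarray,
        length: np.ndarray,
        five: np.ndarray,
        three: np.ndarray,
        bg_seq: np.ndarray,  # dtype object; "" for fragment reads
        read_index: np.ndarray,
    ):
        self.ref = tuple(ref)
        self.parent_idx = parent_idx
        self.start = start
        self.length = length
        self.five = five
        self.three = three
        self.bg_seq = bg_seq
        self.read_index = read_index

    def __len__(self) -> int:
        return len(self.parent_idx)

    def _seq(self, i: int) -> str:
        p = self.parent_idx[i]
        if p < 0:
            return self.bg_seq[i][: self.length[i]]
        s = self.start[i]
        return self.ref[p].seq[s : s + self.length[i]]

    def __getitem__(self, i):
        if isinstance(i, slice):
            return [self[j] for j in range(*i.indices(len(self)))]
        p = self.parent_idx[i]
        return SimRead(
            read_id=f"r{self.read_index[i]:07d}",
            seq=self._seq(i),
            truth_parent=BACKGROUND if p < 0 else self.ref[p].id,
            truth_start=None if p < 0 else int(self.start[i]),
            state=TerminalState(FivePrime(int(self.five[i])), ThreePrime(int(self.three[i]))),
        )

    def __iter__(self) -> Iterator[SimRead]:
        for i in range(len(self)):
            yield self[i]

    def sequences(self) -> list[str]:
        """Materialise all read sequences (current, post-treatment lengths)."""
        out: list[str] = []
        seqs = [r.seq for r in self.ref]
        for i in range(len(self)):
            p = self.parent_idx[i]
            if p < 0:
                out.append(self.bg_seq[i][: self.length[i]])
            else:
                s = self.start[i]
                out.append(seqs[p][s : s + self.length[i]])
        return out

    def subset(self, mask: np.ndarray) -> "SimLibrary":
        return SimLibrary(
            self.ref,
            self.parent_idx[mask],
            self.start[mask],
            self.length[mask],
            self.five[mask],
            self.three[mask],
            self.bg_seq[mask],
            self.read_index[mask],
        )

    def copy(self) -> "SimLibrary":
        return SimLibrary(
            self.ref,
            self.parent_idx.copy(),
            self.start.copy(),
            self.length.copy(),
            self.five.copy(),
            self.three.copy(),
            self.bg_seq.copy(),
            self.read_index.copy(),
        )


def _random_sequences(rng: np.random.Generator, lengths: np.ndarray) -> list[str]:
    """Vectorised random A/C/G/T strings of the given lengths."""
    if len(lengths) == 0:
        return []
    total = int(lengths.sum())
    codes = rng.integers(0, 4, size=total)
    flat = _BASES[codes].tobytes().decode("ascii")
    out = []
    pos = 0
    for l in lengths:
        out.append(flat[pos : pos + l])
        pos += l
    return out


def generate_reference_set(
    lengths: Sequence[int] = (112, 101, 93, 83),
    stem_len: int = 10,
    seed: int = 0,
    ids: Sequence[str] | None = None,
) -> list[YRNASource]:
    """Generate synthetic YRNA-like homolog sequences.

    Each sequence is random except that its last ``stem_len`` bases are the
    reverse complement of its first ``stem_len`` bases, reproducing the
    5'/3' stem complementarity of real YRNAs — the very feature that makes
    split-half matching necessary.  Deterministic given ``seed``.
    """
    if ids is None:
        ids = (
            ["hY1", "hY3", "hY4", "hY5"][: len(lengths)]
            if len(lengths) <= 4
            else [f"Y{i + 1}" for i in range(len(lengths))]
        )
    if len(ids) != len(lengths):
        raise ValueError("ids and lengths must have equal length")
    rng = np.random.default_rng(seed)
    sources = []
    for rec_id, length in zip(ids, lengths):
        if length <= 2 * stem_len:
            raise ValueError(
                f"{rec_id}: length {length} must exceed 2*stem_len ({2 * stem_len})"
            )
        body = "".join(_random_sequences(rng, np.array([length - stem_len])))
        seq = body + revcomp(body[:stem_len])
        sources.append(YRNASource(rec_id, seq))
    return sources


def _half_substring_set(
    ref: Sequence[YRNASource], min_len: int, max_len: int
) -> set[str]:
    subs: set[str] = set()
    for src in ref:
        for half in split_halves(src):
            h = half.seq
            for l in range(min_len, min(max_len, len(h)) + 1):
                for i in range(len(h) - l + 1):
                    subs.add(h[i : i + l])
    return subs


def generate_library(
    ref: Sequence[YRNASource],
    classes: Sequence[FragmentClassConfig],
    background_fraction: float,
    n_reads: int,
    seed: int = 0,
) -> SimLibrary:
    """Sample a pre-treatment read pool.

    Each read draws a fragment class by abundance (or background), then a
    start offset, a length and a terminal state from the class distributions;
    its sequence is copied verbatim from the parent.  Background reads are
    random sequences rejection-sampled so that none is an exact substring of
    any reference half.  Deterministic given ``seed``.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be >= 0")
    for cfg in classes:
        cfg.validate()
    fractions = [c.abundance_fraction for c in classes] + [background_fraction]
    if background_fraction < 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(
            f"class fractions + background must sum to 1, got {sum(fractions)}"
        )
    ref_ids = {s.id: i for i, s in enumerate(ref)}
    for cfg in classes:
        if cfg.parent_id not in ref_ids:
            raise ValueError(f"class parent {cfg.parent_id!r} not in reference set")

    rng = np.random.default_rng(seed)
    parent_idx = np.full(n_reads, -1, dtype=np.int32)
    start = np.zeros(n_reads, dtype=np.int32)
    length = np.zeros(n_reads, dtype=np.int32)
    five = np.zeros(n_reads, dtype=np.uint8)
    three = np.zeros(n_reads, dtype=np.uint8)
    bg_seq = np.full(n_reads, "", dtype=object)

    assignment = rng.choice(len(classes) + 1, size=n_reads, p=fractions)
    for ci, cfg in enumerate(classes):
        mask = assignment == ci
        n = int(mask.sum())
        if n == 0:
            continue
        parent_idx[mask] = ref_ids[cfg.parent_id]
        starts, s_p = zip(*cfg.start_distribution.items())
        start[mask] = rng.choice(starts, size=n, p=np.asarray(s_p) / sum(s_p))
        lens, l_p = zip(*cfg.length_distribution.items())
        length[mask] = rng.choice(lens, size=n, p=np.asarray(l_p) / sum(l_p))
        states, st_p = zip(*cfg.state_distribution.items())
        drawn = rng.choice(len(states), size=n, p=np.asarray(st_p) / sum(st_p))
        five[mask] = np.array([states[k].five_prime for k in drawn], dtype=np.uint8)
        three[mask] = np.array([states[k].three_prime for k in drawn], dtype=np.uint8)
        # fragments must fit in the parent
        max_start = max(cfg.start_distribution)
        max_len = max(cfg.length_distribution)
        if max_start + max_len > ref[ref_ids[cfg.parent_id]].length:
            raise ValueError(f"class {cfg.parent_id}: fragment exceeds parent length")

    bg_mask = assignment == len(classes)
    n_bg = int(bg_mask.sum())
    if n_bg:
        bg_lengths = rng.integers(MIN_FRAGMENT_LEN, MAX_FRAGMENT_LEN + 1, size=n_bg)
        length[bg_mask] = bg_lengths
        states, st_p = zip(*BACKGROUND_STATE_DISTRIBUTION.items())
        drawn = rng.choice(len(states), size=n_bg, p=np.asarray(st_p) / sum(st_p))
        five[bg_mask] = np.array([states[k].five_prime for k in drawn], dtype=np.uint8)
        three[bg_mask] = np.array([states[k].three_prime for k in drawn], dtype=np.uint8)
        forbidden = _half_substring_set(ref, MIN_FRAGMENT_LEN, MAX_FRAGMENT_LEN)
        seqs = _random_sequences(rng, bg_lengths)
        for attempt in range(100):
            redo = [i for i, s in enumerate(seqs) if s in forbidden]
            if not redo:
                break
            redo_lengths = bg_lengths[redo]
            for i, s in zip(redo, _random_sequences(rng, redo_lengths)):
                seqs[i] = s
        else:
            raise RuntimeError("background rejection sampling did not converge")
        bg_seq[bg_mask] = np.array(seqs, dtype=object)

    return SimLibrary(
        ref, parent_idx, start, length, five, three, bg_seq,
        np.arange(n_reads, dtype=np.int64),
    )


# Mixed chemistry for non-YRNA background reads: mostly canonical
# 5'-P/3'-OH species, some 2'-O-methylated (piRNA-like), some 3'-phosphate /
# cyclic-phosphate ends, some 5'-PPP.  Keeps every treated library non-empty,
# as in real total-RNA input.
BACKGROUND_STATE_DISTRIBUTION: dict[TerminalState, float] = {
    TerminalState(FivePrime.MONO_P, ThreePrime.OH): 0.63,
    TerminalState(FivePrime.MONO_P, ThreePrime.OME): 0.18,
    TerminalState(FivePrime.MONO_P, ThreePrime.MONO_P): 0.045,
    TerminalState(FivePrime.MONO_P, ThreePrime.CYCLIC_P): 0.045,
    TerminalState(FivePrime.TRI_P, ThreePrime.OH): 0.10,
}


def _transform_states(
    five: np.ndarray,
    three: np.ndarray,
    treatment: Treatment,
    p_pnk_5p_dephos: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Apply one treatment to state arrays; returns (five', three',
    drop_last_base mask).  All masks are computed from the input state so the
    branches of one operator do not feed each other."""
    five = five.copy()
    three = three.copy()
    drop = np.zeros(len(five), dtype=bool)
    if treatment == Treatment.NONE:
        return five, three, drop
    if treatment == Treatment.OXIDATION_BETA_ELIM:
        # only a free vicinal 2',3'-diol reacts with periodate; the terminal
        # base is then lost by beta-elimination, leaving a 3' monophosphate
        diol = three == ThreePrime.OH
        three[diol] = ThreePrime.MONO_P
        drop = diol
        return five, three, drop
    if treatment == Treatment.RPPH:
        five[five == FivePrime.TRI_P] = FivePrime.MONO_P
        return five, three, drop
    if treatment == Treatment.PNK:
        was_oh = five == FivePrime.OH
        was_p = five == FivePrime.MONO_P
        three[(three == ThreePrime.MONO_P) | (three == ThreePrime.CYCLIC_P)] = (
            ThreePrime.OH
        )
        five[was_oh] = FivePrime.MONO_P
        dephos = was_p & (rng.random(len(five)) < p_pnk_5p_dephos)
        five[dephos] = FivePrime.OH
        return five, three, drop
    if treatment == Treatment.PNK_RPPH:
        five, three, drop = _transform_states(
            five, three, Treatment.PNK, p_pnk_5p_dephos, rng
        )
        five2, three2, drop2 = _transform_states(
            five, three, Treatment.RPPH, p_pnk_5p_dephos, rng
        )
        return five2, three2, drop | drop2
    raise ValueError(f"unknown treatment {treatment!r}")


def apply_treatment(
    reads: SimLibrary | Iterable[SimRead],
    treatment: Treatment,
    params: Mapping[str, float] | None = None,
    seed: int = 0,
) -> SimLibrary | list[SimRead]:
    """Apply a treatment operator to a read pool, returning a new pool.

    Periodate oxidation / beta-elimination removes the last base of every
    read with a free 3'-OH and leaves a 3' monophosphate; 2'-O-methylated,
    3'-phosphate and cyclic-phosphate ends are inert.  RppH converts 5'-PPP
    to 5'-P.  PNK removes 3' phosphates and cyclic phosphates (-> 3'-OH),
    phosphorylates 5'-OH ends, and dephosphorylates existing 5'
    monophosphates with probability ``p_pnk_5p_dephos`` (net balance of its
    kinase and phosphatase/exchange activities).  PNK_RPPH applies PNK first,
    then RppH.  Ground-truth fields are never altered.
    """
    p = DEFAULT_P_PNK_5P_DEPHOS
    if params:
        p = float(params.get("p_pnk_5p_dephos", p))
        if not 0.0 <= p <= 1.0:
            raise ValueError("p_pnk_5p_dephos must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if isinstance(reads, SimLibrary):
        out = reads.copy()
        out.five, out.three, drop = _transform_states(
            out.five, out.three, treatment, p, rng
        )
        out.length = out.length - drop.astype(out.length.dtype)
        return out
    read_list = list(reads)
    five = np.array([r.state.five_prime for r in read_list], dtype=np.uint8)
    three = np.array([r.state.three_prime for r in read_list], dtype=np.uint8)
    five, three, drop = _transform_states(five, three, treatment, p, rng)
    out_reads = []
    for r, f, t, d in zip(read_list, five, three, drop):
        out_reads.append(
            SimRead(
                read_id=r.read_id,
                seq=r.seq[:-1] if d else r.seq,
                truth_parent=r.truth_parent,
                truth_start=r.truth_start,
                state=TerminalState(FivePrime(int(f)), ThreePrime(int(t))),
            )
        )
    return out_reads


def ligate_and_select(
    reads: SimLibrary | Iterable[SimRead], max_len: int = SIZE_SELECT_MAX
) -> SimLibrary | list[SimRead]:
    """Two-adapter ligation plus size selection.

    Only molecules with a 5' monophosphate and a free, unblocked 3'-OH
    (plain hydroxyl or 2'-O-methylated ribose) can receive both adapters;
    size selection keeps inserts of at most ``max_len`` nt.  Order is
    preserved and the output is a subset of the input.
    """
    if isinstance(reads, SimLibrary):
        mask = (
            (reads.five == FivePrime.MONO_P)
            & ((reads.three == ThreePrime.OH) | (reads.three == ThreePrime.OME))
            & (reads.length <= max_len)
        )
        return reads.subset(mask)
    return [r for r in reads if r.ligatable and len(r.seq) <= max_len]


def write_library(
    reads: SimLibrary | Iterable[SimRead],
    fastq_path: str | Path,
    truth_path: str | Path | None = None,
) -> None:
    """Write reads as 4-line FASTQ (constant 'I' quality) plus an optional
    ground-truth TSV (read_id, parent, start, length, five_prime, three_prime;
    start is 'NA' for background reads)."""
    with open(fastq_path, "w") as fq:
        truth = open(truth_path, "w") if truth_path else None
        try:
            if truth:
                truth.write("read_id\tparent\tstart\tlength\tfive_prime\tthree_prime\n")
            for r in reads:
                fq.write(f"@{r.read_id}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")
                if truth:
                    s = "NA" if r.truth_start is None else str(r.truth_start)
                    truth.write(
                        f"{r.read_id}\t{r.truth_parent}\t{s}\t{len(r.seq)}\t"
                        f"{r.state.five_prime.name}\t{r.state.three_prime.name}\n"
                    )
        finally:
            if truth:
                truth.close()


def peaked_length_distribution(
    mode: int, lo: int = MIN_FRAGMENT_LEN, hi: int = MAX_FRAGMENT_LEN
) -> dict[int, float]:
    """Unimodal length distribution over [lo, hi]: weight halves per nt of
    distance from the mode."""
    if not lo <= mode <= hi:
        raise ValueError("mode outside support")
    weights = {l: 2.0 ** (-abs(l - mode)) for l in range(lo, hi + 1)}
    total = sum(weights.values())
    return {l: w / total for l, w in weights.items()}


def _uniform(values: Iterable) -> dict:
    vals = list(values)
    return {v: 1.0 / len(vals) for v in vals}


_S = TerminalState  # local shorthand for the preset tables


def sperm_head_config() -> tuple[list[FragmentClassConfig], float]:
    """Default mature-sperm-head truth configuration.

    Fragment classes mirror the qualitative picture seen in mature sperm
    heads: Ys1 dominates (modal length 30 nt, starting mostly at the first
    base), followed by Ys4 and Ys3 (modal length 31 nt, mostly second base),
    with Ys5 rare.  Ys1/Ys3 are 5'-monophosphorylated and 2'-O-methylated at
    the 3' end (piRNA-like); Ys4 is a mixture with a 5'-triphosphorylated,
    unmethylated subpopulation; Ys5 is purely 5'-PPP/3'-OH and therefore
    invisible without RppH.  Returns (classes, background_fraction).
    """
    pi_like = {_S(FivePrime.MONO_P, ThreePrime.OME): 1.0}
    ppp = {_S(FivePrime.TRI_P, ThreePrime.OH): 1.0}
    classes = [
        FragmentClassConfig(
            "hY1", {0: 0.7, 1: 0.3}, peaked_length_distribution(30), pi_like, 0.35
        ),
        FragmentClassConfig(
            "hY3", {0: 0.3, 1: 0.7}, peaked_length_distribution(31), pi_like, 0.15
        ),
        FragmentClassConfig(
            "hY4",
            {0: 0.5, 1: 0.5},
            peaked_length_distribution(31),
            {
                _S(FivePrime.MONO_P, ThreePrime.OME): 0.4,
                _S(FivePrime.TRI_P, ThreePrime.OH): 0.6,
            },
            0.20,
        ),
        FragmentClassConfig(
            "hY5", {0: 0.5, 1: 0.5}, peaked_length_distribution(31), ppp, 0.05
        ),
    ]
    return classes, 0.25


def oocyte_config() -> tuple[list[FragmentClassConfig], float]:
    """Oocyte-like truth configuration: YsRNAs are scarcer, Ys3 is the major
    class, Ys1 is nearly absent, and no class carries 3' 2'-O-methylation
    (all 3'-OH), so simulated oxidation removes them entirely.  Modal lengths
    31-32 nt; with no homolog attribution available for those modes, Ys3
    takes 31 nt and Ys4 32 nt as a declared convention.  Returns
    (classes, background_fraction)."""
    plain = {_S(FivePrime.MONO_P, ThreePrime.OH): 1.0}
    classes = [
        FragmentClassConfig(
            "hY1", {0: 0.7, 1: 0.3}, peaked_length_distribution(31), plain, 0.01
        ),
        FragmentClassConfig(
            "hY3", {0: 0.3, 1: 0.7}, peaked_length_distribution(31), plain, 0.30
        ),
        FragmentClassConfig(
            "hY4", {0: 0.5, 1: 0.5}, peaked_length_distribution(32), plain, 0.15
        ),
        FragmentClassConfig(
            "hY5", {0: 0.5, 1: 0.5}, peaked_length_distribution(31), plain, 0.05
        ),
    ]
    return classes, 0.49
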