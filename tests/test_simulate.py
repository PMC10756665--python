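import itertools
import math

import numpy as np
import pytest
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ysrna.reference import revcomp
from ysrna.simulate import (
    BACKGROUND,
    FivePrime,
    FragmentClassConfig,
    SimRead,
    TerminalState,
    ThreePrime,
    Treatment,
    apply_treatment,
    generate_library,
    generate_reference_set,
    ligate_and_select,
    peaked_length_distribution,
    write_library,
)

ALL_STATES = [
    TerminalState(f, t) for f, t in itertools.product(FivePrime, ThreePrime)
]


def make_read(five, three, seq="ACGTACGTACGTACGTACGTACGTACGTAC"):
    return SimRead("r1", seq, "hY1", 0, TerminalState(five, three))


class TestGenerateReferenceSet:
    def test_stem_complementarity_and_lengths(self):
        sources = generate_reference_set((112, 101, 93, 83), stem_len=10, seed=1)
        assert [s.length for s in sources] == [112, 101, 93, 83]
        for s in sources:
            assert revcomp(s.seq[:10]) == s.seq[-10:]

    def test_deterministic_given_seed(self):
        a = generate_reference_set(seed=7)
        b = generate_reference_set(seed=7)
        assert [s.seq for s in a] == [s.seq for s in b]
        c = generate_reference_set(seed=8)
        assert [s.seq for s in a] != [s.seq for s in c]

    def test_stem_longer_than_half_rejected(self):
        with pytest.raises(ValueError):
            generate_reference_set((83,), stem_len=60, seed=0)


@pytest.fixture(scope="module")
def single_class(ref):
    return FragmentClassConfig(
        parent_id="hY1",
        start_distribution={0: 1.0},
        length_distribution={30: 1.0},
        state_distribution={TerminalState(FivePrime.MONO_P, ThreePrime.OME): 1.0},
        abundance_fraction=0.8,
    )


class TestGenerateLibrary:
    def test_zero_reads_gives_empty_library(self, ref, single_class):
        lib = generate_library(ref, [single_class], 0.2, 0, seed=1)
        assert len(lib) == 0

    def test_degenerate_distributions_copy_parent_prefix(self, ref, single_class):
        lib = generate_library(ref, [single_class], 0.2, 2000, seed=3)
        expected = ref[0].seq[:30]
        n_class = 0
        for read in lib:
            if read.truth_parent != BACKGROUND:
                n_class += 1
                assert read.seq == expected
                assert read.truth_start == 0
        assert n_class > 0

    def test_truth_channel_matches_parent_sequence(self, ref):
        classes, bg = _mixed_classes()
        lib = generate_library(ref, classes, bg, 5000, seed=11)
        by_id = {s.id: s for s in ref}
        for read in lib:
            if read.truth_parent == BACKGROUND:
                continue
            parent = by_id[read.truth_parent]
            s = read.truth_start
            assert parent.seq[s : s + len(read.seq)] == read.seq

    def test_background_never_matches_a_half(self, ref, index, single_class):
        lib = generate_library(ref, [single_class], 0.2, 5000, seed=5)
        n_bg = 0
        for read in lib:
            if read.truth_parent == BACKGROUND:
                n_bg += 1
                assert index.occurrences(read.seq) == []
        assert n_bg > 0

    def test_class_counts_follow_binomial(self, ref):
        cfg = FragmentClassConfig(
            "hY1", {0: 1.0}, {30: 1.0},
            {TerminalState(FivePrime.MONO_P, ThreePrime.OME): 1.0}, 0.6,
        )
        lib = generate_library(ref, [cfg], 0.4, 100_000, seed=1)
        n_class = int((lib.parent_idx >= 0).sum())
        sd = math.sqrt(100_000 * 0.6 * 0.4)
        assert abs(n_class - 60_000) <= 4 * sd

    def test_deterministic_given_seed(self, ref, single_class):
        a = generate_library(ref, [single_class], 0.2, 3000, seed=9)
        b = generate_library(ref, [single_class], 0.2, 3000, seed=9)
        assert [r.seq for r in a] == [r.seq for r in b]
        assert [r.state for r in a] == [r.state for r in b]

    def test_invalid_distributions_rejected(self, ref):
        bad = FragmentClassConfig(
            "hY1", {0: 0.5, 1: 0.4}, {30: 1.0},
            {TerminalState(FivePrime.MONO_P, ThreePrime.OME): 1.0}, 0.8,
        )
        with pytest.raises(ValueError):
            generate_library(ref, [bad], 0.2, 100, seed=1)
        with pytest.raises(ValueError):
            FragmentClassConfig(
                "hY1", {0: 1.0}, {40: 1.0},
                {TerminalState(FivePrime.MONO_P, ThreePrime.OME): 1.0}, 0.8,
            ).validate()

    def test_fractions_must_sum_to_one(self, ref, single_class):
        with pytest.raises(ValueError):
            generate_library(ref, [single_class], 0.5, 100, seed=1)


def _mixed_classes():
    pi = {TerminalState(FivePrime.MONO_P, ThreePrime.OME): 1.0}
    ppp = {TerminalState(FivePrime.TRI_P, ThreePrime.OH): 1.0}
    return (
        [
            FragmentClassConfig("hY1", {0: 0.7, 1: 0.3},
                                peaked_length_distribution(30), pi, 0.4),
            FragmentClassConfig("hY5", {0: 0.5, 1: 0.5},
                                peaked_length_distribution(31), ppp, 0.3),
        ],
        0.3,
    )


class TestApplyTreatment:
    @pytest.mark.parametrize(
        "treatment,state_in,expected_state,expected_len",
        [
            # periodate attacks only the free 2',3'-diol: one base lost, 3'-P left
            (Treatment.OXIDATION_BETA_ELIM,
             (FivePrime.MONO_P, ThreePrime.OH), (FivePrime.MONO_P, ThreePrime.MONO_P), 29),
            (Treatment.OXIDATION_BETA_ELIM,
             (FivePrime.MONO_P, ThreePrime.OME), (FivePrime.MONO_P, ThreePrime.OME), 30),
            (Treatment.OXIDATION_BETA_ELIM,
             (FivePrime.MONO_P, ThreePrime.MONO_P), (FivePrime.MONO_P, ThreePrime.MONO_P), 30),
            (Treatment.OXIDATION_BETA_ELIM,
             (FivePrime.MONO_P, ThreePrime.CYCLIC_P), (FivePrime.MONO_P, ThreePrime.CYCLIC_P), 30),
            # RppH trims 5'-PPP to 5'-P and touches nothing else
            (Treatment.RPPH,
             (FivePrime.TRI_P, ThreePrime.OH), (FivePrime.MONO_P, ThreePrime.OH), 30),
            (Treatment.RPPH,
             (FivePrime.OH, ThreePrime.OME), (FivePrime.OH, ThreePrime.OME), 30),
            # PNK: 3' phosphates removed, 5'-OH phosphorylated
            (Treatment.PNK,
             (FivePrime.OH, ThreePrime.MONO_P), (FivePrime.MONO_P, ThreePrime.OH), 30),
            (Treatment.PNK,
             (FivePrime.TRI_P, ThreePrime.CYCLIC_P), (FivePrime.TRI_P, ThreePrime.OH), 30),
            # combined: PNK then RppH restores ligatable ends on 5'-PPP/3'-P RNA
            (Treatment.PNK_RPPH,
             (FivePrime.TRI_P, ThreePrime.MONO_P), (FivePrime.MONO_P, ThreePrime.OH), 30),
        ],
    )
    def test_terminal_chemistry_transitions(
        self, treatment, state_in, expected_state, expected_len
    ):
        read = make_read(*state_in)
        (out,) = apply_treatment([read], treatment, seed=0)
        assert (out.state.five_prime, out.state.three_prime) == expected_state
        assert len(out.seq) == expected_len
        assert out.seq == read.seq[:expected_len]

    @pytest.mark.parametrize("p,expected_five", [(1.0, FivePrime.OH),
                                                 (0.0, FivePrime.MONO_P)])
    def test_pnk_dephosphorylation_probability_extremes(self, p, expected_five):
        read = make_read(FivePrime.MONO_P, ThreePrime.OME)
        (out,) = apply_treatment([read], Treatment.PNK,
                                 params={"p_pnk_5p_dephos": p}, seed=0)
        assert out.state.five_prime == expected_five
        assert out.state.three_prime == ThreePrime.OME

    @pytest.mark.parametrize(
        "treatment", [Treatment.NONE, Treatment.OXIDATION_BETA_ELIM, Treatment.RPPH]
    )
    def test_deterministic_operators_are_idempotent(self, treatment):
        for state in ALL_STATES:
            read = make_read(state.five_prime, state.three_prime)
            once = apply_treatment([read], treatment, seed=0)
            twice = apply_treatment(once, treatment, seed=0)
            assert once[0].state == twice[0].state
            assert once[0].seq == twice[0].seq

    def test_pnk_three_prime_action_is_idempotent(self):
        # the stochastic 5' kinase/phosphatase balance is exercised elsewhere;
        # the 3' phosphatase action must be a fixed point
        for three in ThreePrime:
            read = make_read(FivePrime.TRI_P, three)
            once = apply_treatment([read], Treatment.PNK, seed=0)
            twice = apply_treatment(once, Treatment.PNK, seed=1)
            expected = (
                ThreePrime.OH
                if three in (ThreePrime.MONO_P, ThreePrime.CYCLIC_P)
                else three
            )
            assert once[0].state.three_prime == expected
            assert twice[0].state.three_prime == expected

    def test_truth_fields_preserved_and_only_oxidation_edits_sequence(self, ref):
        classes, bg = _mixed_classes()
        lib = generate_library(ref, classes, bg, 2000, seed=2)
        before = list(lib)
        for treatment in Treatment:
            treated = apply_treatment(lib, treatment, seed=4)
            for old, new in zip(before, treated):
                assert new.truth_parent == old.truth_parent
                assert new.truth_start == old.truth_start
                assert new.read_id == old.read_id
                if treatment == Treatment.OXIDATION_BETA_ELIM:
                    assert new.seq in (old.seq, old.seq[:-1])
                else:
                    assert new.seq == old.seq

    def test_library_and_read_list_paths_agree(self, ref):
        classes, bg = _mixed_classes()
        lib = generate_library(ref, classes, bg, 500, seed=6)
        for treatment in Treatment:
            via_lib = list(apply_treatment(lib, treatment, seed=13))
            via_list = apply_treatment(list(lib), treatment, seed=13)
            assert [(r.seq, r.state) for r in via_lib] == [
                (r.seq, r.state) for r in via_list
            ]


class TestLigateAndSelect:
    @pytest.mark.parametrize(
        "five,three,length,kept",
        [
            (FivePrime.MONO_P, ThreePrime.OME, 30, True),
            (FivePrime.MONO_P, ThreePrime.OH, 30, True),
            (FivePrime.TRI_P, ThreePrime.OH, 30, False),
            (FivePrime.OH, ThreePrime.OH, 30, False),
            (FivePrime.MONO_P, ThreePrime.MONO_P, 30, False),
            (FivePrime.MONO_P, ThreePrime.CYCLIC_P, 30, False),
            (FivePrime.MONO_P, ThreePrime.OH, 60, False),
        ],
    )
    def test_ligation_and_size_gates(self, five, three, length, kept):
        read = make_read(five, three, seq="A" * length)
        out = ligate_and_select([read])
        assert (len(out) == 1) is kept

    def test_selection_is_a_subset_and_a_projection(self, ref):
        classes, bg = _mixed_classes()
        lib = generate_library(ref, classes, bg, 3000, seed=8)
        once = ligate_and_select(lib)
        assert len(once) <= len(lib)
        ids_in = [r.read_id for r in lib]
        assert [r.read_id for r in once] == [
            i for i, r in zip(ids_in, lib) if r.ligatable
        ]
        twice = ligate_and_select(once)
        assert len(twice) == len(once)
        assert np.array_equal(twice.read_index, once.read_index)


class TestWriteLibrary:
    def test_fastq_and_truth_layout(self, tmp_path):
        reads = [
            make_read(FivePrime.MONO_P, ThreePrime.OME, seq="ACGT" * 7),
            make_read(FivePrime.MONO_P, ThreePrime.OH, seq="ACGT" * 8),
            SimRead("bg1", "TTTTGGGGCCCCAAAATTTTGGGGCC", BACKGROUND, None,
                    TerminalState(FivePrime.MONO_P, ThreePrime.OH)),
        ]
        fq = tmp_path / "lib.fastq"
        truth = tmp_path / "truth.tsv"
        write_library(reads, fq, truth)
        fq_lines = fq.read_text().splitlines()
        assert len(fq_lines) == 12
        assert fq_lines[0].startswith("@")
        assert fq_lines[3] == "I" * 28
        truth_lines = truth.read_text().splitlines()
        assert len(truth_lines) == 4
        assert truth_lines[-1].split("\t")[2] == "NA"

    def test_empty_library_writes_valid_empty_files(self, tmp_path):
        fq = tmp_path / "empty.fastq"
        truth = tmp_path / "truth.tsv"
        write_library([], fq, truth)
        assert fq.read_text() == ""
        assert truth.read_text().splitlines() == [
            "read_id\tparent\tstart\tlength\tfive_prime\tthree_prime"
        ]

    def test_round_trip_preserves_sequences(self, tmp_path, ref):
        classes, bg = _mixed_classes()
        lib = ligate_and_select(generate_library(ref, classes, bg, 500, seed=12))
        fq = tmp_path / "lib.fastq"
        write_library(lib, fq)
        with open(fq) as handle:
            back = [seq for _t, seq, _q in FastqGeneralIterator(handle)]
        assert back == [r.seq for r in lib]
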