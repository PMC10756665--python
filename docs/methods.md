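# Methods

## Scientific setting

YRNAs are ~100-nt RNA-polymerase-III transcripts (human homologs hY1, hY3,
hY4, hY5, of 112/101/93/83 nt) whose 5' and 3' ends base-pair into a stem.
Fragments of 25–35 nt derived from them — YsRNAs — appear in small-RNA
sequencing libraries of human sperm heads and related tissues, and their
length and terminal chemistry (5' monophosphate, 3' 2'-O-methylation) make
them piRNA-like. Two experimental facts drive the design of this package:

1. **Exact-match counting against split halves.** Because the stem makes the
   two ends of a YRNA cryptically complementary, each homolog is split into a
   5' and a 3' half before matching, and a read is counted only when the
   entire read is exactly (100% identity, forward strand) contained in a
   half. Counts are normalised to reads per million (RPM) of an
   alignable-read denominator supplied per library.
2. **Terminal chemistry controls library representation.** Standard
   two-adapter small-RNA library preparation requires a 5' monophosphate and
   a free 3'-OH. Treatments that rewrite termini (periodate
   oxidation/β-elimination, T4 PNK, RppH) therefore change which molecules
   are *sequenced at all*, and comparing RPM across treatment arms reveals
   the native termini.

## The library model

`ysrna.simulate` generates reads with a fully specified ground truth:

- **Reference.** `generate_reference_set` produces random sequences with the
  four published homolog lengths whose last `stem_len` (default 10) bases
  are the reverse complement of the first `stem_len` bases, so the stem
  rationale for split-half matching is present in the synthetic reference.
  The packaged FASTA (`ysrna/data/yrna_synthetic.fasta`) is such a synthetic
  stand-in, not the NCBI sequences; any real reference FASTA can be supplied
  instead.
- **Fragment classes.** Each class fixes a parent homolog, a start-offset
  distribution over {0, 1} (first/second base of the source), a length
  distribution over [25, 35] nt, a terminal-state distribution and an
  abundance fraction. Default length distributions are unimodal with weight
  2^(−|l − mode|), which keeps the mode unambiguous at realistic depths.
- **Background.** Non-YRNA reads (uniform lengths 25–35 nt) are
  rejection-sampled so none is an exact substring of any half, keeping truth
  labels clean. Their terminal states are a fixed mixture (63% 5'-P/3'-OH,
  18% 5'-P/3'-2'-O-methyl, 9% 3'-phosphate or cyclic phosphate, 10%
  5'-PPP/3'-OH) so that every treated library retains reads, as real
  total-RNA input does.
- **Treatment operators** act on terminal states only (plus a single 3' base
  loss for oxidation):
  - oxidation/β-elimination: 3'-OH → one base removed, 3'-P; all other 3'
    states inert;
  - RppH: 5'-PPP → 5'-P;
  - PNK: 3'-P and 2',3'-cyclic-P → 3'-OH; 5'-OH → 5'-P; existing 5'-P
    removed with probability `p_pnk_5p_dephos` (default 0.8);
  - PNK+RppH: PNK then RppH.
  Oxidation, RppH and PNK's 3' action are idempotent; PNK's 5' branch is
  intentionally not, because its competing kinase and phosphatase/exchange
  activities are collapsed into one per-molecule Bernoulli draw. The 0.8
  default is a free parameter chosen to produce a pronounced net loss of
  5'-monophosphorylated species, the qualitative behaviour the assay relies
  on; it is not a measured enzymatic efficiency.
- **Ligation and size selection.** A read is retained iff its 5' end is a
  monophosphate, its 3' end is OH or 2'-O-methyl (which leaves the 3'-OH
  free), and its length is ≤ 50 nt.

### Panel design and denominators

`workflow.simulate_panel` generates one pre-treatment pool and treats
aliquots of it, mirroring the laboratory design of dividing one RNA
preparation into treatment fractions. For simulated data the RPM denominator
is the pool size (the number of molecules that entered library preparation),
constant across the arms of a panel. This models equal RNA input per aliquot
and makes RPM an absolute recovery rate, so that a treatment that destroys
ligatability shows up as an RPM loss. A per-arm retained-read denominator
would cancel uniform losses and hide exactly the signals the assay reads out.
For real libraries the denominator is the external genome-alignment count
and is always supplied by the user, never recomputed.

## Matching and counting

The exact-match engine (`reference.MatchIndex`) is a hash map from every
substring of every half to its sorted occurrence list — practical because
halves are ≤ 56 nt, and exactly equivalent to scanning all halves for
full-read containment (property-tested against a naive scan). Matching is
forward-strand only, as small-RNA libraries are stranded. Reads shorter than
`min_len` (default 20 nt, configurable) are skipped to avoid spurious short
matches; multi-hit reads increment every matching cell. One documented
blind spot is inherent to split matching: a read spanning the half boundary
matches neither half and is not counted.

The split point is ceil(L/2), so the 5' half is never the shorter one
(112 → 56+56, 101 → 51+50, 93 → 47+46, 83 → 42+41). This is a declared
convention: the original analysis states only that sequences were divided
into roughly two halves. Coordinates are 0-based and half-open throughout;
"first base" of a source is offset 0.

## Modification calls

`inference.run_inference` converts per-(homolog, half) RPM values across
treatment arms into categorical calls:

- `ox_ratio` = RPM(oxidised)/RPM(untreated). Retention ≥
  `protected_threshold` (default 0.5) ⇒ 3' `PROTECTED_2OME`; below ⇒
  `UNPROTECTED`.
- `rpph_ratio` = RPM(RppH)/RPM(untreated), with the denominator clamped at
  `floor` when the untreated class is below it — a pure 5'-PPP class has ~0
  RPM untreated, so the clamped value is a lower bound on the true gain.
  Gain ≥ `gain_threshold` (default 2.0) ⇒ 5' `TRI_P`.
- `pnk_ratio` = RPM(PNK)/RPM(untreated). Retention ≤ `loss_threshold`
  (default 0.5) with no RppH gain ⇒ 5' `MONO_P`.
- Any ratio whose guard (untreated RPM ≥ `floor`, default 1.0 RPM) fails is
  `INSUFFICIENT_DATA` and propagates to the call. `TRI_P` takes precedence
  over `MONO_P` when both rules fire, because an RppH gain is evidence of a
  population invisible untreated.

The thresholds are package defaults, not measured quantities: they sit
midway between the two qualitative regimes the assay distinguishes (near-full
retention versus near-complete collapse; strong RppH gain versus none) and
are recorded in every output. The combined PNK+RppH arm is simulated and
tabulated but not used by the call rules, as it adds no independent
information under this model. Calls are invariant under common rescaling of
a panel's RPMs (with the floor scaled accordingly), since only ratios enter
the rules.

A consequence worth noting: classes whose 3' end is a phosphate or cyclic
phosphate are never ligatable in any rule-relevant arm, so both calls are
`INSUFFICIENT_DATA`. That is the correct output, not a failure mode — such
molecules are structurally invisible to this assay design.

## Default truth configurations

- **Sperm-head preset**: Ys1 (35%, mode 30 nt, starts mostly at base 1,
  5'-P/3'-2'-O-methyl), Ys4 (20%, mixture of 40% 5'-P/3'-2'-O-methyl and
  60% 5'-PPP/3'-OH), Ys3 (15%, mode 31 nt, starts mostly at base 2,
  5'-P/3'-2'-O-methyl), Ys5 (5%, 5'-PPP/3'-OH), 25% background. Class
  ordering (Ys1 > Ys4 > Ys3 > Ys5) and the Ys4/Ys5 triphosphate
  subpopulations reproduce the qualitative sperm-head picture.
- **Oocyte preset**: Ys3 dominant (30%), Ys4 15%, Ys5 5%, Ys1 nearly absent
  (1%), 49% background; every class 5'-P/3'-OH, so simulated oxidation
  removes all of them. Modal lengths 31–32 nt; the assignment of 31 to Ys3
  and 32 to Ys4 is a convention, since no homolog attribution for the
  oocyte modes is available.

## What the simulations do and do not show

Passing parameter-recovery tests show that the inference rules correctly
invert the library-preparation model they were designed around: fragment
origins, treatment chemistry, ligation gates and size selection. The
generator deliberately omits sequencing error, adapter-emission artefacts,
PCR duplication, partial chemical conversion, cross-mapping to non-YRNA loci
and biological replicate variance. On real data those factors blur the
ratios, so default thresholds should be read as separating qualitative
regimes, not as calibrated decision boundaries.

## Problem sizes and numerics

Simulated analyses in the test suite and acceptance script use 100,000-read
pools (matching the scale at which class RPMs are far from the 1-RPM floor)
and smaller pools (3,000–20,000 reads) where only qualitative structure is
asserted; the parameter-recovery study runs 100 replicates per terminal-state
configuration. Distribution weights must sum to 1 within 1e-9. Degenerate
inputs are defined: zero-read libraries are valid and empty; an empty
reference or a class whose fragments overrun their parent is rejected at
validation. All randomness flows through `numpy.random.default_rng` seeds;
per-arm streams are spawned from one `SeedSequence`, so a single seed fixes
every output byte.
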