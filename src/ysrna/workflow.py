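"""End-to-end in-memory pipeline: simulate a treatment panel from one RNA
pool, quantify every arm, and call terminal modifications.

The panel design mirrors the wet-lab layout: one RNA pool is generated and
then divided into aliquots, one per treatment arm, so all arms share the
same molecules and differ only in terminal chemistry.  RPM denominators are
the pool size, modelling equal RNA input per aliquot.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence

import numpy as np

from .inference import (
    CallThresholds,
    ModificationCall,
    panels_from_tables,
    run_inference,
)
from .quantify import CountTable, count_sequences
from .reference import MatchIndex, YRNASource, build_match_index
from .simulate import (
    FragmentClassConfig,
    SimLibrary,
    Treatment,
    apply_treatment,
    generate_library,
    ligate_and_select,
)

__all__ = ["simulate_panel", "quantify_panel", "run_panel"]


def simulate_panel(
    ref: Sequence[YRNASource],
    classes: Sequence[FragmentClassConfig],
    background_fraction: float,
    n_reads: int,
    treatments: Sequence[Treatment],
    seed: int = 0,
    params: Mapping[str, float] | None = None,
) -> dict[Treatment, SimLibrary]:
    """One sequencing-ready library per treatment arm, all aliquots of the
    same seeded read pool."""
    ss = np.random.SeedSequence(seed)
    pool_seed, *arm_seeds = ss.spawn(1 + len(treatments))
    pool = generate_library(ref, classes, background_fraction, n_reads,
                            seed=pool_seed)
    libs: dict[Treatment, SimLibrary] = {}
    for treatment, arm_seed in zip(treatments, arm_seeds):
        treated = apply_treatment(pool, treatment, params=params, seed=arm_seed)
        libs[treatment] = ligate_and_select(treated)
    return libs


def quantify_panel(
    libs: Mapping[Treatment, SimLibrary],
    index: MatchIndex,
    denominator: float,
    sample_prefix: str = "sim",
    min_len: int = 20,
    max_len: int = 50,
) -> list[CountTable]:
    """Count every arm of a simulated panel against the split-half index."""
    return [
        count_sequences(
            lib.sequences(), index, denominator,
            sample_id=f"{sample_prefix}_{treatment.value}", treatment=treatment,
            min_len=min_len, max_len=max_len,
        )
        for treatment, lib in libs.items()
    ]


def run_panel(
    ref: Sequence[YRNASource],
    classes: Sequence[FragmentClassConfig],
    background_fraction: float,
    n_reads: int,
    treatments: Sequence[Treatment] = (
        Treatment.NONE,
        Treatment.OXIDATION_BETA_ELIM,
        Treatment.PNK,
        Treatment.RPPH,
    ),
    seed: int = 0,
    thresholds: CallThresholds | None = None,
    params: Mapping[str, float] | None = None,
    index: MatchIndex | None = None,
) -> tuple[dict[Treatment, SimLibrary], list[CountTable], list[ModificationCall]]:
    """Simulate, quantify and call one full treatment panel."""
    if index is None:
        index = build_match_index(ref)
    libs = simulate_panel(
        ref, classes, background_fraction, n_reads, treatments, seed=seed,
        params=params,
    )
    tables = quantify_panel(libs, index, denominator=n_reads)
    calls = run_inference(panels_from_tables(tables), thresholds)
    return libs, tables, calls
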