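"""ysrna: split-half exact-match profiling of YRNA-derived small RNAs and
inference of their terminal chemistry from differential sequencing libraries.
"""

from importlib import resources

from .inference import (
    INSUFFICIENT_DATA,
    CallThresholds,
    FivePrimeCall,
    ModificationCall,
    ThreePrimeCall,
    TreatmentPanel,
    call_five_prime,
    call_three_prime,
    gain_ratio,
    panels_from_tables,
    protection_ratio,
    run_inference,
)
from .profiles import build_matrix, compare_profiles, homolog_ratio
from .quantify import (
    CountTable,
    HitRecord,
    length_profile,
    match_read,
    quantify_library,
    trim_adapter,
)
from .reference import (
    HalfReference,
    MatchIndex,
    Side,
    YRNASource,
    build_match_index,
    load_reference,
    split_halves,
)
from .simulate import (
    FivePrime,
    FragmentClassConfig,
    SimLibrary,
    SimRead,
    TerminalState,
    ThreePrime,
    Treatment,
    apply_treatment,
    generate_library,
    generate_reference_set,
    ligate_and_select,
    oocyte_config,
    sperm_head_config,
    write_library,
)
from .workflow import run_panel, simulate_panel

__version__ = "0.1.0"


def packaged_reference_path():
    """Path to the packaged synthetic YRNA homolog reference FASTA.

    The file is a synthetic stand-in generated by
    :func:`generate_reference_set`: four random sequences with the published
    homolog lengths (hY1 112 nt, hY3 101 nt, hY4 93 nt, hY5 83 nt) and a
    10-nt 5'/3' stem complementarity, not the true NCBI sequences.
    """
    return resources.files(__package__) / "data" / "yrna_synthetic.fasta"
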