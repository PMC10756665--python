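import pytest

from ysrna.reference import build_match_index
from ysrna.simulate import generate_reference_set


@pytest.fixture(scope="session")
def ref():
    """Synthetic four-homolog reference with the published YRNA lengths."""
    return generate_reference_set(lengths=(112, 101, 93, 83), stem_len=10, seed=0)


@pytest.fixture(scope="session")
def index(ref):
    return build_match_index(ref)
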