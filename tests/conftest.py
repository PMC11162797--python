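import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helper

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from primex.chemistry import homopolymer
from primex.synth import DEFAULT_PRIMER_RNA6, DEFAULT_PRIMER_TERMINAL_ONLY

#: the one fixed seed used by seeded recovery tests
SEED = 7


@pytest.fixture
def rna6_primer():
    return DEFAULT_PRIMER_RNA6


@pytest.fixture
def terminal_only_primer():
    return DEFAULT_PRIMER_TERMINAL_ONLY


@pytest.fixture
def rc6():
    return homopolymer("C", 6)
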