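import numpy as np
import pytest

from cspfam.anchor_map import Alignment
from cspfam.seqio import SeqRecord
from cspfam.synthetic_data import FamilySpec, simulate_family


@pytest.fixture
def small_alignment() -> Alignment:
    return Alignment(
        [
            SeqRecord(id="ref", seq="M-KAV-L"),
            SeqRecord(id="s1", seq="MQKAV-L"),
            SeqRecord(id="s2", seq="M-KEVAL"),
        ]
    )


@pytest.fixture
def family_bundle():
    """One default synthetic family with its truth bundle."""
    return simulate_family(FamilySpec(seed=42, sub_prob=0.03))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
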