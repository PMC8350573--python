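import numpy as np
import pytest

from prionome.composition import (
    ARABIDOPSIS_PROTEOME_FREQS,
    CANONICAL_AA,
    GENERIC_PROTEOME_FREQS,
    PRION_DOMAIN_FREQS,
)
from prionome.prld_scan import build_llr_table


def freqs_with(special):
    """Frequency table with given values; the rest uniform."""
    rest = [a for a in CANONICAL_AA if a not in special]
    remaining = 1.0 - sum(special.values())
    freqs = {a: remaining / len(rest) for a in rest}
    freqs.update(special)
    return freqs


@pytest.fixture(scope="session")
def default_table():
    """The scanner's default scoring table (alpha = 50)."""
    return build_llr_table(
        PRION_DOMAIN_FREQS,
        ARABIDOPSIS_PROTEOME_FREQS,
        GENERIC_PROTEOME_FREQS,
        alpha=50.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
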