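import numpy as np
import pytest

from mitopop.alignment import from_strings


BASES = "ACGT"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_alignment(rng, n, L, pops=None, alphabet=BASES):
    seqs = [
        "".join(rng.choice(list(alphabet), size=L)) for _ in range(n)
    ]
    return from_strings(seqs, pops=pops)


@pytest.fixture
def toy_two_pop():
    """Two populations fixed for haplotypes differing at 3 sites."""
    return from_strings(
        ["AAAAAA"] * 4 + ["TTTAAA"] * 4,
        pops=["p1"] * 4 + ["p2"] * 4,
    )
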