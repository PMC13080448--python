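import pytest

import ecfoam as e


@pytest.fixture(scope="session")
def dm_frame():
    """A double-minute-like metaphase frame: 40 scattered EC foci, 2 chr8."""
    return e.generate_metaphase(e.MetaphaseSpec(n_ec_foci=40, n_chr8=2, seed=7))


@pytest.fixture(scope="session")
def hsr_frame():
    """An HSR-like frame: few EC foci, many intrachromosomal signals."""
    return e.generate_metaphase(
        e.MetaphaseSpec(n_ec_foci=4, n_intrachromosomal_foci=30, seed=3)
    )
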