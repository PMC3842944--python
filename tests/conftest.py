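import pytest

from famcensus.simulate import SimProteomeSpec, gen_proteome


@pytest.fixture(scope="session")
def small_proteome():
    """Planted proteome: 5 true members, 3 single-domain decoys, 2 fragments."""
    return gen_proteome(
        SimProteomeSpec(
            n_true=5, n_decoys_single_domain=3, n_decoys_short=2, seed=1
        )
    )
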