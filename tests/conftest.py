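import pytest

from codonopt import build_decoding_map, default_repertoire, gen_trna_profile


@pytest.fixture(scope="session")
def repertoire():
    return default_repertoire()


@pytest.fixture(scope="session")
def dmap(repertoire):
    return build_decoding_map(repertoire)


@pytest.fixture(scope="session")
def profile():
    """A fixed skewed-but-positive anticodon abundance profile."""
    return gen_trna_profile(seed=11)
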