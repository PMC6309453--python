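import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from vnscan import (
    AlleleConfig,
    MemeSetConfig,
    TERE,
    VNS,
    gen_allele_pair,
    gen_meme_set,
    parse_pattern,
)


@pytest.fixture(scope="session")
def vns_motif():
    return parse_pattern(VNS, name="VNS")


@pytest.fixture(scope="session")
def tere_motif():
    return parse_pattern(TERE, name="TERE")


@pytest.fixture(scope="session")
def meme_fixture():
    """Eight synthetic motif files sharing a noisy 13-column core (seed 2)."""
    files, core, offsets = gen_meme_set(MemeSetConfig(seed=2))
    return files, core, offsets


@pytest.fixture(scope="session")
def allele_fixture():
    """Default promoter-allele preset: 540 bp ref, 16 subs, 1 deletion (seed 4)."""
    return gen_allele_pair(AlleleConfig(seed=4))
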