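import pytest

from tmrna_curator.core import GeneForm, Thresholds
from tmrna_curator.synth import GenConfig, gen_gene


@pytest.fixture(scope="session")
def thresholds():
    return Thresholds()


@pytest.fixture(scope="session")
def clean_gene():
    return gen_gene(GenConfig(seed=1))


@pytest.fixture(scope="session")
def relatives():
    return [gen_gene(GenConfig(seed=9900 + i))[0] for i in range(4)]


@pytest.fixture(scope="session")
def intron_gene():
    return gen_gene(
        GenConfig(seed=77, form=GeneForm.INTRON, intron_subsite=7, intron_len=293)
    )
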