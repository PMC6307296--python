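import numpy as np
import pytest

from ccch_survey import synthetic


@pytest.fixture(scope="session")
def family():
    """The synthetic 103-protein reference family with ground-truth hits."""
    return synthetic.gen_brassica_family(seed=1)


@pytest.fixture(scope="session")
def family_models():
    return synthetic.gen_brassica_gene_models(seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
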