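import numpy as np
import pytest

from duplexmc import models

DNA_MEANS = models.DNA_DEFAULT_MEAN
RNA_MEANS = models.RNA_DEFAULT_MEAN


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def dna_model():
    return models.dna_default_model()


@pytest.fixture(scope="session")
def rna_model():
    return models.rna_default_model()
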