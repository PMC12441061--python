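import pytest
from hypothesis import settings

from vntrscan.model import MotifCatalog, RepeatMotif
from vntrscan.simulate import random_catalog

settings.register_profile("suite", derandomize=True, max_examples=40, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def catalog():
    """Single GC-rich synthetic motif (the common MUC1-like case)."""
    return random_catalog(123)


@pytest.fixture(scope="session")
def catalog3():
    """Three-motif catalog exercising junction k-mer handling."""
    return random_catalog(456, n_motifs=3)


@pytest.fixture(scope="session")
def homopolymer_catalog():
    """Motif starting with a C run, for degenerate-insertion cases."""
    seq = "CCCCC" + random_catalog(789).motifs[0].sequence[5:]
    return MotifCatalog((RepeatMotif("HP1", seq),), source="test")
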