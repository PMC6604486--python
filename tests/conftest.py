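import pytest

from mipfam.alignment import make_aligner
from mipfam.motif_profile import default_templates
from mipfam import synthetic_data as sd


@pytest.fixture(scope="session")
def templates():
    return default_templates()


@pytest.fixture(scope="session")
def refset():
    """Synthetic 35-member reference aquaporin set (13/10/9/3 split)."""
    return sd.make_refset()


@pytest.fixture(scope="session")
def aligner():
    return make_aligner()
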