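import numpy as np
import pytest

from punapipe.provenance import LithicAssemblage
from punapipe.samples import load_reference_burials


@pytest.fixture(scope="session")
def burials():
    """The packaged 16-burial table (corrected isotope values, sex, ages)."""
    return load_reference_burials()


@pytest.fixture(scope="session")
def ilave_assemblage():
    """Summary-count assemblage: 539 artefacts, 534 locally matched."""
    return LithicAssemblage.from_counts(539, 534)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
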