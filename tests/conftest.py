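import numpy as np
import pytest

import aawsim as aw


@pytest.fixture(scope="session")
def standard_library():
    """A 255-peptide 14-mer library, the standard array layout."""
    return aw.generate_library(255, 14, seed=7)


@pytest.fixture(scope="session")
def standard_X(standard_library):
    return aw.composition_matrix(standard_library)


@pytest.fixture(scope="session")
def assigned_h():
    return aw.sample_assigned_aaws(seed=1)


@pytest.fixture()
def tiny_library():
    return aw.PeptideLibrary(
        ids=("p1", "p2", "p3"), sequences=("ACD", "CDA", "WYY")
    )
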