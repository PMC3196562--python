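import numpy as np
import pytest

from dcepop import (KineticParameters, REFERENCE_RATES, StudyDesign,
                    generate_study, mtl3_graph)


@pytest.fixture(scope="session")
def graph():
    return mtl3_graph()


@pytest.fixture(scope="session")
def reference_params():
    return KineticParameters(dict(REFERENCE_RATES))


@pytest.fixture(scope="session")
def small_study():
    """Five-dataset synthetic study used by fast I/O and diagnostics tests."""
    design = StudyDesign(n_datasets=5, vti_group_sizes=(2, 1, 1, 1), seed=7)
    return generate_study(design)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
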