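import numpy as np
import pytest

from hcscreen import ScreenDesign, build_screen_layout


@pytest.fixture(scope="session")
def default_design():
    return ScreenDesign()


@pytest.fixture(scope="session")
def default_layouts(default_design):
    return build_screen_layout(default_design)


@pytest.fixture(scope="session")
def small_design():
    """One-plate screen: 50 genes x 3 siRNAs fills 150 of 352 library wells."""
    return ScreenDesign(n_genes=50)


@pytest.fixture(scope="session")
def small_layouts(small_design):
    return build_screen_layout(small_design)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
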