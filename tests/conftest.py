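import warnings

import numpy as np
import pytest

from fsin.cable import build_cell
from fsin.morphology import generate_morphology
from fsin.presets import (AVERAGED_MORPHO, FITTED_DENSITIES, HUMAN_MORPHO,
                          MOUSE_MORPHO)

warnings.filterwarnings("ignore", message="resampling trace")
warnings.filterwarnings("ignore", message="dt = ")


@pytest.fixture(scope="session")
def human_tree():
    return generate_morphology(HUMAN_MORPHO)


@pytest.fixture(scope="session")
def mouse_tree():
    return generate_morphology(MOUSE_MORPHO)


@pytest.fixture(scope="session")
def averaged_tree():
    return generate_morphology(AVERAGED_MORPHO)


@pytest.fixture(scope="session")
def fitted_cell(averaged_tree):
    """The packaged re-fit model on the averaged-species morphology."""
    return build_cell(averaged_tree, FITTED_DENSITIES)


@pytest.fixture(scope="session")
def human_cell(human_tree):
    return build_cell(human_tree, FITTED_DENSITIES)


@pytest.fixture(scope="session")
def mouse_cell(mouse_tree):
    return build_cell(mouse_tree, FITTED_DENSITIES)
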