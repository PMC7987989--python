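import numpy as np
import pytest

from gastrumorph import AnalysisConfig, RegionAnnotation
from gastrumorph.synthetic import straight_lip


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def lip() -> RegionAnnotation:
    return straight_lip(length=400.0)


@pytest.fixture
def unit_square() -> RegionAnnotation:
    return RegionAnnotation("square", "polygon",
                            np.array([[0.0, 0.0], [1.0, 0.0],
                                      [1.0, 1.0], [0.0, 1.0]]))
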