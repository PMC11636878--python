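import numpy as np
import pytest

from tubepinn.geometry import CaseParameters, ChannelGeometry
from tubepinn.networks import (CASE_INPUTS, COORD_INPUTS, TSC_INPUTS,
                               NetworkSpec, build_model)


@pytest.fixture
def mid_case():
    """The single-case benchmark geometry (A = 0.025, sigma = 0.134)."""
    return CaseParameters(A=0.025, sigma=0.134)


@pytest.fixture
def mid_geom(mid_case):
    return ChannelGeometry(case=mid_case)


@pytest.fixture
def straight_case():
    return CaseParameters(A=0.0, sigma=0.134)


@pytest.fixture
def straight_geom(straight_case):
    return ChannelGeometry(case=straight_case)


@pytest.fixture
def small_mixed_model():
    """Tiny mixed network with full multi-case inputs, fixed seed."""
    spec = NetworkSpec(kind="mixed", main_widths=(16, 16),
                       input_names=COORD_INPUTS + TSC_INPUTS + CASE_INPUTS)
    return build_model(spec, seed=3)


@pytest.fixture
def interior_points(mid_geom):
    rng = np.random.default_rng(11)
    x = rng.uniform(0.05, 0.95, 120)
    from tubepinn.geometry import radius_profile

    r = radius_profile(x, mid_geom)
    y = rng.uniform(-0.9, 0.9, 120) * r
    return x, y
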