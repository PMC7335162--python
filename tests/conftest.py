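import numpy as np
import pytest

from foramxrf import (
    default_acquisition,
    default_wall_model,
    extract_profile,
    ratio_profile,
    render_element_maps,
)

TRUE_YTT_BOUNDARIES = (3000.0, 4250.0, 10250.0)


@pytest.fixture(scope="session")
def ytt_model():
    return default_wall_model("YTT")


@pytest.fixture(scope="session")
def modern_model():
    return default_wall_model("modern")


@pytest.fixture(scope="session")
def ytt_stack(ytt_model):
    """One rendered default-YTT map stack at the reference settings."""
    acq = default_acquisition(ytt_model, seed=1)
    return render_element_maps(ytt_model, acq)


@pytest.fixture(scope="session")
def ytt_profiles(ytt_stack):
    """Width-21 averaged profiles along the central row, per element."""
    width, height = next(iter(ytt_stack.maps.values())).shape[::-1]
    row = height // 2
    return {
        line: extract_profile(ytt_stack[line], (row, 0), (row, width - 1), 21)
        for line in ytt_stack.lines
    }


@pytest.fixture(scope="session")
def ytt_ratios(ytt_profiles):
    return {
        "Mn/Ca": ratio_profile(ytt_profiles["Mn"], ytt_profiles["Ca"]),
        "Zn/Ca": ratio_profile(ytt_profiles["Zn"], ytt_profiles["Ca"]),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
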