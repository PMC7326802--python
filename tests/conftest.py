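import numpy as np
import pytest
from hypothesis import settings

from myoperf.kinetics import FineCurve, KineticParams, frame_average, simulate_tissue_curve
from myoperf.synthetic import InputFunctionParams, default_schedule, feng_input
from myoperf.tac import TimeActivityCurve
from myoperf.units import seconds_to_minutes

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def schedule52():
    """The 52-frame, 30-minute dynamic protocol."""
    return default_schedule()


@pytest.fixture(scope="session")
def fine_grid():
    """0.5-s fine grid (minutes) covering the 30-minute scan."""
    return seconds_to_minutes(np.arange(0, 3601) * 0.5)


@pytest.fixture(scope="session")
def bolus_input(fine_grid):
    """Default Feng-type bolus input on the fine grid."""
    return feng_input(InputFunctionParams(), fine_grid)


@pytest.fixture(scope="session")
def noiseless_tac_factory(bolus_input, schedule52):
    """Noiseless frame-averaged tissue TAC for given kinetic parameters."""

    def make(k1: float, k2: float, vb: float, label: str = "") -> TimeActivityCurve:
        fine = simulate_tissue_curve(KineticParams(k1, k2, vb), bolus_input)
        return frame_average(fine, schedule52, region_label=label)

    return make


@pytest.fixture(scope="session")
def input_tac(bolus_input, schedule52):
    """The bolus input frame-averaged onto the acquisition schedule."""
    return frame_average(bolus_input, schedule52, region_label="LV")
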