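"""Shared fixtures: the default rig and reusable closed-loop runs.

Closed-loop runs are session-scoped because they are the expensive part of
the suite (hundreds of PnP solves each); unit tests run them at a reduced
10 Hz sample rate, which does not change the geometry being tested.
"""

import numpy as np
import pytest

from camgaze.calibration import default_calibration_dots, run_calibration
from camgaze.simulator import (RigConfig, ScenarioStream,
                               make_calibration_scenario,
                               make_fixation_scenario, run_closed_loop)

UNIT_RATE_HZ = 10.0


@pytest.fixture(scope="session")
def rig():
    return RigConfig()


@pytest.fixture(scope="session")
def screen(rig):
    return rig.screen


@pytest.fixture(scope="session")
def intrinsics(rig):
    return rig.intrinsics


@pytest.fixture(scope="session")
def calibration(rig):
    """Noiseless 5-dot calibration on the rig."""
    scenario = make_calibration_scenario(rig.screen, sample_rate_hz=UNIT_RATE_HZ)
    stream = ScenarioStream(scenario, rig)
    return run_calibration(stream.frames(), default_calibration_dots(rig.screen),
                           rig.screen, rig.intrinsics)


@pytest.fixture(scope="session")
def fixed_head_loop(rig):
    """Noiseless 16-dot fixation task with the head fixed."""
    scenario = make_fixation_scenario(rig.screen, head_mode="fixed", rig=rig,
                                      sample_rate_hz=UNIT_RATE_HZ)
    return run_closed_loop(scenario, rig, seed=11)


@pytest.fixture(scope="session")
def moving_head_loop(rig):
    """Noiseless 16-dot fixation task with the head turning toward targets."""
    scenario = make_fixation_scenario(rig.screen, head_mode="toward_target",
                                      rig=rig, sample_rate_hz=UNIT_RATE_HZ)
    return run_closed_loop(scenario, rig, seed=11)
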