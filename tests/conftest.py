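"""Shared fixtures: small, deterministic simulations reused across tests.

Simulations are session-scoped because each takes seconds; tests must not
mutate the returned truth objects.
"""

import numpy as np
import pytest

from poredirection.pattern_analysis import RegionalTrace
from poredirection.synthetic_data import (
    DYE_PRESETS,
    scenario_config,
    simulate_uptake,
    synthetic_calibration,
)


def truth_to_trace(truth, cell_id=0, weighted=True) -> RegionalTrace:
    """Regional ground truth of a simulation as a RegionalTrace."""
    rt = truth.regional_truth(weighted=weighted)
    return RegionalTrace(
        cell_id=cell_id,
        times=rt["time_s"].to_numpy(),
        anode=rt["anode"].to_numpy(),
        middle=rt["middle"].to_numpy(),
        cathode=rt["cathode"].to_numpy(),
        units="uM",
    )


@pytest.fixture(scope="session")
def anode_truth():
    """Noiseless anode-dominant scenario, 20 s, 64 px grid."""
    config = scenario_config(
        "nanosecond_multi_anode", grid_n=64, pixel_size=0.5, duration=20.0,
        pulse_time=2.0, frame_interval=0.1, noise_sigma=0.0, seed=11,
    )
    return simulate_uptake(config)


@pytest.fixture(scope="session")
def symmetric_truth():
    """Noiseless strictly symmetric calcein-style scenario, 20 s."""
    config = scenario_config(
        "symmetric_low", grid_n=64, pixel_size=0.5, duration=20.0,
        pulse_time=2.0, frame_interval=0.2, noise_sigma=0.0, seed=12,
    )
    return simulate_uptake(config)


@pytest.fixture(scope="session")
def micro_truth():
    """Noiseless microsecond-regime scenario (bipolar influx with anode
    transient, binding dye), 90 s — long enough for the asymmetry to decay
    and the middle region to overtake the anode region."""
    config = scenario_config(
        "microsecond_bipolar", grid_n=64, pixel_size=0.5, duration=90.0,
        pulse_time=5.0, frame_interval=0.2, noise_sigma=0.0, seed=13,
    )
    return simulate_uptake(config)


@pytest.fixture(scope="session")
def linear_curve():
    """Plain linear calibration used for rendering synthetic stacks."""
    return synthetic_calibration(dye_name="", slope=50.0, intercept=100.0)


@pytest.fixture
def circular_mask():
    """25-row circular mask on a 40x40 frame."""
    yy, xx = np.mgrid[0:40, 0:40]
    return (yy - 20) ** 2 + (xx - 20) ** 2 <= 12**2


@pytest.fixture
def free_dye():
    return DYE_PRESETS["calcein"]
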