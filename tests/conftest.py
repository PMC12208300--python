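"""Shared fixtures: a small synthetic population and one calibrated session.

The expensive closed-loop runs (calibration, a grid evaluation block) are
session-scoped so the decoder-quality, ablation and acceptance tests share
them.  Sixteen electrodes per array keep the loops fast while preserving
the planted per-array structure.
"""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from neurocursor import (
    CalibrationConfig,
    GridConfig,
    GridTask,
    PopulationSpec,
    SyntheticPopulation,
    run_calibration,
    run_fixed_session,
)
from neurocursor.cortex import SimulatedUser


@pytest.fixture(scope="session")
def population():
    return SyntheticPopulation(PopulationSpec(n_per_array=16, seed=1))


@pytest.fixture(scope="session")
def calibrated(population):
    """A 90 s Radial8 calibration run against the shared population."""
    result = run_calibration(
        CalibrationConfig(block_s=90.0),
        population,
        rng=np.random.default_rng(2),
    )
    assert result.cursor_decoder is not None
    return result


@pytest.fixture(scope="session")
def grid_telemetry(population, calibrated):
    """A 540 s (three blocks' worth) 6x6 grid evaluation session with the
    calibrated decoders — enough click-terminated trials for the window
    classification analyses to have statistical power."""
    rng = np.random.default_rng(3)
    task = GridTask(GridConfig(n=6), rng)
    user = SimulatedUser(stop_radius=task.cell / 2)
    return run_fixed_session(
        task,
        population,
        user,
        calibrated.normalizer,
        calibrated.cursor_decoder,
        calibrated.click_decoder,
        duration_s=540.0,
        rng=rng,
    )
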