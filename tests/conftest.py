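"""Shared fixtures: standard stimulus profiles and scenario presets."""

import dataclasses

import pytest

from povar import StimulusProfile, scenario_params


@pytest.fixture
def povar_profile() -> StimulusProfile:
    """Tilt 30 deg (336 deg/s at 17 cm), 0.3 Hz, CW, 3 minutes."""
    return StimulusProfile(paradigm="pOVAR", main_axis_velocity=336,
                           eccentric_axis_velocity=108, duration=180)


@pytest.fixture
def povar_profile_ccw(povar_profile) -> StimulusProfile:
    return dataclasses.replace(povar_profile, eccentric_axis_velocity=-108)


@pytest.fixture
def tav_profile() -> StimulusProfile:
    return StimulusProfile(paradigm="TAV", duration=60, tav_plateau_velocity=100)


@pytest.fixture
def control_scenario():
    return scenario_params("control", seed=1)
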