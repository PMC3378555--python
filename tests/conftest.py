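import numpy as np
import pandas as pd
import pytest

from retinowm import synthetic
from retinowm.design import canonical_hrf, dct_basis
from retinowm.protocol import MappingProtocol, TaskTiming


@pytest.fixture(scope="session")
def protocol():
    return MappingProtocol()


@pytest.fixture(scope="session")
def hrf(protocol):
    return canonical_hrf(protocol.volume_ms)


@pytest.fixture(scope="session")
def highpass(protocol):
    return dct_basis(protocol.n_volumes, 8)


@pytest.fixture(scope="session")
def positions():
    return synthetic.generate_stimulus_positions()


@pytest.fixture(scope="session")
def noiseless_sheet(protocol):
    return synthetic.generate_voxel_sheet(48, protocol, seed=11, noise_sd=0.0)


@pytest.fixture(scope="session")
def tiny_sheet(protocol):
    """Minimal tiling: one voxel per (area, quadrant, ring) cell, no noise."""
    return synthetic.generate_voxel_sheet(16, protocol, seed=3, noise_sd=0.0)


@pytest.fixture(scope="session")
def trials_categorical(positions):
    return synthetic.generate_trial_sequence("categorical", positions, seed=7)


@pytest.fixture(scope="session")
def trials_coordinate(positions):
    return synthetic.generate_trial_sequence("coordinate", positions, seed=7)


def single_trial_table(
    instruction: str,
    s1_quadrant: int,
    s1_ring: int,
    trial_type: str = "match",
    s2_quadrant: int | None = None,
    s2_ring: int | None = None,
    jitter_ms: float = 5000.0,
    timing: TaskTiming | None = None,
) -> pd.DataFrame:
    """Hand-built one-trial session for targeted simulation tests."""
    from retinowm.protocol import DOT_RADII, OPPOSITE_QUADRANT

    timing = timing or TaskTiming()
    if trial_type == "match" and s2_quadrant is None:
        s2_quadrant = OPPOSITE_QUADRANT[s1_quadrant] if instruction == "categorical" else s1_quadrant
        s2_ring = s1_ring
    is_catch = trial_type == "catch"
    s1_onset = float(timing.fixation_ms)
    s2_onset = s1_onset + timing.stim_ms + jitter_ms
    row = {
        "trial_id": 0,
        "instruction": instruction,
        "trial_type": trial_type,
        "s1_position_id": 0,
        "s1_quadrant": s1_quadrant,
        "s1_ring": s1_ring,
        "s1_radius_deg": DOT_RADII[s1_ring - 1],
        "s1_angle_deg": (s1_quadrant - 1) * 90.0 + 45.0,
        "s2_position_id": -1 if is_catch else 1,
        "s2_quadrant": -1 if is_catch else s2_quadrant,
        "s2_ring": -1 if is_catch else s2_ring,
        "s2_radius_deg": np.nan if is_catch else DOT_RADII[s2_ring - 1],
        "jitter_ms": jitter_ms,
        "s1_onset_ms": s1_onset,
        "s2_onset_ms": np.nan if is_catch else s2_onset,
        "correct_response": "none" if is_catch else trial_type,
    }
    trials = pd.DataFrame([row])
    trials.attrs["timing"] = timing
    trials.attrs["session_ms"] = s2_onset + timing.stim_ms + timing.response_ms + timing.iti_ms
    return trials
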