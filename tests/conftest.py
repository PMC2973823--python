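"""Shared fixtures: small synthetic recordings reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

import rgcdecode as rd
from rgcdecode.synthdata import sample_cell_params


@pytest.fixture(scope="session")
def stim300():
    """300 flashes with the default protocol (~8 min of recording)."""
    return rd.generate_stimulus(300, seed=42)


@pytest.fixture(scope="session")
def pop60(stim300):
    """Default heterogeneous population, 60 cells, fixed seed."""
    return rd.generate_population(rd.PopulationSpec(n_cells=60, seed=42), stim300)


@pytest.fixture(scope="session")
def tuned_params():
    """One tuned cell drawn from the class distribution (fixed seed)."""
    return sample_cell_params("tuned", "tuned0", np.random.default_rng(7))


@pytest.fixture(scope="session")
def tuned_recording(tuned_params):
    """A tuned cell responding to 500 flashes — the colour-readout testbed."""
    stim = rd.generate_stimulus(500, seed=7)
    train = rd.simulate_cell(tuned_params, stim, seed=70)
    return stim, train
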