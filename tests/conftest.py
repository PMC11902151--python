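import numpy as np
import pytest
from hypothesis import settings

from qeirq.model_core import NOMINAL_PARAMETERS, CellState, build_geometry
from qeirq import engine

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def nominal():
    return NOMINAL_PARAMETERS


@pytest.fixture(scope="session")
def small_record(nominal):
    """One eventful simulation on a small lattice, with a full event log."""
    geom = build_geometry(4, 20, "periodic")
    rec = engine.run_simulation(
        nominal, geom, engine.make_schedule("single"), seed=5, record_events=True
    )
    return rec


def replay_events(rec):
    """Replay an event log, asserting every transition is graph-legal.

    Returns the reconstructed final state.
    """
    codes = CellState(rec.params)
    state = np.zeros(rec.geometry.n_cells, int)
    for e in rec.events:
        cell, frm, to = int(e["cell"]), int(e["from_code"]), int(e["to_code"])
        assert state[cell] == frm, "event does not apply to the current state"
        if frm == codes.Q:
            # activation by a neighbor, or scheduled initiation straight to I_1
            assert to in (1, codes.first_i)
        else:
            assert codes.spontaneous_successor(frm) == to
        state[cell] = to
    return state
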