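import numpy as np
import pytest

from mea_evoked.core_model import (
    CompartmentMap,
    Recording,
    SpikeTrain,
    StimulationSession,
    assign_compartments,
    standard_120_layout,
    three_compartment_geometry,
)


@pytest.fixture(scope="session")
def layout():
    return standard_120_layout()


@pytest.fixture(scope="session")
def compartments(layout):
    return assign_compartments(layout, three_compartment_geometry(layout))


@pytest.fixture
def small_recording(layout, compartments):
    """Tiny deterministic recording: 3 populated electrodes, one session."""
    duration = 700.0
    eids = list(layout.electrode_ids[:3])
    trains = {
        eids[0]: SpikeTrain(eids[0], np.arange(1.0, 600.0, 2.0), 0.0, duration),
        eids[1]: SpikeTrain(eids[1], np.array([10.0, 10.05, 10.1]), 0.0, duration),
        eids[2]: SpikeTrain(eids[2], np.array([]), 0.0, duration),
    }
    for eid in layout.electrode_ids[3:]:
        trains[eid] = SpikeTrain(eid, np.array([]), 0.0, duration)
    session = StimulationSession(eids[0], 600.0 + 2.5 + 5.0 * np.arange(12))
    return Recording(
        layout=layout,
        compartments=compartments,
        trains=trains,
        sessions=(session,),
        population_label="other",
        duration=duration,
    )
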