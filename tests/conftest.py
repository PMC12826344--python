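import numpy as np
import pytest

from dmpacost.cohort import (
    CohortParams,
    ParticipantRecord,
    default_study_params,
    generate_cohort,
)
from dmpacost.costs import CostSchedule, build_cost_schedule, default_inventory
from dmpacost.estimation import TransitionMatrix
from dmpacost.states import FACILITY, SI, STATES


@pytest.fixture(scope="session")
def inventory():
    return default_inventory()


@pytest.fixture(scope="session")
def schedule(inventory):
    return build_cost_schedule(inventory)


@pytest.fixture(scope="session")
def study_params():
    return default_study_params(seed=0)


@pytest.fixture(scope="session")
def study_cohort(study_params):
    return generate_cohort(study_params)


@pytest.fixture
def toy_two_state():
    """One costed absorbing-exit state: stay 0.8/cycle, $3/cycle, n0=100."""
    p = np.eye(len(STATES))
    i, j = STATES.index(SI), STATES.index("NONE")
    p[i, i], p[i, j] = 0.8, 0.2
    matrix = TransitionMatrix(states=STATES, p=p)
    sched = CostSchedule(per_cycle={(SI, FACILITY): 3.0}, si_entry_cost={})
    return matrix, sched


def make_record(arm, statuses, units=None, location=FACILITY, pid="P0000"):
    """Shorthand for a participant record: statuses exclude wave 0."""
    return ParticipantRecord(
        participant_id=pid,
        arm=arm,
        location=location,
        wave_status=(arm, *statuses),
        units_dispensed=units,
    )


def small_params(**overrides) -> CohortParams:
    base = dict(
        n_per_arm=(40, 40, 40),
        hazard_change=0.2,
        p_transition_si=0.5,
        retention_per_wave=0.95,
        seed=0,
    )
    base.update(overrides)
    return CohortParams(**base)
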