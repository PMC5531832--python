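import numpy as np
import pandas as pd
import pytest

from pstmodels import (
    AgentParams,
    build_session_schedule,
    modified_pst,
    original_pst,
    simulate_session,
)


@pytest.fixture(scope="session")
def modified_spec():
    return modified_pst()


@pytest.fixture(scope="session")
def original_spec():
    return original_pst()


@pytest.fixture(scope="session")
def modified_session(modified_spec):
    """One simulated two-day session of a competent learner."""
    sched = build_session_schedule(modified_spec, seed=2024)
    params = AgentParams(alpha_gain=0.35, alpha_loss=0.3, beta=4.0)
    return simulate_session(params, sched, "ON-ON", seed=77, subject_id="S1")


def make_trials(choices, feedbacks, pair_label="AB", phase="learning",
                subject_id="S1", condition="ON", stims=("A", "B")):
    """Hand-built trial table for metric fixtures."""
    rows = []
    for i, (c, f) in enumerate(zip(choices, feedbacks)):
        rows.append(
            {
                "subject_id": subject_id,
                "group": "PD",
                "condition": condition,
                "session_day": 1,
                "phase": phase,
                "block": 0,
                "trial": i,
                "pair_label": pair_label,
                "stim_left": stims[0],
                "stim_right": stims[1],
                "choice": c,
                "chose_optimal": c == stims[0],
                "feedback": f,
            }
        )
    return pd.DataFrame(rows)
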